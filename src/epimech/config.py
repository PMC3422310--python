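"""YAML experiment configuration.

A single config file holds blocks ``growth``, ``mechanics``, ``policy``,
``experiment``, ``output`` and ``seed``; unknown keys are rejected so typos
fail early.  All defaults match the study protocol (growth increments
1-8%, division at doubled size, unit tension coefficients, 10 replicates
for natural proliferation and 5 for the differential experiment).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import GrowthParams, SimConfig
from .mechanics import MechParams
from .schemes import SchemePolicy


@dataclass
class OutputSpec:
    directory: str = "out"
    svg: bool = False


@dataclass
class ExperimentSpec:
    kind: str = "simulate"  # simulate | natural | memory | differential
    replicates: int = 10
    max_cells: int = 4000
    schemes: list[str] = field(default_factory=lambda: ["random",
                                                        "largest_side",
                                                        "orthogonal"])
    strategy: str = "probabilistic_mix"
    values: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75])
    gammas: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0])
    seed_cells: int = 1000
    clone_fraction: float = 0.10
    rounds: int = 5


@dataclass
class FullConfig:
    growth: GrowthParams = field(default_factory=GrowthParams)
    mechanics: MechParams = field(default_factory=MechParams)
    policy: SchemePolicy = field(default_factory=SchemePolicy)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    output: OutputSpec = field(default_factory=OutputSpec)
    seed: int = 0

    def sim_config(self) -> SimConfig:
        import dataclasses as dc
        growth = dc.replace(self.growth,
                            max_cells=self.experiment.max_cells)
        return SimConfig(growth=growth, mech=self.mechanics,
                         policy=self.policy, seed=self.seed)


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> FullConfig:
    """Parse a YAML config file into a :class:`FullConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"growth", "mechanics", "policy", "experiment", "output", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    return FullConfig(
        growth=_build(GrowthParams, raw.get("growth", {}), "growth"),
        mechanics=_build(MechParams, raw.get("mechanics", {}), "mechanics"),
        policy=_build(SchemePolicy, raw.get("policy", {}), "policy"),
        experiment=_build(ExperimentSpec, raw.get("experiment", {}),
                          "experiment"),
        output=_build(OutputSpec, raw.get("output", {}), "output"),
        seed=int(raw.get("seed", 0)),
    )


def echo_config(config: FullConfig, path: str | Path) -> None:
    """Write the fully resolved config back out as YAML."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=False))
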