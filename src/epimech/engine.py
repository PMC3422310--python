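"""The stochastic growth–relax–divide–rearrange main loop.

Each time step: (1) every proliferating cell's target size is multiplied by
``1 + u`` with ``u`` uniform in the growth range (quiescent cells do not
grow); (2) the mesh is relaxed to quasi-static force balance; (3) every
cell whose target size has doubled since birth divides through a plane
chosen by the active orientation policy; (4) relax; (5) short inner edges
undergo T1 neighbor exchange; (6) relax.

With the default growth range of 1–8% per step, a cell needs about
``log 2 / log 1.045 ~ 16`` steps to double, so roughly 17 steps make one
round of division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import fixtures
from .core import Tissue, validate
from .mechanics import MechParams, assign_tensions, relax
from .schemes import SchemePolicy, choose_plane, pick_scheme, record_division
from .topology import (DivisionError, T1Refused, TopoEvent,
                       detect_t1_candidates, divide_cell, t1_rearrangement)

logger = logging.getLogger(__name__)

#: nominal number of engine steps that make up one round of division
STEPS_PER_ROUND = 17


@dataclass
class GrowthParams:
    """Stochastic growth and division-trigger parameters.

    ``growth_low``/``growth_high`` bound the per-step relative target-size
    increment; division triggers once a cell's target size reaches
    ``division_threshold`` times its size at birth, provided the cell has
    mechanically caught up with its target (its area/target ratio is at
    least ``relax_gate`` times the tissue median, which keeps geometrically
    unrelaxed cells from dividing).  ``t1_threshold_frac`` sets the T1
    trigger as a fraction of the mean inner-edge length.
    """

    growth_low: float = 0.01
    growth_high: float = 0.08
    division_threshold: float = 2.0
    relax_gate: float = 0.8
    t1_threshold_frac: float = 0.05
    max_cells: int = 4000
    max_generations: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.growth_low <= self.growth_high:
            raise ValueError("growth range must satisfy 0 < low <= high")
        if self.division_threshold <= 1:
            raise ValueError("division_threshold must exceed 1")


@dataclass
class SimConfig:
    growth: GrowthParams = field(default_factory=GrowthParams)
    mech: MechParams = field(default_factory=MechParams)
    policy: SchemePolicy = field(default_factory=SchemePolicy)
    seed: int = 0
    initial: str = "single"  # "single" or a Tissue supplied to run()
    check_invariants: bool = False


@dataclass
class SimulationResult:
    """Time series of events and polygon-class histograms for one run."""

    seed: int
    config: dict
    events: list[TopoEvent]
    histograms: list[dict]  # per step: {"step", "n_cells", "counts": {k: n}}
    tissue: Tissue
    n_steps: int

    @property
    def division_events(self) -> list[TopoEvent]:
        return [e for e in self.events if e.kind == "division"]

    @property
    def t1_events(self) -> list[TopoEvent]:
        return [e for e in self.events if e.kind == "t1"]

    def division_intervals(self) -> list[int]:
        """Steps between a cell's birth and its own division, for every
        dividing cell that was itself born during the run."""
        birth: dict[int, int] = {}
        intervals = []
        for ev in self.events:
            if ev.kind != "division":
                continue
            mother, d1, d2 = ev.cells
            if mother in birth:
                intervals.append(ev.step - birth[mother])
            birth[d1] = ev.step
            birth[d2] = ev.step
        return intervals


def interior_class_counts(tissue: Tissue) -> dict[int, int]:
    """Polygon-class counts over interior cells (no outer edge)."""
    counts: dict[int, int] = {}
    for cid in tissue.interior_cell_ids():
        k = tissue.sidedness(cid)
        counts[k] = counts.get(k, 0) + 1
    return counts


def step(tissue: Tissue, growth: GrowthParams, mech: MechParams,
         policy: SchemePolicy, rng: np.random.Generator,
         step_index: int = 0) -> list[TopoEvent]:
    """Advance the tissue one time step; returns the events executed."""
    events: list[TopoEvent] = []

    # (1) stochastic growth of target sizes, proliferating cells only
    prolif = sorted(c for c, cell in tissue.cells.items() if cell.proliferating)
    if prolif:
        incr = rng.uniform(growth.growth_low, growth.growth_high, len(prolif))
        for cid, u in zip(prolif, incr):
            tissue.cells[cid].target_size *= 1.0 + u

    # (2) relax to quasi-static balance
    relax(tissue, mech)

    # (3) divisions
    eps_len = 1e-3 * tissue.mean_edge_length()
    if prolif:
        ratios = {cid: tissue.cell_area(cid) / tissue.cells[cid].target_size
                  for cid in prolif}
        median_ratio = float(np.median(list(ratios.values())))
        eligible = [cid for cid in prolif
                    if tissue.cells[cid].target_size
                    >= growth.division_threshold * tissue.cells[cid].birth_target
                    and ratios[cid] >= growth.relax_gate * median_ratio]
        order = [eligible[i] for i in rng.permutation(len(eligible))]
        for cid in order:
            cell = tissue.cells[cid]
            scheme = pick_scheme(cell, policy, rng)
            try:
                plane = choose_plane(tissue, cid, scheme, rng)
                d1, d2, ev = divide_cell(tissue, cid, plane,
                                         eps_len=eps_len, step=step_index)
            except (DivisionError, ValueError) as exc:
                logger.debug("division of cell %d deferred: %s", cid, exc)
                continue
            record_division((tissue.cells[d1], tissue.cells[d2]),
                            plane, scheme, cell.lineage.all_orthogonal)
            ev.info["scheme"] = scheme
            events.append(ev)

    # (4) relax after divisions
    if events:
        assign_tensions(tissue, mech)
    relax(tissue, mech)

    # (5) T1 rearrangements on short inner edges, at most one per junction
    thr = growth.t1_threshold_frac * tissue.mean_edge_length(inner_only=True)
    used_vertices: set[int] = set()
    n_t1 = 0
    for eid in detect_t1_candidates(tissue, thr):
        if eid not in tissue.edges:
            continue
        e = tissue.edges[eid]
        if e.v1 in used_vertices or e.v2 in used_vertices:
            continue
        if tissue.edge_length(eid) >= thr:
            continue
        verts = (e.v1, e.v2)
        try:
            ev = t1_rearrangement(tissue, eid, eps_len=eps_len,
                                  new_len=1.2 * thr, step=step_index)
        except T1Refused as exc:
            logger.debug("T1 on edge %d refused: %s", eid, exc)
            continue
        used_vertices.update(verts)
        events.append(ev)
        n_t1 += 1

    # (6) final relax
    if n_t1:
        assign_tensions(tissue, mech)
    relax(tissue, mech)
    return events


def run(config: SimConfig, initial_tissue: Tissue | None = None,
        ) -> SimulationResult:
    """Run the growth engine until the stop criterion.

    Starts from a single cell (a regular 12-gon of unit area) unless an
    ``initial_tissue`` is supplied.  Stops when the cell count reaches
    ``max_cells`` or any cell reaches ``max_generations`` divisions.
    Identical configs and seeds give identical event logs.
    """
    rng = np.random.default_rng(config.seed)
    if initial_tissue is not None:
        tissue = initial_tissue
    elif config.initial == "single":
        tissue = fixtures.single_cell()
    else:
        raise ValueError(f"unknown initial condition {config.initial!r}")

    assign_tensions(tissue, config.mech)
    relax(tissue, config.mech)

    events: list[TopoEvent] = []
    histograms: list[dict] = []
    step_index = 0
    while True:
        if len(tissue.cells) >= config.growth.max_cells:
            break
        if any(c.generation >= config.growth.max_generations
               for c in tissue.cells.values()):
            break
        step_index += 1
        events.extend(step(tissue, config.growth, config.mech, config.policy,
                           rng, step_index))
        histograms.append({"step": step_index, "n_cells": len(tissue.cells),
                           "counts": interior_class_counts(tissue)})
        if config.check_invariants:
            report = validate(tissue)
            if report:
                raise AssertionError(
                    f"invariant violations at step {step_index}: {report[:5]}")
        if step_index > 200 * config.growth.max_generations:
            logger.warning("run stopped: step budget exhausted")
            break

    return SimulationResult(seed=config.seed, config=_echo_config(config),
                            events=events, histograms=histograms,
                            tissue=tissue, n_steps=step_index)


def _echo_config(config: SimConfig) -> dict:
    from dataclasses import asdict
    return {"growth": asdict(config.growth),
            "mech": asdict(config.mech),
            "policy": {"mode": config.policy.mode,
                       "p_orthogonal": config.policy.p_orthogonal,
                       "initial_type_assignment":
                           dict(config.policy.initial_type_assignment)},
            "seed": config.seed,
            "initial": config.initial}
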