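"""The two experiment families: natural proliferation and differential
proliferation with tunable boundary tension.

*Natural proliferation* grows a tissue from a single cell under one of the
division-plane orientation schemes (or a memory-mixing strategy) and
reports the polygon-class distribution and rearrangement counts, averaged
over seeded replicates.

*Differential proliferation* starts from an equilibrated tissue, marks an
inner clone as proliferating and the surrounding cells as quiescent, sets
the tension coefficient ``gamma_pq`` on the clone boundary, and tracks how
the mean sidedness of interfacial proliferating (IP) and interfacial
quiescent (IQ) cells departs from its value at the start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import fixtures
from .core import Tissue
from .engine import (STEPS_PER_ROUND, GrowthParams, SimConfig, run, step)
from .mechanics import MechParams, assign_tensions, relax
from .schemes import SchemePolicy
from .stats import (hexagon_frequency, mean_sidedness, polygon_distribution,
                    rearrangement_count)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# natural proliferation
# ----------------------------------------------------------------------

def run_natural(schemes: list[str] | tuple[str, ...] = ("random",
                                                        "largest_side",
                                                        "orthogonal"),
                replicates: int = 10, max_cells: int = 4000,
                base_seed: int = 0,
                growth: GrowthParams | None = None,
                mech: MechParams | None = None) -> pd.DataFrame:
    """Grow replicate tissues from a single cell for each scheme.

    Returns one row per (scheme, replicate) with the final interior
    polygon-class frequencies, hexagon frequency, mean sidedness and T1
    count.  Replicates differ only by seed.
    """
    rows = []
    for scheme in schemes:
        for rep in range(replicates):
            seed = base_seed + 1000 * rep + _scheme_offset(scheme)
            cfg = _natural_config(scheme, max_cells, seed, growth, mech)
            res = run(cfg)
            rows.append(_distribution_row(res, scheme=scheme, replicate=rep,
                                          seed=seed))
    return pd.DataFrame(rows)


def _scheme_offset(scheme: str) -> int:
    return {"random": 0, "largest_side": 1, "orthogonal": 2,
            "probabilistic_mix": 3, "lineage_typed": 4}.get(scheme, 9)


def _natural_config(scheme: str, max_cells: int, seed: int,
                    growth: GrowthParams | None,
                    mech: MechParams | None,
                    policy: SchemePolicy | None = None) -> SimConfig:
    g = growth if growth is not None else GrowthParams()
    g = replace(g, max_cells=max_cells, max_generations=99)
    return SimConfig(growth=g,
                     mech=mech if mech is not None else MechParams(),
                     policy=policy if policy is not None
                     else SchemePolicy(mode=scheme),
                     seed=seed)


def _distribution_row(res, **meta) -> dict:
    hist = polygon_distribution(res.tissue)
    row = dict(meta)
    row.update({
        "n_cells": len(res.tissue.cells),
        "n_interior": hist.n_cells,
        "hexagon_frequency": hexagon_frequency(hist),
        "mean_sidedness": mean_sidedness(hist),
        "t1_count": rearrangement_count(res),
        "n_steps": res.n_steps,
    })
    for k in range(3, 11):
        row[f"f{k}"] = hist.frequency(k)
    return row


def aggregate_natural(table: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean and standard deviation per scheme."""
    cols = [c for c in table.columns
            if c.startswith("f") or c in ("hexagon_frequency",
                                          "mean_sidedness", "t1_count")]
    return table.groupby("scheme")[cols].agg(["mean", "std"])


# ----------------------------------------------------------------------
# cell-memory mixing
# ----------------------------------------------------------------------

def run_memory(strategy: str, values: list[float], replicates: int = 5,
               max_cells: int = 4000, base_seed: int = 0,
               growth: GrowthParams | None = None,
               mech: MechParams | None = None) -> pd.DataFrame:
    """Mix orthogonal and largest-side division by one of two strategies.

    ``strategy="probabilistic_mix"``: each division independently uses the
    orthogonal scheme with probability ``p`` (grid given by ``values``).
    ``strategy="lineage_typed"``: the run starts from 4 founding cells, of
    which a fraction (grid given by ``values``, multiples of 1/4) carries a
    heritable orthogonal type; daughters inherit their mother's type.

    Returns one row per (value, replicate) with the final distribution and
    the fraction of cells whose entire ancestry divided orthogonally.
    """
    if strategy not in ("probabilistic_mix", "lineage_typed"):
        raise ValueError(f"unknown memory strategy {strategy!r}")
    rows = []
    for value in values:
        for rep in range(replicates):
            seed = base_seed + 1000 * rep + int(round(100 * value)) + 7
            if strategy == "probabilistic_mix":
                policy = SchemePolicy(mode="probabilistic_mix",
                                      p_orthogonal=value)
                cfg = _natural_config("probabilistic_mix", max_cells, seed,
                                      growth, mech, policy=policy)
                res = run(cfg)
            else:
                res = _run_lineage_typed(value, max_cells, seed, growth, mech)
            row = _distribution_row(res, strategy=strategy, value=value,
                                    replicate=rep, seed=seed)
            row["all_orthogonal_fraction"] = _all_orthogonal_fraction(res.tissue)
            rows.append(row)
    return pd.DataFrame(rows)


def _all_orthogonal_fraction(tissue: Tissue) -> float:
    flags = [c.lineage.all_orthogonal and c.generation > 0
             for c in tissue.cells.values()]
    return float(np.mean(flags)) if flags else 0.0


def _run_lineage_typed(fraction: float, max_cells: int, seed: int,
                       growth: GrowthParams | None,
                       mech: MechParams | None):
    """Grow to 4 founding cells, type ``fraction`` of them orthogonal, then
    continue under inherited types."""
    n_orth = int(round(4 * fraction))
    if abs(4 * fraction - n_orth) > 1e-9:
        raise ValueError("lineage fraction must be a multiple of 1/4")
    cfg4 = _natural_config("largest_side", 4, seed, growth, mech)
    warm = run(cfg4)
    tissue = warm.tissue
    rng = np.random.default_rng(seed + 555)
    ids = sorted(tissue.cells)
    orth_ids = set(rng.choice(ids, size=n_orth, replace=False)) if n_orth else set()
    for cid, cell in tissue.cells.items():
        cell.lineage.heritable_type = ("orthogonal" if cid in orth_ids
                                       else "largest_side")
        # ancestry bookkeeping restarts at the typed founders
        cell.lineage.all_orthogonal = cid in orth_ids
        cell.generation = 0
    policy = SchemePolicy(mode="lineage_typed")
    cfg = _natural_config("lineage_typed", max_cells, seed + 1, growth, mech,
                          policy=policy)
    return run(cfg, initial_tissue=tissue)


def memory_linear_fit(table: pd.DataFrame) -> dict:
    """Linear regression of hexagon frequency on the mixing value
    (slope, intercept, r-squared)."""
    res = sps.linregress(table["value"], table["hexagon_frequency"])
    return {"slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2}


# ----------------------------------------------------------------------
# differential proliferation
# ----------------------------------------------------------------------

@dataclass
class DifferentialConfig:
    """Protocol parameters for the differential-proliferation experiment.

    The seed tissue is an equilibrated epithelium; an inner clone of
    ``clone_fraction`` of its cells proliferates while the rest is
    quiescent.  ``gamma_pq`` is the tension coefficient on clone-boundary
    edges (tensions inside each compartment stay at 1).
    """

    seed_cells: int = 1000
    clone_fraction: float = 0.10
    gamma_pq: float = 1.0
    rounds: int = 5
    replicates: int = 5
    base_seed: int = 0
    growth: GrowthParams = field(default_factory=GrowthParams)
    mech: MechParams = field(default_factory=MechParams)

    def __post_init__(self) -> None:
        if self.gamma_pq <= 0:
            raise ValueError("gamma_pq must be positive")
        if not 0 < self.clone_fraction < 1:
            raise ValueError("clone_fraction must be in (0, 1)")


def identify_interface_cells(tissue: Tissue) -> tuple[set[int], set[int]]:
    """Interfacial proliferating (IP) and interfacial quiescent (IQ) cells.

    IP cells are proliferating cells with at least one quiescent neighbor;
    IQ cells are quiescent cells with at least one proliferating neighbor.
    The sets are disjoint; both are empty in a single-class tissue.
    """
    ip, iq = set(), set()
    for cid, cell in tissue.cells.items():
        for nid in tissue.neighbors(cid):
            other = tissue.cells[nid]
            if cell.proliferating and not other.proliferating:
                ip.add(cid)
            elif not cell.proliferating and other.proliferating:
                iq.add(cid)
    return ip, iq


def assign_differential_classes(tissue: Tissue,
                                clone_fraction: float = 0.10) -> set[int]:
    """Mark the innermost ``clone_fraction`` of cells (by distance of their
    centroid from the tissue centroid) as proliferating, the rest
    quiescent.  Returns the clone's cell ids."""
    cents = {cid: tissue.cell_centroid(cid) for cid in tissue.cells}
    middle = np.mean(list(cents.values()), axis=0)
    dists = {cid: float(np.hypot(*(c - middle))) for cid, c in cents.items()}
    cutoff = np.quantile(list(dists.values()), clone_fraction)
    clone = {cid for cid, d in dists.items() if d <= cutoff}
    for cid, cell in tissue.cells.items():
        cell.proliferating = cid in clone
    return clone


def make_seed_tissue(n_cells: int, seed: int,
                     mech: MechParams | None = None) -> Tissue:
    """Equilibrated starting tissue for the differential experiment: a
    centroidally relaxed Voronoi epithelium brought to mechanical balance
    (a stand-in for the endpoint of a natural proliferation run)."""
    tissue = fixtures.voronoi_tissue(n_cells, seed=seed)
    p = mech if mech is not None else MechParams()
    assign_tensions(tissue, p)
    relax(tissue, p)
    return tissue


def run_differential(config: DifferentialConfig,
                     seed_tissue: Tissue | None = None) -> pd.DataFrame:
    """Differential-proliferation time series for one boundary tension.

    Returns one row per (replicate, step) with the mean sidedness of the
    current IP and IQ sets and their change from the t=0 baseline.  The
    division policy is largest-side.
    """
    rows = []
    for rep in range(config.replicates):
        seed = config.base_seed + 1000 * rep + int(10 * config.gamma_pq)
        tissue = (seed_tissue.copy() if seed_tissue is not None
                  else make_seed_tissue(config.seed_cells, seed))
        assign_differential_classes(tissue, config.clone_fraction)
        mech = replace(config.mech, gamma_pq=config.gamma_pq)
        assign_tensions(tissue, mech)
        relax(tissue, mech)

        ip0, iq0 = identify_interface_cells(tissue)
        if not ip0 or not iq0:
            raise ValueError("seed tissue has no proliferating/quiescent "
                             "interface")
        base_ip = float(np.mean([tissue.sidedness(c) for c in ip0]))
        base_iq = float(np.mean([tissue.sidedness(c) for c in iq0]))

        rng = np.random.default_rng(seed)
        policy = SchemePolicy(mode="largest_side")
        n_steps = config.rounds * STEPS_PER_ROUND
        for si in range(1, n_steps + 1):
            step(tissue, config.growth, mech, policy, rng, step_index=si)
            ip, iq = identify_interface_cells(tissue)
            m_ip = (float(np.mean([tissue.sidedness(c) for c in ip]))
                    if ip else np.nan)
            m_iq = (float(np.mean([tissue.sidedness(c) for c in iq]))
                    if iq else np.nan)
            rows.append({
                "gamma_pq": config.gamma_pq, "replicate": rep, "step": si,
                "round": (si - 1) // STEPS_PER_ROUND + 1,
                "n_cells": len(tissue.cells),
                "n_ip": len(ip), "n_iq": len(iq),
                "mean_ip": m_ip, "mean_iq": m_iq,
                "delta_ip": m_ip - base_ip, "delta_iq": m_iq - base_iq,
            })
    return pd.DataFrame(rows)


def differential_steady_state(table: pd.DataFrame,
                              from_round: int = 4) -> pd.DataFrame:
    """Steady-state change in mean sidedness per boundary tension: the
    across-replicate mean of ``delta_ip``/``delta_iq`` over rounds
    ``from_round`` and later."""
    late = table[table["round"] >= from_round]
    return late.groupby("gamma_pq")[["delta_ip", "delta_iq"]].mean()
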