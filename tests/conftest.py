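"""Shared fixtures.

The expensive simulation campaigns (replicate growth runs to 1,000 cells,
memory-mixing grids, the differential-proliferation protocol) are session-
scoped so the acceptance tests and the distribution-shape tests share one
set of runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from epimech import fixtures
from epimech.engine import GrowthParams, SimConfig, run
from epimech.mechanics import MechParams, assign_tensions, relax
from epimech.schemes import SchemePolicy

logging.getLogger("epimech").setLevel(logging.ERROR)

SCHEMES = ("largest_side", "orthogonal", "random")
N_REPLICATES = 5
#: growth-run endpoint for the scaled-down distribution campaigns (about
#: ten rounds of division from a single cell)
NATURAL_MAX_CELLS = 1000


@pytest.fixture(scope="session")
def honeycomb19():
    return fixtures.honeycomb(19)


@pytest.fixture(scope="session")
def relaxed_honeycomb():
    t = fixtures.honeycomb(61)
    assign_tensions(t, MechParams())
    relax(t, MechParams())
    return t


@pytest.fixture()
def mech_params():
    return MechParams()


def natural_config(mode: str, seed: int,
                   max_cells: int = NATURAL_MAX_CELLS) -> SimConfig:
    return SimConfig(growth=GrowthParams(max_cells=max_cells,
                                         max_generations=99),
                     policy=SchemePolicy(mode=mode), seed=seed)


@pytest.fixture(scope="session")
def natural_runs():
    """Replicate growth runs per scheme: single cell grown to 1,000 cells."""
    out = {}
    for mode in SCHEMES:
        out[mode] = [run(natural_config(mode, seed))
                     for seed in range(1, N_REPLICATES + 1)]
    return out


@pytest.fixture(scope="session")
def memory_mix_table():
    from epimech.experiments import run_memory
    return run_memory("probabilistic_mix", values=[0.25, 0.5, 0.75],
                      replicates=4, max_cells=1000, base_seed=100)


@pytest.fixture(scope="session")
def memory_lineage_table():
    """Lineage-typed mixing at full scale: clones need several hundred
    cells each before the heritable types express their topology."""
    from epimech.experiments import run_memory
    return run_memory("lineage_typed", values=[0.0, 0.25, 0.5, 0.75, 1.0],
                      replicates=3, max_cells=4000, base_seed=400)


@pytest.fixture(scope="session")
def differential_tables():
    """Differential-proliferation time series for the four boundary
    tensions, on a shared 1,000-cell equilibrated seed tissue."""
    import pandas as pd

    from epimech.experiments import (DifferentialConfig, make_seed_tissue,
                                     run_differential)
    seed_tissue = make_seed_tissue(1000, seed=11)
    frames = []
    for gamma in (0.5, 1.0, 1.5, 2.0):
        cfg = DifferentialConfig(seed_cells=1000, clone_fraction=0.10,
                                 gamma_pq=gamma, rounds=5, replicates=2,
                                 base_seed=3)
        frames.append(run_differential(cfg, seed_tissue=seed_tissue))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def one_run(natural_runs):
    """A single representative endpoint (largest-side scheme)."""
    return natural_runs["largest_side"][0]


def hexagon_pct(result) -> float:
    from epimech.stats import hexagon_frequency, polygon_distribution
    return 100.0 * hexagon_frequency(polygon_distribution(result.tissue))
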