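"""Observables: polygon-class distributions, hexagon frequency, sidedness
means and changes, rearrangement counts.

By default, distributions are taken over *interior* cells only (cells with
no outer edge): cells on the tissue rim are missing neighbors, which
depresses their sidedness for reasons of geometry rather than topology
regulation.  Pass an explicit subset to override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Tissue


@dataclass
class PolygonHistogram:
    """Counts of cells per polygon class (sidedness)."""

    counts: dict[int, int] = field(default_factory=dict)
    subset: str = "interior"

    @property
    def n_cells(self) -> int:
        return sum(self.counts.values())

    def frequency(self, k: int) -> float:
        """Normalized frequency of polygon class ``k``."""
        n = self.n_cells
        if n == 0:
            raise ValueError("empty histogram")
        return self.counts.get(k, 0) / n

    def frequencies(self) -> dict[int, float]:
        n = self.n_cells
        if n == 0:
            raise ValueError("empty histogram")
        return {k: v / n for k, v in sorted(self.counts.items())}

    def to_series(self, classes: Sequence[int] = range(3, 11)) -> pd.Series:
        return pd.Series({k: self.frequency(k) for k in classes},
                         name="frequency")


def polygon_distribution(tissue: Tissue,
                         subset: Iterable[int] | None = None) -> PolygonHistogram:
    """Histogram of polygon classes over a cell subset.

    ``subset`` defaults to the interior cells (no outer edge); an empty
    subset is an error.
    """
    if subset is None:
        ids = tissue.interior_cell_ids()
        label = "interior"
    else:
        ids = list(subset)
        label = "custom"
    if not ids:
        raise ValueError("empty cell subset")
    counts: dict[int, int] = {}
    for cid in ids:
        k = tissue.sidedness(cid)
        counts[k] = counts.get(k, 0) + 1
    return PolygonHistogram(counts=counts, subset=label)


def hexagon_frequency(histogram: PolygonHistogram) -> float:
    """Frequency of the 6-sided class."""
    return histogram.frequency(6)


def mean_sidedness(histogram: PolygonHistogram) -> float:
    """Count-weighted mean polygon class."""
    n = histogram.n_cells
    if n == 0:
        raise ValueError("empty histogram")
    return sum(k * v for k, v in histogram.counts.items()) / n


def rearrangement_count(result) -> int:
    """Number of executed T1 events over a whole run."""
    return sum(1 for e in result.events if e.kind == "t1")


def delta_mean_sides(series: Sequence[float], baseline: float) -> np.ndarray:
    """Element-wise change of a mean-sidedness time series from a baseline."""
    return np.asarray(series, dtype=float) - baseline


def steady_state_delta(series: Sequence[float], baseline: float,
                       steps_per_round: int = 17) -> float:
    """Steady-state change in mean sidedness: the average of
    ``series - baseline`` over the final round of the series."""
    s = delta_mean_sides(series, baseline)
    if len(s) < steps_per_round:
        raise ValueError("series shorter than one round of division")
    return float(np.mean(s[-steps_per_round:]))


def summary_frame(result) -> pd.DataFrame:
    """Per-step summary table of a simulation run.

    Columns: step, n_cells, class frequencies 3..10, mean sidedness and the
    cumulative T1 count.
    """
    t1_by_step: dict[int, int] = {}
    for e in result.events:
        if e.kind == "t1":
            t1_by_step[e.step] = t1_by_step.get(e.step, 0) + 1
    rows = []
    cum_t1 = 0
    for h in result.histograms:
        counts = h["counts"]
        n = sum(counts.values())
        cum_t1 += t1_by_step.get(h["step"], 0)
        row = {"step": h["step"], "n_cells": h["n_cells"]}
        for k in range(3, 11):
            row[f"f{k}"] = counts.get(k, 0) / n if n else np.nan
        row["mean_sidedness"] = (sum(k * v for k, v in counts.items()) / n
                                 if n else np.nan)
        row["cum_t1"] = cum_t1
        rows.append(row)
    return pd.DataFrame(rows)
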