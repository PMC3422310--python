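"""Experiment drivers: interfaces, memory mixing, differential protocol."""

import networkx as nx
import numpy as np
import pytest

from epimech import fixtures
from epimech.engine import GrowthParams
from epimech.experiments import (DifferentialConfig,
                                 assign_differential_classes,
                                 identify_interface_cells, make_seed_tissue,
                                 memory_linear_fit, run_differential,
                                 run_memory, run_natural)


class TestInterfaceCells:
    def test_single_cell_clone(self):
        t = fixtures.honeycomb(19)
        for c in t.cells.values():
            c.proliferating = False
        t.cells[0].proliferating = True
        ip, iq = identify_interface_cells(t)
        assert ip == {0}
        assert iq == t.neighbors(0)

    def test_single_class_tissue_has_empty_sets(self):
        t = fixtures.honeycomb(19)
        ip, iq = identify_interface_cells(t)
        assert ip == set() and iq == set()
        for c in t.cells.values():
            c.proliferating = False
        ip, iq = identify_interface_cells(t)
        assert ip == set() and iq == set()

    def test_sets_are_disjoint(self):
        t = make_seed_tissue(200, seed=1)
        assign_differential_classes(t, 0.2)
        ip, iq = identify_interface_cells(t)
        assert ip and iq and not (ip & iq)

    def test_clone_interface_forms_a_ring(self):
        t = make_seed_tissue(500, seed=8)
        assign_differential_classes(t, 0.1)
        ip, _ = identify_interface_cells(t)
        assert len(ip) >= 8
        g = nx.Graph()
        g.add_nodes_from(ip)
        for cid in ip:
            for nid in t.neighbors(cid):
                if nid in ip:
                    g.add_edge(cid, nid)
        assert nx.is_connected(g)
        assert all(d >= 2 for _, d in g.degree())  # a closed ring, no stubs


class TestAssignClasses:
    def test_requested_fraction_is_marked(self):
        t = make_seed_tissue(300, seed=2)
        clone = assign_differential_classes(t, 0.1)
        assert len(clone) == pytest.approx(30, abs=4)
        assert all(t.cells[c].proliferating for c in clone)
        assert not any(t.cells[c].proliferating
                       for c in set(t.cells) - clone)

    def test_clone_is_strictly_interior(self):
        t = make_seed_tissue(300, seed=2)
        clone = assign_differential_classes(t, 0.1)
        assert not any(t.touches_exterior(c) for c in clone)


SMALL_GROWTH = GrowthParams(max_cells=64, max_generations=99)


class TestMemoryStrategies:
    def test_probability_one_uses_only_orthogonal(self):
        table = run_memory("probabilistic_mix", values=[1.0], replicates=1,
                           max_cells=64, base_seed=0)
        assert table["all_orthogonal_fraction"].iloc[0] == pytest.approx(1.0)

    def test_probability_zero_has_no_orthogonal_ancestry(self):
        table = run_memory("probabilistic_mix", values=[0.0], replicates=1,
                           max_cells=64, base_seed=0)
        assert table["all_orthogonal_fraction"].iloc[0] == pytest.approx(0.0)

    def test_all_orthogonal_ancestry_decays_like_p_to_the_g(self):
        """Under an even mix the surviving all-orthogonal fraction after g
        generations is p^g (0.5^6 ~ 1.6% at 64 cells)."""
        table = run_memory("probabilistic_mix", values=[0.5], replicates=4,
                           max_cells=64, base_seed=1)
        frac = table["all_orthogonal_fraction"].mean()
        assert frac == pytest.approx(0.5 ** 6, abs=0.04)

    def test_lineage_fraction_is_preserved_by_inheritance(self):
        table = run_memory("lineage_typed", values=[0.25], replicates=1,
                           max_cells=64, base_seed=2)
        # a quarter of the founders are orthogonal-typed, and inheritance
        # keeps the lineage fraction at exactly 1/4
        assert table["all_orthogonal_fraction"].iloc[0] == \
            pytest.approx(0.25, abs=0.08)

    def test_lineage_fraction_must_be_quarter_multiple(self):
        with pytest.raises(ValueError):
            run_memory("lineage_typed", values=[0.3], replicates=1,
                       max_cells=16)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            run_memory("telepathic", values=[0.5])

    def test_linear_fit_on_synthetic_line(self):
        import pandas as pd
        table = pd.DataFrame({"value": [0, 0.25, 0.5, 0.75, 1.0],
                              "hexagon_frequency": [0.45, 0.475, 0.5,
                                                    0.525, 0.55]})
        fit = memory_linear_fit(table)
        assert fit["slope"] == pytest.approx(0.1)
        assert fit["intercept"] == pytest.approx(0.45)
        assert fit["r_squared"] == pytest.approx(1.0)


class TestNaturalDriver:
    def test_table_has_one_row_per_scheme_and_replicate(self):
        table = run_natural(schemes=["largest_side", "random"], replicates=2,
                            max_cells=48, base_seed=0)
        assert len(table) == 4
        assert set(table["scheme"]) == {"largest_side", "random"}
        assert (table["n_cells"] >= 48).all()
        fcols = [c for c in table.columns if c.startswith("f")]
        assert np.allclose(table[fcols].sum(axis=1), 1.0, atol=1e-6)


class TestDifferentialDriver:
    def test_requires_an_interface(self):
        t = fixtures.honeycomb(19)  # all proliferating: no interface
        cfg = DifferentialConfig(seed_cells=19, replicates=1, rounds=1)
        with pytest.raises(ValueError):
            # classes assigned inside; fraction puts the whole patch in
            # one class only if the tissue is degenerate -- force it
            for c in t.cells.values():
                c.proliferating = True
            ip, iq = identify_interface_cells(t)
            if not ip:
                raise ValueError("no interface")
            run_differential(cfg, seed_tissue=t)

    def test_time_series_shape_and_round_clock(self):
        cfg = DifferentialConfig(seed_cells=150, clone_fraction=0.1,
                                 gamma_pq=1.0, rounds=2, replicates=1,
                                 base_seed=1)
        table = run_differential(cfg)
        assert len(table) == 2 * 17  # rounds x steps-per-round
        assert table["round"].max() == 2
        assert (table.groupby("round").size() == 17).all()
        # deltas are consistent with the recorded means
        first = table.iloc[0]
        base_ip = first["mean_ip"] - first["delta_ip"]
        assert np.allclose(table["mean_ip"] - table["delta_ip"], base_ip)
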