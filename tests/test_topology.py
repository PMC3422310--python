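"""Cell division and T1 neighbor exchange."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimech import fixtures
from epimech.core import build_tissue, validate
from epimech.topology import (DivisionError, DivisionPlane, T1Refused,
                              detect_t1_candidates, divide_cell,
                              t1_rearrangement)

SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


class TestDivision:
    def test_square_cut_through_opposite_midpoints(self):
        t = build_tissue([SQUARE])
        d1, d2, ev = divide_cell(t, 0, DivisionPlane((0.5, 0.5), (0, 1)))
        assert validate(t) == []
        assert {len(t.cells[d].edges) for d in (d1, d2)} == {4}
        assert t.cell_area(d1) == pytest.approx(0.5, abs=1e-3)
        assert t.cell_area(d2) == pytest.approx(0.5, abs=1e-3)

    def test_hexagon_cut_gives_pentagon_daughters_and_heptagon_neighbors(self):
        t = fixtures.honeycomb(19)
        center = 0
        eid = t.cells[center].edges[0]
        e = t.edges[eid]
        mid = 0.5 * (t.vertices[e.v1] + t.vertices[e.v2])
        c = t.cell_centroid(center)
        before = {n: t.sidedness(n) for n in t.neighbors(center)}
        d1, d2, ev = divide_cell(t, center, DivisionPlane(c, mid - c))
        assert validate(t) == []
        assert t.sidedness(d1) == 5 and t.sidedness(d2) == 5
        gained = [n for n, s in before.items() if t.sidedness(n) == s + 1]
        assert len(gained) == 2  # the two cut neighbors go hexagon -> heptagon
        assert all(before[n] == 6 for n in gained)

    def test_area_is_conserved(self):
        t = fixtures.honeycomb(19)
        total = t.total_area()
        c = t.cell_centroid(0)
        divide_cell(t, 0, DivisionPlane(c, (1, 0.3)))
        assert t.total_area() == pytest.approx(total, rel=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(angle=st.floats(0, np.pi), cell_index=st.integers(0, 6))
    def test_daughter_sidedness_sum_identity(self, angle, cell_index):
        """Interior mother of sidedness n cut on two inner edges:
        daughter sidedness sums to n + 4."""
        t = fixtures.honeycomb(49)
        cid = t.interior_cell_ids()[cell_index]
        n = t.sidedness(cid)
        c = t.cell_centroid(cid)
        plane = DivisionPlane(c, (np.cos(angle), np.sin(angle)))
        try:
            d1, d2, ev = divide_cell(t, cid, plane)
        except DivisionError:
            return  # tangent / degenerate planes may defer; nothing to check
        # both cuts landed on inner edges (interior mother in a honeycomb)
        assert t.sidedness(d1) + t.sidedness(d2) == n + 4
        assert validate(t) == []

    def test_skewed_plane_is_rebalanced(self):
        # anchor far off-center: the split must still come out near half
        t = build_tissue([SQUARE])
        d1, d2, _ = divide_cell(t, 0, DivisionPlane((0.05, 0.5), (0, 1)))
        frac = t.cell_area(d1)
        assert 0.35 <= frac <= 0.65

    def test_plane_missing_cell_raises(self):
        t = build_tissue([SQUARE])
        with pytest.raises(DivisionError):
            divide_cell(t, 0, DivisionPlane((5.0, 5.0), (0, 1)))


class TestT1:
    @staticmethod
    def inner_edge_with_four_distinct_cells(t):
        for eid, e in t.edges.items():
            if e.is_inner:
                try:
                    return eid
                except T1Refused:
                    continue
        raise AssertionError("no candidate edge")

    def test_sidedness_transfer(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items()
                   if set(edge.cells()) == {0, 1})
        ev = t1_rearrangement(t, eid, eps_len=0.01)
        losers, gainers = ev.cells[:2], ev.cells[2:]
        assert [t.sidedness(c) for c in losers] == [5, 5]
        assert [t.sidedness(c) for c in gainers] == [7, 7]
        assert validate(t) == []

    def test_total_side_count_cell_count_area_conserved(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items()
                   if set(edge.cells()) == {0, 1})
        sides = sum(len(c.edges) for c in t.cells.values())
        ncells, area = len(t.cells), t.total_area()
        t1_rearrangement(t, eid, eps_len=0.01)
        assert sum(len(c.edges) for c in t.cells.values()) == sides
        assert len(t.cells) == ncells
        assert t.total_area() == pytest.approx(area, rel=1e-9)

    def test_involution_restores_adjacency(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items()
                   if set(edge.cells()) == {0, 1})
        ev = t1_rearrangement(t, eid, eps_len=0.01)
        assert 1 not in t.neighbors(0)
        t1_rearrangement(t, ev.edges_created[0], eps_len=0.01)
        assert 1 in t.neighbors(0)
        assert validate(t) == []

    def test_boundary_edge_refused(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items() if not edge.is_inner)
        with pytest.raises(T1Refused):
            t1_rearrangement(t, eid)

    def test_new_edge_orthogonal_to_old(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items()
                   if set(edge.cells()) == {0, 1})
        old = t.edge_vector(eid)
        ev = t1_rearrangement(t, eid, eps_len=0.01)
        new = t.edge_vector(ev.edges_created[0])
        assert abs(np.dot(old, new)) < 1e-9
        assert np.hypot(*new) == pytest.approx(0.01)


class TestDetectCandidates:
    def test_uniform_honeycomb_has_none(self, honeycomb19):
        thr = 0.1 * honeycomb19.mean_edge_length(inner_only=True)
        assert detect_t1_candidates(honeycomb19, thr) == []

    def test_shrunk_edge_is_found(self, honeycomb19):
        t = honeycomb19.copy()
        eid = next(e for e, edge in t.edges.items()
                   if set(edge.cells()) == {0, 1})
        e = t.edges[eid]
        mid = 0.5 * (t.vertices[e.v1] + t.vertices[e.v2])
        d = t.vertices[e.v2] - t.vertices[e.v1]
        t.vertices[e.v1][:] = mid - 0.005 * d
        t.vertices[e.v2][:] = mid + 0.005 * d
        thr = 0.1 * t.mean_edge_length(inner_only=True)
        assert detect_t1_candidates(t, thr) == [eid]

    def test_all_candidates_below_threshold(self):
        t = fixtures.voronoi_tissue(60, seed=5)
        rng = np.random.default_rng(0)
        # anisotropic squeeze creates short edges
        for v in t.vertices.values():
            v[1] *= 0.55
        thr = 0.3 * t.mean_edge_length(inner_only=True)
        for eid in detect_t1_candidates(t, thr):
            assert t.edge_length(eid) < thr
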