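"""Force laws and quasi-static relaxation."""

import numpy as np
import pytest

from epimech import fixtures
from epimech.core import build_tissue
from epimech.mechanics import (DegenerateGeometryError, MechParams,
                               _MeshArrays, assign_tensions, cell_pressure,
                               net_vertex_forces, pressure_force, relax,
                               tension_force)


def horizontal_pair():
    """Two unit squares sharing a vertical edge."""
    sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
    return build_tissue([sq, [(1, 0), (2, 0), (2, 1), (1, 1)]])


class TestTensionForce:
    def test_unit_edge_pulls_endpoints_together(self):
        t = build_tissue([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        eid = next(e for e, edge in t.edges.items()
                   if abs(t.edge_vector(e)[1]) < 1e-12)  # a horizontal edge
        t.edges[eid].tension = 1.0
        f1, f2 = tension_force(t, eid)
        v = t.edge_vector(eid)
        u = v / np.hypot(*v)
        assert f1 == pytest.approx(u)        # v1 pulled toward v2
        assert f2 == pytest.approx(-u)
        assert np.allclose(f1 + f2, 0)

    def test_linear_in_coefficient(self):
        t = horizontal_pair()
        eid = next(e for e, edge in t.edges.items() if edge.is_inner)
        t.edges[eid].tension = 2.0
        f1, _ = tension_force(t, eid)
        assert np.hypot(*f1) == pytest.approx(2.0)

    def test_mixed_class_edge_uses_gamma_pq(self):
        t = horizontal_pair()
        cells = list(t.cells.values())
        cells[0].proliferating = True
        cells[1].proliferating = False
        assign_tensions(t, MechParams(gamma_pq=1.5))
        eid = next(e for e, edge in t.edges.items() if edge.is_inner)
        f1, _ = tension_force(t, eid)
        assert np.hypot(*f1) == pytest.approx(1.5)

    def test_zero_length_edge_raises(self):
        t = horizontal_pair()
        eid = next(iter(t.edges))
        e = t.edges[eid]
        t.vertices[e.v2][:] = t.vertices[e.v1]
        with pytest.raises(DegenerateGeometryError):
            tension_force(t, eid)


class TestCellPressure:
    def test_zero_at_target(self):
        t = build_tissue([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        t.cells[0].target_size = t.cell_area(0)
        assert cell_pressure(t, 0, MechParams()) == pytest.approx(0.0)

    def test_compressed_cell_pushes_outward(self):
        t = build_tissue([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        t.cells[0].target_size = 2.0  # area 1 = half the target
        p = cell_pressure(t, 0, MechParams(pressure_stiffness=1.0))
        assert p == pytest.approx(1.0)  # K (At - A) / A = 1 * 1 / 1

    def test_monotone_decreasing_in_area(self):
        params = MechParams()
        values = []
        for scale in (0.6, 0.8, 1.0, 1.2, 1.4):
            sq = np.array([(0, 0), (1, 0), (1, 1), (0, 1)]) * scale
            t = build_tissue([sq])
            t.cells[0].target_size = 1.0
            values.append(cell_pressure(t, 0, params))
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[2] == pytest.approx(0.0)

    def test_nonpositive_target_rejected(self):
        t = build_tissue([[(0, 0), (1, 0), (1, 1), (0, 1)]])
        t.cells[0].target_size = 0.0
        with pytest.raises(ValueError):
            cell_pressure(t, 0, MechParams())


class TestPressureForce:
    def test_equal_pressures_cancel(self):
        t = horizontal_pair()
        eid = next(e for e, edge in t.edges.items() if edge.is_inner)
        f1, f2 = pressure_force(t, eid, 1.0, 1.0)
        assert np.allclose(f1, 0) and np.allclose(f2, 0)

    def test_magnitude_and_direction(self):
        t = horizontal_pair()
        eid = next(e for e, edge in t.edges.items() if edge.is_inner)
        e = t.edges[eid]
        f1, f2 = pressure_force(t, eid, 1.0, 0.0)
        # each endpoint carries half of |dp| * length = 0.5
        assert np.hypot(*f1) == pytest.approx(0.5)
        assert np.allclose(f1, f2)
        # force points from the higher-pressure (left) cell into the right
        right_centroid = t.cell_centroid(e.right)
        mid = 0.5 * (t.vertices[e.v1] + t.vertices[e.v2])
        assert np.dot(f1, right_centroid - mid) > 0

    def test_antisymmetric_in_pressure_swap(self):
        t = horizontal_pair()
        eid = next(e for e, edge in t.edges.items() if edge.is_inner)
        f1, _ = pressure_force(t, eid, 1.0, 0.0)
        g1, _ = pressure_force(t, eid, 0.0, 1.0)
        assert np.allclose(f1, -g1)


class TestNetForces:
    def test_honeycomb_interior_at_equilibrium(self):
        t = fixtures.honeycomb(61)
        assign_tensions(t, MechParams())
        ff = net_vertex_forces(t, MechParams())
        interior = [i for i, v in enumerate(ff.vertex_ids)
                    if all(t.edges[e].is_inner for e in t.vertex_edges(v))]
        assert len(interior) > 0
        assert np.max(np.hypot(*ff.total[interior].T)) < 1e-9

    @pytest.mark.parametrize("maker", [
        lambda: fixtures.honeycomb(37),
        lambda: fixtures.voronoi_tissue(40, seed=4),
    ])
    def test_total_force_sums_to_zero(self, maker):
        t = maker()
        assign_tensions(t, MechParams())
        ff = net_vertex_forces(t, MechParams())
        assert np.allclose(ff.total.sum(axis=0), 0, atol=1e-8)
        # internal force pairs cancel separately per contribution
        assert np.allclose(ff.tension.sum(axis=0), 0, atol=1e-8)
        assert np.allclose(ff.pressure.sum(axis=0), 0, atol=1e-8)

    def test_perturbed_vertex_feels_restoring_force(self):
        params = MechParams()
        t = fixtures.honeycomb(19)
        assign_tensions(t, params)
        relax(t, params)
        vid = next(v for v in t.vertices
                   if all(t.edges[e].is_inner for e in t.vertex_edges(v)))
        orig = t.vertices[vid].copy()
        delta = np.array([0.01, 0.004])
        t.vertices[vid] += delta
        ff = net_vertex_forces(t, params)
        f = ff.total[ff.vertex_ids.index(vid)]
        # force points within 90 degrees of the restoring direction
        assert np.dot(f, -delta) > 0


class TestRelax:
    def test_equilibrium_needs_no_iterations(self):
        params = MechParams()
        t = fixtures.honeycomb(61)
        assign_tensions(t, params)
        for _ in range(5):  # settle the rim fully
            _, iters = relax(t, params)
            if iters < params.max_relax_iters:
                break
        before = {v: p.copy() for v, p in t.vertices.items()}
        _, iters = relax(t, params)
        assert iters <= 1
        assert all(np.allclose(before[v], t.vertices[v]) for v in before)

    def test_small_perturbation_recovered(self):
        params = MechParams()
        t = fixtures.honeycomb(19)
        assign_tensions(t, params)
        relax(t, params)
        vid = next(v for v in t.vertices
                   if all(t.edges[e].is_inner for e in t.vertex_edges(v)))
        orig = t.vertices[vid].copy()
        t.vertices[vid] += 0.01 * t.mean_edge_length()
        relax(t, params)
        assert np.hypot(*(t.vertices[vid] - orig)) < 1e-2

    def test_grown_cell_expands(self):
        params = MechParams()
        t = fixtures.honeycomb(19)
        assign_tensions(t, params)
        relax(t, params)
        before = t.cell_area(0)
        t.cells[0].target_size *= 2.0
        relax(t, params)
        assert t.cell_area(0) > before

    def test_kernel_matches_numpy_path(self):
        params = MechParams()
        a = fixtures.voronoi_tissue(30, seed=9)
        b = a.copy()
        assign_tensions(a, params)
        assign_tensions(b, params)
        relax(a, params, use_kernel=True)
        relax(b, params, use_kernel=False)
        pa = np.array([a.vertices[v] for v in sorted(a.vertices)])
        pb = np.array([b.vertices[v] for v in sorted(b.vertices)])
        assert np.allclose(pa, pb, atol=1e-9)

    def test_force_evaluations_agree_between_paths(self):
        params = MechParams()
        t = fixtures.voronoi_tissue(25, seed=2)
        assign_tensions(t, params)
        arrays = _MeshArrays.from_tissue(t)
        f_np, _ = arrays.forces(arrays.pos, params.pressure_stiffness)
        from epimech._kernels import HAVE_NUMBA, _forces_into
        if not HAVE_NUMBA:
            pytest.skip("numba unavailable; single-path build")
        force = np.zeros_like(f_np)
        areas = np.zeros(len(arrays.ctarget))
        _forces_into(np.ascontiguousarray(arrays.pos), arrays.ev1,
                     arrays.ev2, arrays.eten, arrays.eleft, arrays.eright,
                     arrays.ctarget, arrays.seg_a, arrays.seg_b,
                     arrays.seg_cell, params.pressure_stiffness, force, areas)
        assert np.allclose(force, f_np, atol=1e-12)
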