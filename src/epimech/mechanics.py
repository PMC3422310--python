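"""Tension and pressure forces on junction vertices, and quasi-static
relaxation of the mesh.

Two forces act on every edge and are carried to its endpoint vertices:

* **Tension** — a constant-magnitude line tension.  Each endpoint is pulled
  toward the opposite endpoint with force equal to the edge's tension
  coefficient (the unit vector in the direction of shortening the edge).
  The coefficient may depend on the cell classes on either side of the
  edge, which is how increased tension at a proliferating/quiescent
  boundary is modeled.
* **Pressure** — cells below their target area push outward.  A cell's
  pressure follows a gas-like area-restoring law ``p = K (A_t - A) / A``:
  zero at target, diverging under compression (so line tension can never
  crush a cell to zero area), tending to ``-K`` under extreme stretch.
  The net pressure force on an edge is ``(p_left - p_right) * length``,
  normal to the edge, from the higher-pressure side to the lower, split
  equally between its endpoints.  The exterior medium has pressure 0.

Between topological events the tissue is assumed quasi-static: vertices are
moved by overdamped gradient descent until the maximum residual force falls
below a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import EXTERIOR, Tissue

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised by force evaluation on a zero-length edge."""


@dataclass
class MechParams:
    """Mechanical parameters.

    ``gamma_pp``, ``gamma_qq`` and ``gamma_pq`` are tension coefficients on
    edges between two proliferating cells, two quiescent cells, and a
    mixed pair; ``boundary_tension`` applies to outer edges.
    ``pressure_stiffness`` is the pressure constant ``K`` of the gas-like
    area-restoring law, calibrated so the simulated rearrangement rate per
    division under random plane orientation matches the reported value;
    ``step_fraction`` sets the Euler step as a fraction of the mean edge
    length per unit force (the product of mobility and time step).
    """

    gamma_pp: float = 1.0
    gamma_qq: float = 1.0
    gamma_pq: float = 1.0
    boundary_tension: float = 1.0
    pressure_stiffness: float = 2.0
    mobility: float = 1.0
    step_fraction: float = 0.05
    relax_tolerance: float = 1e-3
    max_relax_iters: int = 500

    def __post_init__(self) -> None:
        for name in ("gamma_pp", "gamma_qq", "gamma_pq", "boundary_tension",
                     "pressure_stiffness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mobility <= 0 or self.relax_tolerance <= 0:
            raise ValueError("mobility and relax_tolerance must be positive")

    def tension_for(self, left_proliferating: bool | None,
                    right_proliferating: bool | None) -> float:
        """Tension coefficient by the cell classes of an edge's two sides
        (``None`` meaning the exterior)."""
        if left_proliferating is None or right_proliferating is None:
            return self.boundary_tension
        if left_proliferating and right_proliferating:
            return self.gamma_pp
        if not left_proliferating and not right_proliferating:
            return self.gamma_qq
        return self.gamma_pq


@dataclass
class ForceField:
    """Per-vertex force vectors decomposed into tension and pressure."""

    vertex_ids: list[int]
    tension: np.ndarray  # (n, 2)
    pressure: np.ndarray  # (n, 2)

    @property
    def total(self) -> np.ndarray:
        return self.tension + self.pressure

    def max_magnitude(self) -> float:
        return float(np.max(np.hypot(*self.total.T))) if len(self.vertex_ids) else 0.0


def assign_tensions(tissue: Tissue, params: MechParams) -> None:
    """Set every edge's tension coefficient from the cell classes on its
    two sides (outer edges get the boundary tension)."""
    for e in tissue.edges.values():
        lp = None if e.left == EXTERIOR else tissue.cells[e.left].proliferating
        rp = None if e.right == EXTERIOR else tissue.cells[e.right].proliferating
        e.tension = params.tension_for(lp, rp)


# ----------------------------------------------------------------------
# single-element force laws (reference API; relaxation uses the array form)
# ----------------------------------------------------------------------

def tension_force(tissue: Tissue, edge_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Tension force pair on the edge's endpoints ``(f_v1, f_v2)``.

    Each endpoint is pulled toward the other with magnitude equal to the
    edge's tension coefficient; the pair sums to zero.
    """
    e = tissue.edges[edge_id]
    d = tissue.edge_vector(edge_id)
    length = float(np.hypot(*d))
    if length <= 0:
        raise DegenerateGeometryError(f"edge {edge_id} has zero length")
    u = d / length
    return e.tension * u, -e.tension * u


def cell_pressure(tissue: Tissue, cell_id: int, params: MechParams) -> float:
    """Gas-like area-restoring pressure ``p = K (A_t - A) / A``.

    Positive and diverging when the cell is compressed below its target
    area, zero at target, negative (bounded below by ``-K``) when
    stretched.
    """
    cell = tissue.cells[cell_id]
    if cell.target_size <= 0:
        raise ValueError(f"cell {cell_id} has nonpositive target size")
    area = tissue.cell_area(cell_id)
    return (params.pressure_stiffness * (cell.target_size - area)
            / max(area, 1e-12 * cell.target_size))


def pressure_force(tissue: Tissue, edge_id: int, p_left: float,
                   p_right: float) -> tuple[np.ndarray, np.ndarray]:
    """Pressure force pair on the edge's endpoints.

    Net magnitude ``|p_left - p_right| * length``, normal to the edge,
    directed from the higher-pressure side to the lower, split equally
    between the endpoints.
    """
    d = tissue.edge_vector(edge_id)
    length = float(np.hypot(*d))
    if length <= 0:
        raise DegenerateGeometryError(f"edge {edge_id} has zero length")
    u = d / length
    # for a counter-clockwise left cell, (-uy, ux) points into the left
    # side, so (uy, -ux) is the outward normal from left into right
    n_right = np.array([u[1], -u[0]])
    f = 0.5 * (p_left - p_right) * length * n_right
    return f, f


def net_vertex_forces(tissue: Tissue, params: MechParams) -> ForceField:
    """Net force on every vertex: the sum of tension and pressure
    contributions of all incident edges."""
    arrays = _MeshArrays.from_tissue(tissue)
    ften, fpre, _ = arrays.forces(arrays.pos, params.pressure_stiffness,
                                  split=True)
    return ForceField(vertex_ids=arrays.vids, tension=ften, pressure=fpre)


# ----------------------------------------------------------------------
# array-based evaluation and relaxation
# ----------------------------------------------------------------------

@dataclass
class _MeshArrays:
    """Flat numpy view of a tissue for fast force evaluation."""

    vids: list[int]
    pos: np.ndarray        # (nv, 2)
    ev1: np.ndarray        # (ne,) vertex slot of each edge's v1
    ev2: np.ndarray
    eten: np.ndarray       # (ne,) tension coefficients
    eleft: np.ndarray      # (ne,) cell slot or -1 for the exterior
    eright: np.ndarray
    ctarget: np.ndarray    # (nc,) target areas
    seg_a: np.ndarray      # boundary segments (vertex slots), CCW per cell
    seg_b: np.ndarray
    seg_cell: np.ndarray   # owning cell slot per segment
    cids: list[int] = field(default_factory=list)

    @classmethod
    def from_tissue(cls, tissue: Tissue) -> "_MeshArrays":
        vids = sorted(tissue.vertices)
        vslot = {v: i for i, v in enumerate(vids)}
        pos = np.array([tissue.vertices[v] for v in vids], dtype=float)
        cids = sorted(tissue.cells)
        cslot = {c: i for i, c in enumerate(cids)}

        eids = sorted(tissue.edges)
        ev1 = np.array([vslot[tissue.edges[e].v1] for e in eids], dtype=np.intp)
        ev2 = np.array([vslot[tissue.edges[e].v2] for e in eids], dtype=np.intp)
        eten = np.array([tissue.edges[e].tension for e in eids], dtype=float)
        eleft = np.array([cslot.get(tissue.edges[e].left, -1) for e in eids],
                         dtype=np.intp)
        eright = np.array([cslot.get(tissue.edges[e].right, -1) for e in eids],
                          dtype=np.intp)
        ctarget = np.array([tissue.cells[c].target_size for c in cids], dtype=float)

        seg_a, seg_b, seg_cell = [], [], []
        for c in cids:
            loop = tissue.cell_vertex_loop(c)
            k = len(loop)
            for i in range(k):
                seg_a.append(vslot[loop[i]])
                seg_b.append(vslot[loop[(i + 1) % k]])
                seg_cell.append(cslot[c])
        return cls(vids=vids, pos=pos, ev1=ev1, ev2=ev2, eten=eten,
                   eleft=eleft, eright=eright, ctarget=ctarget,
                   seg_a=np.array(seg_a, dtype=np.intp),
                   seg_b=np.array(seg_b, dtype=np.intp),
                   seg_cell=np.array(seg_cell, dtype=np.intp), cids=cids)

    def areas(self, pos: np.ndarray) -> np.ndarray:
        pa, pb = pos[self.seg_a], pos[self.seg_b]
        cross = pa[:, 0] * pb[:, 1] - pa[:, 1] * pb[:, 0]
        return 0.5 * np.bincount(self.seg_cell, weights=cross,
                                 minlength=len(self.ctarget))

    def forces(self, pos: np.ndarray, stiffness: float, split: bool = False):
        """Per-vertex forces at the given positions; returns
        ``(tension, pressure, areas)`` if ``split`` else ``(total, areas)``."""
        nv = len(pos)
        d = pos[self.ev2] - pos[self.ev1]
        length = np.hypot(d[:, 0], d[:, 1])
        safe = np.maximum(length, 1e-12)
        ux, uy = d[:, 0] / safe, d[:, 1] / safe

        areas = self.areas(pos)
        p = stiffness * (self.ctarget - areas) / np.maximum(areas, 1e-12 * self.ctarget)
        pl = np.where(self.eleft >= 0, p[self.eleft], 0.0)
        pr = np.where(self.eright >= 0, p[self.eright], 0.0)
        # half of the net pressure force per endpoint, normal into the
        # lower-pressure side
        half = 0.5 * (pl - pr) * length
        fpx, fpy = half * uy, -half * ux

        tx, ty = self.eten * ux, self.eten * uy
        if split:
            ften = np.zeros((nv, 2))
            fpre = np.zeros((nv, 2))
            ften[:, 0] = (np.bincount(self.ev1, tx, minlength=nv)
                          - np.bincount(self.ev2, tx, minlength=nv))
            ften[:, 1] = (np.bincount(self.ev1, ty, minlength=nv)
                          - np.bincount(self.ev2, ty, minlength=nv))
            fpre[:, 0] = (np.bincount(self.ev1, fpx, minlength=nv)
                          + np.bincount(self.ev2, fpx, minlength=nv))
            fpre[:, 1] = (np.bincount(self.ev1, fpy, minlength=nv)
                          + np.bincount(self.ev2, fpy, minlength=nv))
            return ften, fpre, areas
        f = np.zeros((nv, 2))
        f[:, 0] = (np.bincount(self.ev1, tx + fpx, minlength=nv)
                   + np.bincount(self.ev2, fpx - tx, minlength=nv))
        f[:, 1] = (np.bincount(self.ev1, ty + fpy, minlength=nv)
                   + np.bincount(self.ev2, fpy - ty, minlength=nv))
        return f, areas


def relax(tissue: Tissue, params: MechParams, *,
          use_kernel: bool = True) -> tuple[Tissue, int]:
    """Overdamped quasi-static relaxation of vertex positions, in place.

    Explicit Euler steps ``x <- x + eta * F``.  Each vertex's displacement
    per iteration is additionally capped at a fraction of its shortest
    incident edge, which keeps the very short edges created by T1 events
    and division degeneracies from destabilising the update.  A step that
    would invert a cell (nonpositive area) is retried with half the step
    size.  Stops when the maximum per-vertex force falls below
    ``params.relax_tolerance`` or after ``params.max_relax_iters``
    iterations (logged as a warning, never an exception).

    Returns the tissue and the number of iterations used.  ``use_kernel``
    selects the compiled inner loop (numerically identical to the numpy
    path, which remains available for cross-checking).
    """
    arrays = _MeshArrays.from_tissue(tissue)
    if len(arrays.vids) == 0:
        return tissue, 0
    mean_len = float(np.mean(np.hypot(
        *(arrays.pos[arrays.ev2] - arrays.pos[arrays.ev1]).T)))
    if mean_len <= 0:
        return tissue, 0
    eta0 = params.mobility * params.step_fraction * mean_len
    eta_min = 1e-6 * eta0
    k = params.pressure_stiffness
    nv = len(arrays.vids)

    from ._kernels import HAVE_NUMBA, relax_kernel
    if use_kernel and HAVE_NUMBA:
        pos = np.ascontiguousarray(arrays.pos)
        iters, fmax = relax_kernel(
            pos, arrays.ev1, arrays.ev2, arrays.eten, arrays.eleft,
            arrays.eright, arrays.ctarget, arrays.seg_a, arrays.seg_b,
            arrays.seg_cell, k, eta0, params.relax_tolerance,
            params.max_relax_iters)
        if fmax >= params.relax_tolerance:
            logger.warning("relaxation stopped at max force %.3g after %d "
                           "iters", fmax, iters)
        for i, vid in enumerate(arrays.vids):
            tissue.vertices[vid][:] = pos[i]
        return tissue, iters

    pos = arrays.pos
    force, areas = arrays.forces(pos, k)
    fmax = float(np.max(np.hypot(force[:, 0], force[:, 1])))
    eta = eta0
    iters = 0
    while iters < params.max_relax_iters and fmax >= params.relax_tolerance:
        d = pos[arrays.ev2] - pos[arrays.ev1]
        elen = np.hypot(d[:, 0], d[:, 1])
        min_len = np.full(nv, np.inf)
        np.minimum.at(min_len, arrays.ev1, elen)
        np.minimum.at(min_len, arrays.ev2, elen)
        disp = eta * force
        mag = np.hypot(disp[:, 0], disp[:, 1])
        cap = 0.3 * min_len
        scale = np.where(mag > cap, cap / np.maximum(mag, 1e-300), 1.0)
        disp *= scale[:, None]

        trial = pos + disp
        tforce, tareas = arrays.forces(trial, k)
        if np.all(tareas > 0) or eta <= eta_min:
            pos, force = trial, tforce
            fmax = float(np.max(np.hypot(tforce[:, 0], tforce[:, 1])))
            eta = min(eta * 1.2, eta0)
        else:
            eta = max(eta * 0.5, eta_min)
        iters += 1
    if fmax >= params.relax_tolerance:
        logger.warning("relaxation stopped at max force %.3g after %d iters",
                       fmax, iters)
    for i, vid in enumerate(arrays.vids):
        tissue.vertices[vid][:] = pos[i]
    return tissue, iters
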