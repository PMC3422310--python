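"""Discrete topological operators: cell division and T1 neighbor exchange.

Division inserts a new edge through the mother cell along a chosen plane,
splitting the two intersected boundary edges, so each far-side neighbor
gains one side.  A cut falling on an existing vertex is handled by the
degeneracy rule: the cut point is kept a small distance away from the
vertex, leaving a very short edge piece (an "infinitely small" new edge).

A T1 rearrangement removes a short edge shared by two cells and creates a
new short edge, orthogonal to the old one, between the two cells that
previously met only at its endpoints.  The total number of cell sides in
the tissue is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EXTERIOR, Lineage, Tissue, polygon_area


class DivisionError(ValueError):
    """Division plane cannot produce a valid split of the mother cell."""


class T1Refused(ValueError):
    """T1 preconditions not met for the requested edge."""


@dataclass
class DivisionPlane:
    """A division line through ``anchor`` (the mother's mass center) with
    unit ``direction``."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.hypot(*d)
        if n <= 0:
            raise ValueError("plane direction must be nonzero")
        self.direction = d / n

    @property
    def normal(self) -> np.ndarray:
        return np.array([-self.direction[1], self.direction[0]])


@dataclass
class TopoEvent:
    """Append-only log entry for a topological change."""

    kind: str  # "division" | "t1"
    step: int
    cells: tuple[int, ...]
    edges_created: tuple[int, ...] = ()
    edges_removed: tuple[int, ...] = ()
    info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "step": self.step,
                "cells": list(self.cells),
                "edges_created": list(self.edges_created),
                "edges_removed": list(self.edges_removed),
                "info": self.info}


# ----------------------------------------------------------------------
# division
# ----------------------------------------------------------------------

def _chord(points: np.ndarray, anchor: np.ndarray, direction: np.ndarray):
    """Intersection of the line (anchor, direction) with a polygon boundary.

    Returns ``((iA, tA, qA), (iB, tB, qB))``: for each of the two cut
    points, the index of the boundary segment it lies on, the parameter
    along that segment in ``(0, 1)``, and its coordinates.  The chord is the
    one containing the anchor when the line crosses the boundary more than
    twice (non-convex cells).  Returns ``None`` if no bracketing chord
    exists.
    """
    n = np.array([-direction[1], direction[0]])
    s = (points - anchor) @ n
    # nudge exact zeros so every crossing falls strictly inside a segment;
    # the degeneracy clamp below keeps the resulting edge piece finite
    scale = float(np.max(np.abs(s))) or 1.0
    s = np.where(np.abs(s) < 1e-12 * scale, 1e-12 * scale, s)
    k = len(points)
    crossings = []
    for i in range(k):
        s0, s1 = s[i], s[(i + 1) % k]
        if s0 * s1 < 0:
            t = s0 / (s0 - s1)
            q = points[i] + t * (points[(i + 1) % k] - points[i])
            proj = float((q - anchor) @ direction)
            crossings.append((proj, i, t, q))
    if len(crossings) < 2:
        return None
    crossings.sort(key=lambda c: c[0])
    for j in range(len(crossings) - 1):
        if crossings[j][0] <= 0.0 <= crossings[j + 1][0]:
            lo, hi = crossings[j], crossings[j + 1]
            return (hi[1], hi[2], hi[3]), (lo[1], lo[2], lo[3])
    return None


def _cyclic_slice(seq: list, start: int, stop: int) -> list:
    """Elements ``seq[start:stop]`` walking cyclically (empty if start==stop)."""
    n = len(seq)
    out = []
    i = start % n
    while i != stop % n:
        out.append(seq[i])
        i = (i + 1) % n
    return out


def _split_fraction(points: np.ndarray, anchor: np.ndarray,
                    direction: np.ndarray) -> float | None:
    """Area fraction of the daughter on the +normal side of the plane."""
    chord = _chord(points, anchor, direction)
    if chord is None:
        return None
    (ia, _, qa), (ib, _, qb) = chord
    k = len(points)
    chain = [qa] + [points[j % k] for j in
                    range(ia + 1, ia + 1 + ((ib - ia) % k))] + [qb]
    a1 = polygon_area(np.array(chain))
    atot = polygon_area(points)
    return a1 / atot


def divide_cell(tissue: Tissue, cell_id: int, plane: DivisionPlane, *,
                eps_len: float | None = None, step: int = 0,
                area_bounds: tuple[float, float] = (0.35, 0.65),
                ) -> tuple[int, int, TopoEvent]:
    """Divide a cell along ``plane`` into two daughters.

    The plane is the line through the mother's mass center; if the split
    would give either daughter less than ``area_bounds[0]`` of the mother's
    area, the plane is translated along its normal (orientation preserved)
    until the split is balanced.  Each intersected boundary edge is split
    in two, so the far-side neighbor of each gains exactly one side; a new
    edge joins the two cut points.

    Returns ``(daughter_id_1, daughter_id_2, event)``.  Raises
    :class:`DivisionError` when no valid split exists (the caller may defer
    the division one step).
    """
    cell = tissue.cells[cell_id]
    loop_edges = list(cell.edges)
    loop_verts = tissue.cell_vertex_loop(cell_id)
    points = np.array([tissue.vertices[v] for v in loop_verts])
    if eps_len is None:
        eps_len = 1e-3 * tissue.mean_edge_length()

    anchor = plane.anchor.copy()
    frac = _split_fraction(points, anchor, plane.direction)
    if frac is None:
        raise DivisionError(f"plane misses the boundary of cell {cell_id}")
    if not (area_bounds[0] <= frac <= area_bounds[1]):
        anchor = _rebalance_anchor(points, plane, area_bounds)
        if anchor is None:
            raise DivisionError(
                f"cannot balance the area split of cell {cell_id}")

    chord = _chord(points, anchor, plane.direction)
    if chord is None:
        raise DivisionError(f"plane misses the boundary of cell {cell_id}")
    (ia, ta, qa), (ib, tb, qb) = chord
    if ia == ib:
        raise DivisionError(
            f"both cut points fall on the same edge of cell {cell_id}")

    # degeneracy rule: keep each cut point at least eps away from the
    # segment ends, leaving a short new edge instead of a 4-fold junction
    def clamp(i: int, t: float) -> np.ndarray:
        seg_len = float(np.hypot(*(points[(i + 1) % len(points)] - points[i])))
        t_eps = min(eps_len / max(seg_len, 1e-300), 0.49)
        t = min(max(t, t_eps), 1.0 - t_eps)
        return points[i] + t * (points[(i + 1) % len(points)] - points[i])

    qa, qb = clamp(ia, ta), clamp(ib, tb)

    xa = tissue.new_vertex(qa)
    xb = tissue.new_vertex(qb)
    a1, a2 = _split_boundary_edge(tissue, cell_id, loop_edges[ia], xa)
    b1, b2 = _split_boundary_edge(tissue, cell_id, loop_edges[ib], xb)

    mid1 = _cyclic_slice(loop_edges, ia + 1, ib)
    mid2 = _cyclic_slice(loop_edges, ib + 1, ia)
    g = tissue.new_edge(xa, xb, left=-2, right=-2)  # sides fixed below

    d1_edges = [a2] + mid1 + [b1, g]
    d2_edges = [b2] + mid2 + [a1, g]
    d1 = tissue.new_cell(d1_edges,
                         target_size=cell.target_size / 2.0,
                         birth_target=cell.target_size / 2.0,
                         proliferating=cell.proliferating,
                         generation=cell.generation + 1,
                         lineage=cell.lineage.copy())
    d2 = tissue.new_cell(d2_edges,
                         target_size=cell.target_size / 2.0,
                         birth_target=cell.target_size / 2.0,
                         proliferating=cell.proliferating,
                         generation=cell.generation + 1,
                         lineage=cell.lineage.copy())
    # daughter 2 walks the new edge xa -> xb, so it is the left cell
    ge = tissue.edges[g]
    ge.left, ge.right = d2, d1

    for did in (d1, d2):
        for eid in tissue.cells[did].edges:
            e = tissue.edges[eid]
            if e.left == cell_id:
                e.left = did
            elif e.right == cell_id:
                e.right = did
    del tissue.cells[cell_id]

    event = TopoEvent(kind="division", step=step,
                      cells=(cell_id, d1, d2),
                      edges_created=(a1, a2, b1, b2, g),
                      edges_removed=(loop_edges[ia], loop_edges[ib]),
                      info={"direction": [float(plane.direction[0]),
                                          float(plane.direction[1])]})
    return d1, d2, event


def _rebalance_anchor(points: np.ndarray, plane: DivisionPlane,
                      bounds: tuple[float, float]) -> np.ndarray | None:
    """Translate the plane along its normal until the area split is
    balanced (bisection on the offset; the fraction is monotone in it)."""
    n = plane.normal
    proj = (points - plane.anchor) @ n
    lo_off, hi_off = float(proj.min()), float(proj.max())

    def frac_at(off: float) -> float | None:
        return _split_fraction(points, plane.anchor + off * n, plane.direction)

    # the +normal daughter shrinks to 0 near hi_off and grows to 1 near lo_off
    lo, hi = lo_off * 0.999, hi_off * 0.999
    flo, fhi = frac_at(lo), frac_at(hi)
    if flo is None or fhi is None:
        return None
    if flo < fhi:
        lo, hi, flo, fhi = hi, lo, fhi, flo
    target = 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = frac_at(mid)
        if fm is None:
            return None
        if abs(fm - target) < 0.01:
            return plane.anchor + mid * n
        if fm > target:
            lo = mid
        else:
            hi = mid
    fm = frac_at(0.5 * (lo + hi))
    if fm is not None and bounds[0] <= fm <= bounds[1]:
        return plane.anchor + 0.5 * (lo + hi) * n
    return None


def _split_boundary_edge(tissue: Tissue, mother_id: int, eid: int,
                         new_vid: int) -> tuple[int, int]:
    """Split edge ``eid`` at (already created) vertex ``new_vid``.

    Returns the two pieces ``(first, second)`` in the *mother's* traversal
    order.  The far-side neighbor's loop is updated in place (it gains one
    side); the mother's loop is rebuilt by the caller.
    """
    e = tissue.edges[eid]
    p1 = tissue.new_edge(e.v1, new_vid, left=e.left, right=e.right,
                         tension=e.tension)
    p2 = tissue.new_edge(new_vid, e.v2, left=e.left, right=e.right,
                         tension=e.tension)
    neighbor = e.other_cell(mother_id)
    if neighbor != EXTERIOR:
        nloop = tissue.cells[neighbor].edges
        i = nloop.index(eid)
        if tissue.edges[p1].left == neighbor:
            nloop[i:i + 1] = [p1, p2]
        else:
            nloop[i:i + 1] = [p2, p1]
    tissue.remove_edge(eid)
    mother_forward = (e.left == mother_id)
    return (p1, p2) if mother_forward else (p2, p1)


# ----------------------------------------------------------------------
# T1 neighbor exchange
# ----------------------------------------------------------------------

def _partner_edges(tissue: Tissue, vid: int, eid: int,
                   cell_a: int, cell_b: int) -> tuple[int, int, int]:
    """At trivalent vertex ``vid`` of edge ``eid`` (between cells a and b),
    find the other two incident edges and the third cell around the vertex.

    Returns ``(edge_sharing_a, edge_sharing_b, third_cell)``.
    """
    others = [e for e in tissue.vertex_edges(vid) if e != eid]
    if len(others) != 2:
        raise T1Refused(f"vertex {vid} is not trivalent")
    ea = eb = None
    for oe in others:
        cells = set(tissue.edges[oe].cells())
        if cell_a in cells:
            ea = oe
        if cell_b in cells:
            eb = oe
    if ea is None or eb is None or ea == eb:
        raise T1Refused(f"inconsistent corner at vertex {vid}")
    third = set(tissue.edges[ea].cells()) & set(tissue.edges[eb].cells())
    third.discard(cell_a)
    third.discard(cell_b)
    if len(third) != 1:
        raise T1Refused(f"cannot identify the third cell at vertex {vid}")
    return ea, eb, third.pop()


def t1_eligible(tissue: Tissue, edge_id: int) -> bool:
    """Whether a T1 on this edge satisfies all preconditions."""
    try:
        _t1_analyze(tissue, edge_id)
        return True
    except T1Refused:
        return False


def _t1_analyze(tissue: Tissue, edge_id: int):
    e = tissue.edges[edge_id]
    if not e.is_inner:
        raise T1Refused(f"edge {edge_id} is an outer edge")
    ca, cb = e.left, e.right
    ea_u, eb_u, cc = _partner_edges(tissue, e.v1, edge_id, ca, cb)
    ea_w, eb_w, cd = _partner_edges(tissue, e.v2, edge_id, ca, cb)
    if cc == EXTERIOR or cd == EXTERIOR:
        raise T1Refused("T1 would connect a cell to the exterior")
    if cc == cd:
        raise T1Refused("the two gaining cells coincide (shared neighbor)")
    if len(tissue.cells[ca].edges) <= 3 or len(tissue.cells[cb].edges) <= 3:
        raise T1Refused("a losing cell would drop below 3 sides")
    for other in tissue.cells[cc].edges:
        oe = tissue.edges[other]
        if set(oe.cells()) == {cc, cd}:
            raise T1Refused("gaining cells are already adjacent")
    return ca, cb, cc, cd, ea_u, eb_u, ea_w, eb_w


def t1_rearrangement(tissue: Tissue, edge_id: int, *,
                     eps_len: float | None = None,
                     new_len: float | None = None, step: int = 0) -> TopoEvent:
    """Neighbor exchange on an inner edge.

    The edge's two cells lose one side each; the two cells previously
    meeting only at its endpoints gain one side each and become connected
    by a new edge orthogonal to the removed one.  The new junction is
    created at length ``new_len`` (default ``eps_len``); creating it
    slightly longer than the trigger length keeps the exchange from
    reversing immediately on the next step.  Raises :class:`T1Refused`
    when preconditions fail (boundary edge, non-trivalent endpoint,
    shared-neighbor configuration).
    """
    ca, cb, cc, cd, ea_u, eb_u, ea_w, eb_w = _t1_analyze(tissue, edge_id)
    e = tissue.edges[edge_id]
    if eps_len is None:
        eps_len = 1e-3 * tissue.mean_edge_length()
    if new_len is not None:
        eps_len = new_len

    u, w = e.v1, e.v2
    pu, pw = tissue.vertices[u], tissue.vertices[w]
    mid = 0.5 * (pu + pw)
    d = pw - pu
    length = float(np.hypot(*d))
    if length > 0:
        dn = d / length
    else:
        dn = np.array([1.0, 0.0])
    n_left = np.array([-dn[1], dn[0]])  # points into cell A (= e.left)

    # vertex u becomes cell A's corner, w becomes cell B's corner
    tissue.vertices[u][:] = mid + 0.5 * eps_len * n_left
    tissue.vertices[w][:] = mid - 0.5 * eps_len * n_left
    tissue.rewire_edge_endpoint(ea_w, w, u)
    tissue.rewire_edge_endpoint(eb_u, u, w)

    new_eid = tissue.new_edge(u, w, left=cc, right=cd,
                              tension=e.tension)
    tissue.remove_edge(edge_id)

    tissue.cells[ca].edges.remove(edge_id)
    tissue.cells[cb].edges.remove(edge_id)
    _insert_between(tissue, cc, ea_u, eb_u, new_eid)
    _insert_between(tissue, cd, ea_w, eb_w, new_eid)
    _fix_new_edge_orientation(tissue, new_eid, cc, cd)

    return TopoEvent(kind="t1", step=step, cells=(ca, cb, cc, cd),
                     edges_created=(new_eid,), edges_removed=(edge_id,))


def _insert_between(tissue: Tissue, cid: int, e1: int, e2: int,
                    new_eid: int) -> None:
    loop = tissue.cells[cid].edges
    n = len(loop)
    for i in range(n):
        if {loop[i], loop[(i + 1) % n]} == {e1, e2}:
            loop.insert(i + 1, new_eid)
            return
    raise T1Refused(f"edges {e1},{e2} not adjacent in the loop of cell {cid}")


def _fix_new_edge_orientation(tissue: Tissue, eid: int, cc: int, cd: int) -> None:
    """Set left/right of the new edge consistent with cell cc's traversal."""
    e = tissue.edges[eid]
    loop = tissue.cells[cc].edges
    i = loop.index(eid)
    prev = tissue.edges[loop[i - 1]]
    entry = {prev.v1, prev.v2} & {e.v1, e.v2}
    start = entry.pop()
    if start == e.v1:
        e.left, e.right = cc, cd
    else:
        e.left, e.right = cd, cc


# ----------------------------------------------------------------------
# T1 trigger
# ----------------------------------------------------------------------

def detect_t1_candidates(tissue: Tissue, length_threshold: float) -> list[int]:
    """Inner edges shorter than ``length_threshold`` whose T1 preconditions
    hold, sorted by ascending length."""
    import math

    found = []
    verts = tissue.vertices
    for eid, e in tissue.edges.items():
        if not e.is_inner:
            continue
        p, q = verts[e.v1], verts[e.v2]
        length = math.hypot(q[0] - p[0], q[1] - p[1])
        if length < length_threshold and t1_eligible(tissue, eid):
            found.append((length, eid))
    found.sort()
    return [eid for _, eid in found]
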