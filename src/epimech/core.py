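"""Planar polygonal tissue data model.

An epithelial monolayer is represented as a planar, watertight mesh of
polygonal cells.  Cells are bounded by edges; an *inner* edge separates two
cells, an *outer* edge separates a cell from the exterior medium.  Junction
vertices are trivalent in the interior (no more than three cells meet at a
point); vertices on the tissue boundary between two outer edges may be
2-valent.

Coordinates are dimensionless; by convention the initial cell of a
simulation has unit area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Sentinel cell id for the exterior medium on the far side of an outer edge.
EXTERIOR = -1


class TissueStructureError(ValueError):
    """Raised when input geometry cannot form a valid tissue mesh."""


@dataclass
class Lineage:
    """Heritable division state carried by a cell.

    ``last_axis`` is the unit direction of the division plane the cell was
    created by (``None`` before the first division in a lineage);
    ``heritable_type`` is the division scheme a lineage-typed cell passes to
    its daughters; ``all_orthogonal`` tracks whether every ancestral
    division used the orthogonal scheme.
    """

    last_axis: tuple[float, float] | None = None
    heritable_type: str | None = None
    all_orthogonal: bool = True

    def copy(self) -> "Lineage":
        return replace(self)


@dataclass
class Edge:
    id: int
    v1: int
    v2: int
    left: int  # cell id on the left when walking v1 -> v2, or EXTERIOR
    right: int
    tension: float = 1.0

    @property
    def kind(self) -> str:
        return "outer" if EXTERIOR in (self.left, self.right) else "inner"

    @property
    def is_inner(self) -> bool:
        return self.left != EXTERIOR and self.right != EXTERIOR

    def cells(self) -> tuple[int, int]:
        return (self.left, self.right)

    def other_cell(self, cell_id: int) -> int:
        if self.left == cell_id:
            return self.right
        if self.right == cell_id:
            return self.left
        raise KeyError(f"cell {cell_id} is not adjacent to edge {self.id}")

    def other_vertex(self, vid: int) -> int:
        if self.v1 == vid:
            return self.v2
        if self.v2 == vid:
            return self.v1
        raise KeyError(f"vertex {vid} is not an endpoint of edge {self.id}")


@dataclass
class Cell:
    id: int
    edges: list[int]  # cyclically ordered, counter-clockwise
    target_size: float = 1.0
    birth_target: float = 1.0
    proliferating: bool = True
    generation: int = 0
    lineage: Lineage = field(default_factory=Lineage)


class Tissue:
    """Id-indexed collections of vertices, edges and cells.

    The boundary loop of each cell is stored as an ordered edge list; the
    cell is traversed counter-clockwise by walking each edge ``v1 -> v2``
    when the cell is the edge's ``left`` cell and ``v2 -> v1`` otherwise.
    """

    def __init__(self) -> None:
        self.vertices: dict[int, np.ndarray] = {}
        self.edges: dict[int, Edge] = {}
        self.cells: dict[int, Cell] = {}
        self._vertex_edges: dict[int, set[int]] = {}
        self._next_vid = 0
        self._next_eid = 0
        self._next_cid = 0

    # ------------------------------------------------------------------
    # element management
    # ------------------------------------------------------------------
    def new_vertex(self, position: Sequence[float]) -> int:
        vid = self._next_vid
        self._next_vid += 1
        self.vertices[vid] = np.asarray(position, dtype=float).copy()
        self._vertex_edges[vid] = set()
        return vid

    def new_edge(self, v1: int, v2: int, left: int, right: int,
                 tension: float = 1.0) -> int:
        eid = self._next_eid
        self._next_eid += 1
        self.edges[eid] = Edge(eid, v1, v2, left, right, tension)
        self._vertex_edges[v1].add(eid)
        self._vertex_edges[v2].add(eid)
        return eid

    def new_cell(self, edges: list[int], **kwargs) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.cells[cid] = Cell(cid, list(edges), **kwargs)
        return cid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self._vertex_edges[e.v1].discard(eid)
        self._vertex_edges[e.v2].discard(eid)

    def remove_vertex(self, vid: int) -> None:
        if self._vertex_edges.get(vid):
            raise TissueStructureError(f"vertex {vid} still has incident edges")
        self.vertices.pop(vid)
        self._vertex_edges.pop(vid)

    def rewire_edge_endpoint(self, eid: int, old_vid: int, new_vid: int) -> None:
        e = self.edges[eid]
        if e.v1 == old_vid:
            e.v1 = new_vid
        elif e.v2 == old_vid:
            e.v2 = new_vid
        else:
            raise KeyError(f"vertex {old_vid} not on edge {eid}")
        self._vertex_edges[old_vid].discard(eid)
        self._vertex_edges[new_vid].add(eid)

    def vertex_edges(self, vid: int) -> set[int]:
        return self._vertex_edges[vid]

    # ------------------------------------------------------------------
    # geometry queries
    # ------------------------------------------------------------------
    def edge_vector(self, eid: int) -> np.ndarray:
        e = self.edges[eid]
        return self.vertices[e.v2] - self.vertices[e.v1]

    def edge_length(self, eid: int) -> float:
        return float(np.hypot(*self.edge_vector(eid)))

    def mean_edge_length(self, inner_only: bool = False) -> float:
        lengths = [self.edge_length(eid) for eid, e in self.edges.items()
                   if e.is_inner or not inner_only]
        if not lengths:
            return 0.0
        return float(np.mean(lengths))

    def cell_vertex_loop(self, cid: int) -> list[int]:
        """Vertex ids around the cell, counter-clockwise; entry *i* is the
        start vertex of the *i*-th boundary edge in traversal order."""
        cell = self.cells[cid]
        loop = []
        for eid in cell.edges:
            e = self.edges[eid]
            loop.append(e.v1 if e.left == cid else e.v2)
        return loop

    def cell_polygon(self, cid: int) -> np.ndarray:
        return np.array([self.vertices[v] for v in self.cell_vertex_loop(cid)])

    def cell_area(self, cid: int) -> float:
        return polygon_area(self.cell_polygon(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return polygon_centroid(self.cell_polygon(cid))

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    # ------------------------------------------------------------------
    # topology queries
    # ------------------------------------------------------------------
    def neighbors(self, cid: int) -> set[int]:
        """Distinct neighboring cell ids (the exterior is excluded)."""
        cell = self.cells[cid]
        out = set()
        for eid in cell.edges:
            other = self.edges[eid].other_cell(cid)
            if other != EXTERIOR:
                out.add(other)
        return out

    def sidedness(self, cid: int) -> int:
        """Polygon class: the number of distinct neighboring cells."""
        return len(self.neighbors(cid))

    def touches_exterior(self, cid: int) -> bool:
        return any(not self.edges[eid].is_inner for eid in self.cells[cid].edges)

    def interior_cell_ids(self) -> list[int]:
        return [c for c in self.cells if not self.touches_exterior(c)]

    def copy(self) -> "Tissue":
        t = Tissue()
        t.vertices = {v: p.copy() for v, p in self.vertices.items()}
        t.edges = {e: replace(edge) for e, edge in self.edges.items()}
        t.cells = {
            c: Cell(cell.id, list(cell.edges), cell.target_size,
                    cell.birth_target, cell.proliferating, cell.generation,
                    cell.lineage.copy())
            for c, cell in self.cells.items()
        }
        t._vertex_edges = {v: set(s) for v, s in self._vertex_edges.items()}
        t._next_vid = self._next_vid
        t._next_eid = self._next_eid
        t._next_cid = self._next_cid
        return t


# ----------------------------------------------------------------------
# free-standing geometry helpers
# ----------------------------------------------------------------------

def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise loops)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-30:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def sidedness(tissue: Tissue, cell_id: int) -> int:
    """Number of distinct neighboring cells (outer edges do not count)."""
    return tissue.sidedness(cell_id)


# ----------------------------------------------------------------------
# construction from polygon soup
# ----------------------------------------------------------------------

def build_tissue(cell_polygon_list: Iterable[Sequence[Sequence[float]]],
                 *, merge_tol: float | None = None,
                 four_fold: str = "resolve") -> Tissue:
    """Assemble a :class:`Tissue` from a list of coordinate loops.

    Polygons must tile a simply connected region; borders shared between two
    polygons must coincide within ``merge_tol`` (default ``1e-9`` times the
    bounding-box diagonal).  Shared borders are merged into single inner
    edges and coincident corners deduplicated.

    ``four_fold`` controls junctions where four edges meet: ``"resolve"``
    splits them into two trivalent junctions joined by a short edge,
    ``"keep"`` stores them as-is (flagged by :func:`validate`), ``"error"``
    raises.
    """
    polys = [np.asarray(p, dtype=float) for p in cell_polygon_list]
    if not polys:
        raise TissueStructureError("no polygons supplied")
    allpts = np.vstack(polys)
    if not np.all(np.isfinite(allpts)):
        raise TissueStructureError("non-finite coordinates")
    diag = float(np.hypot(*(allpts.max(axis=0) - allpts.min(axis=0))))
    tol = merge_tol if merge_tol is not None else max(1e-9 * diag, 1e-300)

    tissue = Tissue()
    grid: dict[tuple[int, int], int] = {}

    def vertex_for(pt: np.ndarray) -> int:
        gx, gy = int(math.floor(pt[0] / tol)), int(math.floor(pt[1] / tol))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                vid = grid.get((gx + dx, gy + dy))
                if vid is not None and np.hypot(*(tissue.vertices[vid] - pt)) <= tol:
                    return vid
        vid = tissue.new_vertex(pt)
        grid[(gx, gy)] = vid
        return vid

    edge_by_pair: dict[tuple[int, int], int] = {}
    pending: list[tuple[int, list[tuple[int, int]]]] = []

    for poly in polys:
        if polygon_area(poly) < 0:
            poly = poly[::-1]
        vids = []
        for pt in poly:
            vid = vertex_for(pt)
            if not vids or vid != vids[-1]:
                vids.append(vid)
        if len(vids) > 1 and vids[0] == vids[-1]:
            vids.pop()
        if len(vids) < 3:
            raise TissueStructureError("degenerate polygon (fewer than 3 corners)")
        cid = tissue.new_cell([])
        segs = [(vids[i], vids[(i + 1) % len(vids)]) for i in range(len(vids))]
        pending.append((cid, segs))

    for cid, segs in pending:
        edge_ids = []
        for a, b in segs:
            key = (min(a, b), max(a, b))
            eid = edge_by_pair.get(key)
            if eid is None:
                eid = tissue.new_edge(a, b, left=cid, right=EXTERIOR)
                edge_by_pair[key] = eid
            else:
                e = tissue.edges[eid]
                if e.right != EXTERIOR:
                    raise TissueStructureError(
                        f"edge between vertices {a},{b} borders more than two polygons")
                if (e.v1, e.v2) == (a, b):
                    raise TissueStructureError(
                        f"inconsistent winding: edge {a}->{b} traversed twice "
                        "in the same direction (overlapping polygons?)")
                e.right = cid
            edge_ids.append(eid)
        tissue.cells[cid].edges = edge_ids

    for cid in tissue.cells:
        a = tissue.cell_area(cid)
        if a <= 0:
            raise TissueStructureError(f"cell {cid} has nonpositive area")
        tissue.cells[cid].target_size = a
        tissue.cells[cid].birth_target = a

    high = [v for v, es in tissue._vertex_edges.items() if len(es) > 3]
    if high:
        if four_fold == "error":
            raise TissueStructureError(f"junctions of valence > 3 at vertices {high}")
        if four_fold == "resolve":
            eps = 1e-3 * tissue.mean_edge_length()
            for vid in high:
                _resolve_four_fold(tissue, vid, eps)
        elif four_fold != "keep":
            raise ValueError(f"unknown four_fold mode {four_fold!r}")
    return tissue


def _edge_angle_at(tissue: Tissue, eid: int, vid: int) -> float:
    e = tissue.edges[eid]
    other = e.other_vertex(vid)
    d = tissue.vertices[other] - tissue.vertices[vid]
    return math.atan2(d[1], d[0])


def _cell_between(tissue: Tissue, e1: int, e2: int) -> int:
    """The cell shared by two edges (EXTERIOR if their shared side is outside)."""
    c1 = set(tissue.edges[e1].cells())
    c2 = set(tissue.edges[e2].cells())
    common = (c1 & c2) - {EXTERIOR}
    if len(common) == 1:
        return common.pop()
    if EXTERIOR in c1 and EXTERIOR in c2:
        return EXTERIOR
    raise TissueStructureError(f"edges {e1},{e2} share {len(common)} cells")


def _resolve_four_fold(tissue: Tissue, vid: int, eps: float) -> None:
    """Split a 4-valent junction into two trivalent junctions joined by a
    short edge (mirrors the degeneracy rule used at division)."""
    eids = sorted(tissue.vertex_edges(vid))
    if len(eids) != 4:
        raise TissueStructureError(
            f"cannot resolve junction of valence {len(eids)} at vertex {vid}")
    eids.sort(key=lambda e: _edge_angle_at(tissue, e, vid))
    e0, e1, e2, e3 = eids
    # pair (e0,e1) stays on one new vertex, (e2,e3) on the other; the new
    # edge separates the cell between e1,e2 from the cell between e3,e0
    c_a = _cell_between(tissue, e0, e1)
    c_b = _cell_between(tissue, e2, e3)
    c_left = _cell_between(tissue, e1, e2)
    c_right = _cell_between(tissue, e3, e0)
    if c_left == c_right:
        raise TissueStructureError(
            f"cannot split junction at vertex {vid}: single surrounding cell")
    pos = tissue.vertices[vid]
    # displacement direction: bisector of the (e0,e1) pair of edge directions
    ang_a = _bisector(_edge_angle_at(tissue, e0, vid), _edge_angle_at(tissue, e1, vid))
    dir_a = np.array([math.cos(ang_a), math.sin(ang_a)])
    va = tissue.new_vertex(pos + 0.5 * eps * dir_a)
    vb = tissue.new_vertex(pos - 0.5 * eps * dir_a)
    for eid in (e0, e1):
        tissue.rewire_edge_endpoint(eid, vid, va)
    for eid in (e2, e3):
        tissue.rewire_edge_endpoint(eid, vid, vb)
    # orientation: walking va -> vb has c_left on the left iff the loop of
    # c_left traverses vb -> va ... determined below by loop insertion.
    new_eid = tissue.new_edge(va, vb, left=c_left, right=c_right)
    for cid, pair in ((c_left, (e1, e2)), (c_right, (e3, e0))):
        if cid == EXTERIOR:
            continue
        _insert_edge_between(tissue, cid, pair, new_eid)
    _orient_edge_to_loops(tissue, new_eid)
    tissue.remove_vertex(vid)


def _bisector(a1: float, a2: float) -> float:
    return math.atan2(math.sin(a1) + math.sin(a2), math.cos(a1) + math.cos(a2))


def _insert_edge_between(tissue: Tissue, cid: int, pair: tuple[int, int],
                         new_eid: int) -> None:
    """Insert ``new_eid`` into the cell's edge loop between the two edges of
    ``pair`` (which must be cyclically adjacent in the loop)."""
    loop = tissue.cells[cid].edges
    n = len(loop)
    for i in range(n):
        a, b = loop[i], loop[(i + 1) % n]
        if {a, b} == set(pair):
            loop.insert(i + 1, new_eid)
            return
    raise TissueStructureError(
        f"edges {pair} are not adjacent in the loop of cell {cid}")


def _orient_edge_to_loops(tissue: Tissue, eid: int) -> None:
    """Fix (v1,v2)/(left,right) of an edge so the stored left cell really
    lies on the left of the v1->v2 walk, per its cells' loop traversal."""
    e = tissue.edges[eid]
    cid = e.left if e.left != EXTERIOR else e.right
    cell = tissue.cells[cid]
    i = cell.edges.index(eid)
    prev = tissue.edges[cell.edges[i - 1]]
    # traversal of the loop enters `eid` at the vertex shared with `prev`
    entry = {prev.v1, prev.v2} & {e.v1, e.v2}
    if not entry:
        raise TissueStructureError(f"loop of cell {cid} is not consecutive at edge {eid}")
    start = entry.pop()
    forward = (start == e.v1)
    if (cid == e.left) != forward:
        e.left, e.right = e.right, e.left


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate(tissue: Tissue) -> list[str]:
    """Diagnostics report: one string per invariant violation (empty iff valid).

    Checks referential integrity, loop consecutiveness and orientation,
    watertightness (each inner edge in exactly the loops of its two cells),
    junction valence, and positive areas.  Reports, never raises.
    """
    report: list[str] = []
    edge_loop_refs: dict[int, list[int]] = {e: [] for e in tissue.edges}

    for vid, pos in tissue.vertices.items():
        if not np.all(np.isfinite(pos)):
            report.append(f"vertex {vid}: non-finite position")

    for eid, e in tissue.edges.items():
        for vid in (e.v1, e.v2):
            if vid not in tissue.vertices:
                report.append(f"edge {eid}: missing endpoint vertex {vid}")
        for cid in e.cells():
            if cid != EXTERIOR and cid not in tissue.cells:
                report.append(f"edge {eid}: missing cell {cid}")
        if e.left == e.right:
            report.append(f"edge {eid}: identical cells on both sides")
        if e.left == EXTERIOR:
            report.append(f"edge {eid}: exterior stored on the left")

    for cid, cell in tissue.cells.items():
        if len(cell.edges) < 2:
            report.append(f"cell {cid}: fewer than 2 boundary edges")
            continue
        if len(set(cell.edges)) != len(cell.edges):
            report.append(f"cell {cid}: repeated edge in boundary loop")
        ok = True
        for eid in cell.edges:
            e = tissue.edges.get(eid)
            if e is None:
                report.append(f"cell {cid}: missing edge {eid}")
                ok = False
                continue
            edge_loop_refs[eid].append(cid)
            if cid not in e.cells():
                report.append(f"cell {cid}: edge {eid} does not list it as a side")
                ok = False
        if not ok:
            continue
        loop = tissue.cell_vertex_loop(cid)
        n = len(loop)
        for i, eid in enumerate(cell.edges):
            e = tissue.edges[eid]
            end = e.v2 if e.left == cid else e.v1
            if end != loop[(i + 1) % n]:
                report.append(f"cell {cid}: boundary loop not consecutive at edge {eid}")
                break
        area = tissue.cell_area(cid)
        if area <= 0:
            report.append(f"cell {cid}: nonpositive area {area:.3g}")

    for eid, refs in edge_loop_refs.items():
        e = tissue.edges[eid]
        expected = sorted(c for c in e.cells() if c != EXTERIOR)
        if sorted(refs) != expected:
            report.append(
                f"edge {eid}: watertightness violated "
                f"(listed by cells {sorted(refs)}, sides are {expected})")

    for vid, eids in tissue._vertex_edges.items():
        if len(eids) > 3:
            report.append(f"vertex {vid}: {len(eids)} edges meet (max 3)")
        elif len(eids) == 2:
            if all(tissue.edges[e].is_inner for e in eids):
                report.append(f"vertex {vid}: interior vertex with only 2 edges")
        elif len(eids) < 2 and vid in tissue.vertices:
            report.append(f"vertex {vid}: dangling vertex ({len(eids)} edges)")

    return report
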