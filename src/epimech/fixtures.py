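"""Synthetic starting tissues.

Generators for the initial conditions used throughout: a single isolated
cell (a regular polygon standing in for a disk), regular hexagonal
honeycomb patches, and centroidally relaxed Voronoi tessellations that
mimic a relaxed epithelium.  All fixtures use the convention that a cell
has unit area on average.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Voronoi

from .core import Tissue, build_tissue

#: side length of a unit-area regular hexagon
_HEX_SIDE = math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))


def single_cell(n_sides: int = 12, area: float = 1.0) -> Tissue:
    """One isolated cell: a regular ``n_sides``-gon of the given area.

    The isolated cell is physically a disk; a regular 12-gon approximates
    it while keeping the mesh purely polygonal.
    """
    r = math.sqrt(2.0 * area / (n_sides * math.sin(2.0 * math.pi / n_sides)))
    ang = np.linspace(0.0, 2.0 * math.pi, n_sides, endpoint=False)
    poly = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return build_tissue([poly])


def _hex_spiral(n: int) -> list[tuple[int, int]]:
    """First ``n`` axial coordinates of a hexagonal spiral around (0,0)."""
    out = [(0, 0)]
    ring = 0
    directions = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    while len(out) < n:
        ring += 1
        q, r = 0, -ring  # southern corner of the ring
        for d in directions:
            for _ in range(ring):
                if len(out) >= n:
                    return out
                out.append((q, r))
                q, r = q + d[0], r + d[1]
    return out[:n]


def honeycomb(n_cells: int) -> Tissue:
    """Hexagonal honeycomb patch of ``n_cells`` unit-area cells, laid out in
    a spiral of concentric rings (so the patch stays simply connected)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    s = _HEX_SIDE
    corners = np.array([
        (s * math.cos(math.pi / 6 + k * math.pi / 3),
         s * math.sin(math.pi / 6 + k * math.pi / 3))
        for k in range(6)
    ])
    polys = []
    for q, r in _hex_spiral(n_cells):
        cx = s * math.sqrt(3.0) * (q + r / 2.0)
        cy = s * 1.5 * r
        polys.append(corners + (cx, cy))
    return build_tissue(polys)


def voronoi_tissue(n_cells: int, seed: int = 0, lloyd_iters: int = 4) -> Tissue:
    """Centroidally relaxed Voronoi tessellation of ``n_cells`` cells.

    Random seeds are scattered in a disk, relaxed by a few Lloyd iterations
    (clipping regions to the disk), and the ``n_cells`` finite regions
    nearest the origin are assembled into a tissue.  Mean cell area is
    approximately 1.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells < 3:
        # Voronoi needs a few points; tiny requests fall back to honeycomb
        return honeycomb(n_cells)
    rng = np.random.default_rng(seed)
    m = max(int(3.0 * n_cells), n_cells + 30)
    radius = math.sqrt(m / math.pi)
    rr = radius * np.sqrt(rng.random(m))
    th = rng.uniform(0, 2 * math.pi, m)
    pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])

    import shapely.geometry as geom

    disk = geom.Point(0, 0).buffer(radius, quad_segs=64)
    for _ in range(lloyd_iters):
        vor = Voronoi(pts)
        new_pts = pts.copy()
        for i, reg_idx in enumerate(vor.point_region):
            reg = vor.regions[reg_idx]
            if -1 in reg or not reg:
                continue
            poly = geom.Polygon(vor.vertices[reg]).intersection(disk)
            if not poly.is_empty:
                new_pts[i] = np.asarray(poly.centroid.coords[0])
        pts = new_pts

    vor = Voronoi(pts)
    finite = []
    for i, reg_idx in enumerate(vor.point_region):
        reg = vor.regions[reg_idx]
        if -1 in reg or not reg:
            continue
        verts = vor.vertices[reg]
        if np.all(np.hypot(verts[:, 0], verts[:, 1]) < radius - 1e-9):
            finite.append((float(np.hypot(*pts[i])), i, reg))
    finite.sort()
    if len(finite) < n_cells:
        raise ValueError(
            f"could only form {len(finite)} interior Voronoi cells; "
            f"requested {n_cells}")
    polys = [vor.vertices[reg] for _, _, reg in finite[:n_cells]]
    return build_tissue(polys)


def generate_fixture(n_cells: int, seed: int = 0, kind: str = "voronoi") -> Tissue:
    """Synthetic starting tissue of ``n_cells`` cells.

    ``kind`` is ``"honeycomb"`` (regular hexagonal patch), ``"voronoi"``
    (centroidally relaxed random tessellation) or ``"single"`` (one
    regular-polygon cell; ``n_cells`` must be 1).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if kind == "honeycomb":
        return honeycomb(n_cells)
    if kind == "voronoi":
        return voronoi_tissue(n_cells, seed=seed)
    if kind == "single":
        if n_cells != 1:
            raise ValueError("kind='single' requires n_cells == 1")
        return single_cell()
    raise ValueError(f"unknown fixture kind {kind!r}")
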