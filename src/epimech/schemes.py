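"""Division-plane orientation policies and cell-memory mixing strategies.

Three orientation schemes are supported for a dividing cell:

* ``random`` — the plane direction is uniform on [0, pi), through the mass
  center; a control in which orientation carries no information.
* ``largest_side`` — the plane passes through the midpoint of the cell's
  longest edge and the mass center, splitting the largest side.
* ``orthogonal`` — the plane is the mother's last division axis rotated by
  90 degrees (the first division in a lineage uses a random axis); this
  scheme requires heritable "memory" of the previous axis.

Two mixing strategies combine orthogonal with largest-side division:
``probabilistic_mix`` draws the scheme independently at every division
(orthogonal with probability ``p_orthogonal``), while ``lineage_typed``
assigns each founding cell a heritable type that all its descendants keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Cell, Tissue
from .topology import DivisionPlane

ORIENTATION_SCHEMES = ("random", "largest_side", "orthogonal")
MODES = ORIENTATION_SCHEMES + ("probabilistic_mix", "lineage_typed")


@dataclass
class SchemePolicy:
    """Per-run division policy.

    ``mode`` is one of the three pure orientation schemes or a mixing
    strategy; ``p_orthogonal`` is the orthogonal probability under
    ``probabilistic_mix``; ``initial_type_assignment`` maps founding cell
    ids to heritable types under ``lineage_typed``.
    """

    mode: str = "largest_side"
    p_orthogonal: float = 0.5
    initial_type_assignment: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if not 0.0 <= self.p_orthogonal <= 1.0:
            raise ValueError("p_orthogonal must lie in [0, 1]")


def pick_scheme(cell: Cell, policy: SchemePolicy,
                rng: np.random.Generator) -> str:
    """Orientation scheme used for this division of this cell.

    Under ``probabilistic_mix`` the scheme is drawn independently at each
    division; under ``lineage_typed`` it is the cell's heritable type.
    Pure-scheme policies return the mode itself.
    """
    if policy.mode in ORIENTATION_SCHEMES:
        return policy.mode
    if policy.mode == "probabilistic_mix":
        return ("orthogonal" if rng.random() < policy.p_orthogonal
                else "largest_side")
    # lineage_typed
    if cell.lineage.heritable_type is None:
        raise ValueError(
            f"cell {cell.id} has no heritable type under lineage_typed policy")
    return cell.lineage.heritable_type


def choose_plane(tissue: Tissue, cell_id: int, scheme: str,
                 rng: np.random.Generator) -> DivisionPlane:
    """Division plane for a mitotic cell under a pure orientation scheme.

    The plane is always anchored at the cell's mass center.
    """
    cell = tissue.cells[cell_id]
    centroid = tissue.cell_centroid(cell_id)
    if tissue.cell_area(cell_id) <= 0:
        raise ValueError(f"cell {cell_id} has nonpositive area")

    if scheme == "random":
        theta = rng.uniform(0.0, np.pi)
        return DivisionPlane(centroid, (np.cos(theta), np.sin(theta)))

    if scheme == "largest_side":
        best = None
        for eid in cell.edges:
            length = tissue.edge_length(eid)
            # ties broken by lowest edge id for determinism
            key = (-length, eid)
            if best is None or key < best[0]:
                best = (key, eid)
        eid = best[1]
        e = tissue.edges[eid]
        mid = 0.5 * (tissue.vertices[e.v1] + tissue.vertices[e.v2])
        d = mid - centroid
        if np.hypot(*d) < 1e-12:
            theta = rng.uniform(0.0, np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
        return DivisionPlane(centroid, d)

    if scheme == "orthogonal":
        axis = cell.lineage.last_axis
        if axis is None:
            theta = rng.uniform(0.0, np.pi)
            return DivisionPlane(centroid, (np.cos(theta), np.sin(theta)))
        return DivisionPlane(centroid, (-axis[1], axis[0]))

    raise ValueError(f"unknown orientation scheme {scheme!r}")


def record_division(daughters: tuple[Cell, Cell], plane: DivisionPlane,
                    scheme_used: str, mother_all_orthogonal: bool) -> None:
    """Write heritable state onto the daughters after a division."""
    axis = (float(plane.direction[0]), float(plane.direction[1]))
    for d in daughters:
        d.lineage.last_axis = axis
        d.lineage.all_orthogonal = (mother_all_orthogonal
                                    and scheme_used == "orthogonal")
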