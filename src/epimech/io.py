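"""Serialization: tissue documents (JSON), event logs (JSON lines),
summary tables (CSV) and SVG snapshots."""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO

import numpy as np

from .core import EXTERIOR, Lineage, Tissue, validate
from .topology import TopoEvent

FORMAT_VERSION = 1

#: polygon fill colors by sidedness for SVG snapshots
_CLASS_COLORS = {3: "#c6dbef", 4: "#74c476", 5: "#fdae6b", 6: "#d62bb0",
                 7: "#6baed6", 8: "#3182bd", 9: "#08519c"}


class TissueFormatError(ValueError):
    """Raised on malformed or inconsistent tissue documents."""


def tissue_to_document(tissue: Tissue) -> dict:
    """Serializable document for a tissue (lossless round trip)."""
    return {
        "format_version": FORMAT_VERSION,
        "vertices": [{"id": vid, "x": float(p[0]), "y": float(p[1])}
                     for vid, p in sorted(tissue.vertices.items())],
        "edges": [{"id": e.id, "v1": e.v1, "v2": e.v2, "left": e.left,
                   "right": e.right, "kind": e.kind,
                   "tension": float(e.tension)}
                  for _, e in sorted(tissue.edges.items())],
        "cells": [{"id": c.id, "edge_loop": list(c.edges),
                   "target_size": float(c.target_size),
                   "birth_target": float(c.birth_target),
                   "class": "proliferating" if c.proliferating else "quiescent",
                   "generation": c.generation,
                   "lineage": {
                       "last_axis": (list(c.lineage.last_axis)
                                     if c.lineage.last_axis is not None
                                     else None),
                       "heritable_type": c.lineage.heritable_type,
                       "all_orthogonal": c.lineage.all_orthogonal,
                   }}
                  for _, c in sorted(tissue.cells.items())],
    }


def document_to_tissue(doc: dict) -> Tissue:
    """Rebuild a tissue from a document; validates before returning."""
    try:
        version = doc["format_version"]
        if version != FORMAT_VERSION:
            raise TissueFormatError(f"unsupported format version {version}")
        tissue = Tissue()
        for v in doc["vertices"]:
            tissue.vertices[v["id"]] = np.array([v["x"], v["y"]], dtype=float)
            tissue._vertex_edges[v["id"]] = set()
        for e in doc["edges"]:
            from .core import Edge
            edge = Edge(e["id"], e["v1"], e["v2"], e["left"], e["right"],
                        e.get("tension", 1.0))
            for vid in (edge.v1, edge.v2):
                if vid not in tissue.vertices:
                    raise TissueFormatError(
                        f"edge {edge.id}: dangling vertex id {vid}")
                tissue._vertex_edges[vid].add(edge.id)
            tissue.edges[edge.id] = edge
        for c in doc["cells"]:
            lin = c.get("lineage", {})
            axis = lin.get("last_axis")
            from .core import Cell
            cell = Cell(c["id"], list(c["edge_loop"]),
                        target_size=c["target_size"],
                        birth_target=c.get("birth_target", c["target_size"]),
                        proliferating=(c.get("class", "proliferating")
                                       == "proliferating"),
                        generation=c.get("generation", 0),
                        lineage=Lineage(
                            last_axis=tuple(axis) if axis else None,
                            heritable_type=lin.get("heritable_type"),
                            all_orthogonal=lin.get("all_orthogonal", True)))
            for eid in cell.edges:
                if eid not in tissue.edges:
                    raise TissueFormatError(
                        f"cell {cell.id}: dangling edge id {eid}")
            tissue.cells[cell.id] = cell
        tissue._next_vid = max(tissue.vertices, default=-1) + 1
        tissue._next_eid = max(tissue.edges, default=-1) + 1
        tissue._next_cid = max(tissue.cells, default=-1) + 1
    except KeyError as exc:
        raise TissueFormatError(f"missing field {exc}") from exc
    report = validate(tissue)
    if report:
        raise TissueFormatError(
            f"document describes an invalid tissue: {report[:3]}")
    return tissue


def save_tissue(tissue: Tissue, destination: str | Path | IO[str]) -> dict:
    """Write a tissue document as JSON; returns the document."""
    doc = tissue_to_document(tissue)
    if hasattr(destination, "write"):
        json.dump(doc, destination)
    else:
        Path(destination).write_text(json.dumps(doc))
    return doc


def load_tissue(source: str | Path | IO[str]) -> Tissue:
    """Load and validate a tissue document (JSON)."""
    try:
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            doc = json.loads(Path(source).read_text())
    except json.JSONDecodeError as exc:
        raise TissueFormatError(f"not valid JSON: {exc}") from exc
    return document_to_tissue(doc)


def save_events(events: list[TopoEvent], destination: str | Path) -> None:
    """Write a topological event log as JSON lines."""
    with open(destination, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


def tissue_to_svg(tissue: Tissue, destination: str | Path | None = None,
                  width: int = 800) -> str:
    """Static SVG snapshot with cells filled by polygon class."""
    pts = np.array(list(tissue.vertices.values()))
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = float(max(hi - lo)) or 1.0
    scale = (width - 20) / span

    def xy(p):
        return (10 + (p[0] - lo[0]) * scale, 10 + (hi[1] - p[1]) * scale)

    height = int(20 + (hi[1] - lo[1]) * scale)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}">']
    for cid in tissue.cells:
        poly = tissue.cell_polygon(cid)
        k = tissue.sidedness(cid)
        color = _CLASS_COLORS.get(k, "#bdbdbd")
        coords = " ".join(f"{x:.2f},{y:.2f}" for x, y in map(xy, poly))
        parts.append(f'<polygon points="{coords}" fill="{color}" '
                     f'stroke="black" stroke-width="0.5"/>')
    parts.append("</svg>")
    svg = "\n".join(parts)
    if destination is not None:
        Path(destination).write_text(svg)
    return svg
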