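"""Compiled inner loop for quasi-static relaxation.

The relaxation loop evaluates tension and pressure forces on every vertex
many thousand times per simulation; this module provides a numba-compiled
kernel for it.  The kernel is numerically identical to the pure-numpy path
in :mod:`epimech.mechanics` (asserted in the test suite); if numba is
unavailable the caller falls back to the numpy implementation.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _forces_into(pos, ev1, ev2, eten, eleft, eright, ctarget,
                 seg_a, seg_b, seg_cell, stiffness, force, areas):
    """Accumulate net vertex forces and cell areas at ``pos`` in place.

    Returns the maximum per-vertex force magnitude.
    """
    nc = ctarget.shape[0]
    ne = ev1.shape[0]
    nv = pos.shape[0]

    for c in range(nc):
        areas[c] = 0.0
    for s in range(seg_a.shape[0]):
        a = seg_a[s]
        b = seg_b[s]
        areas[seg_cell[s]] += 0.5 * (pos[a, 0] * pos[b, 1]
                                     - pos[a, 1] * pos[b, 0])

    for v in range(nv):
        force[v, 0] = 0.0
        force[v, 1] = 0.0

    for e in range(ne):
        i, j = ev1[e], ev2[e]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        length = (dx * dx + dy * dy) ** 0.5
        safe = length if length > 1e-12 else 1e-12
        ux, uy = dx / safe, dy / safe

        pl = 0.0
        if eleft[e] >= 0:
            c = eleft[e]
            pl = stiffness * (ctarget[c] - areas[c]) / areas[c]
        pr = 0.0
        if eright[e] >= 0:
            c = eright[e]
            pr = stiffness * (ctarget[c] - areas[c]) / areas[c]
        half = 0.5 * (pl - pr) * length
        fpx, fpy = half * uy, -half * ux

        tx, ty = eten[e] * ux, eten[e] * uy
        force[i, 0] += tx + fpx
        force[i, 1] += ty + fpy
        force[j, 0] += fpx - tx
        force[j, 1] += fpy - ty

    fmax = 0.0
    for v in range(nv):
        m = (force[v, 0] ** 2 + force[v, 1] ** 2) ** 0.5
        if m > fmax:
            fmax = m
    return fmax


@njit(cache=True)
def relax_kernel(pos, ev1, ev2, eten, eleft, eright, ctarget,
                 seg_a, seg_b, seg_cell, stiffness,
                 eta0, tol, max_iters):
    """Overdamped relaxation on flat mesh arrays; mutates ``pos``.

    Explicit Euler with a per-vertex displacement cap of 0.3 times the
    shortest incident edge; a step that would invert a cell is retried at
    half step.  Returns ``(iterations, final_max_force)``.
    """
    nv = pos.shape[0]
    ne = ev1.shape[0]
    nc = ctarget.shape[0]
    force = np.empty((nv, 2))
    areas = np.empty(nc)
    trial = np.empty((nv, 2))
    tareas = np.empty(nc)
    min_len = np.empty(nv)
    eta = eta0
    eta_min = 1e-6 * eta0

    fmax = _forces_into(pos, ev1, ev2, eten, eleft, eright, ctarget,
                        seg_a, seg_b, seg_cell, stiffness, force, areas)
    iters = 0
    while iters < max_iters and fmax >= tol:
        for v in range(nv):
            min_len[v] = np.inf
        for e in range(ne):
            i, j = ev1[e], ev2[e]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            length = (dx * dx + dy * dy) ** 0.5
            if length < min_len[i]:
                min_len[i] = length
            if length < min_len[j]:
                min_len[j] = length

        for v in range(nv):
            dx = eta * force[v, 0]
            dy = eta * force[v, 1]
            mag = (dx * dx + dy * dy) ** 0.5
            cap = 0.3 * min_len[v]
            if mag > cap and mag > 0.0:
                s = cap / mag
                dx *= s
                dy *= s
            trial[v, 0] = pos[v, 0] + dx
            trial[v, 1] = pos[v, 1] + dy

        for c in range(nc):
            tareas[c] = 0.0
        for s in range(seg_a.shape[0]):
            a = seg_a[s]
            b = seg_b[s]
            tareas[seg_cell[s]] += 0.5 * (trial[a, 0] * trial[b, 1]
                                          - trial[a, 1] * trial[b, 0])
        inverted = False
        for c in range(nc):
            if tareas[c] <= 0.0:
                inverted = True
                break

        if inverted and eta > eta_min:
            eta = eta * 0.5
            if eta < eta_min:
                eta = eta_min
        else:
            for v in range(nv):
                pos[v, 0] = trial[v, 0]
                pos[v, 1] = trial[v, 1]
            fmax = _forces_into(pos, ev1, ev2, eten, eleft, eright, ctarget,
                                seg_a, seg_b, seg_cell, stiffness,
                                force, areas)
            eta = eta * 1.2
            if eta > eta0:
                eta = eta0
        iters += 1
    return iters, fmax
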