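# Methods

## The model

An epithelial monolayer is a planar, watertight mesh of polygonal cells.
Cells meet along straight *inner edges*; the tissue rim is made of *outer
edges* separating boundary cells from the exterior medium.  Junctions are
trivalent in the interior — no more than three cells meet at a point — so
by Euler's relation for planar tilings the mean number of neighbors of an
interior cell is six.  A cell's *sidedness* (polygon class) is its number
of distinct neighboring cells; outer edges do not count.

Two forces act on the mesh and are applied at junction vertices:

* **Line tension.**  Each edge pulls its two endpoints together with a
  constant-magnitude force equal to its tension coefficient γ (default 1,
  dimensionless).  The coefficient depends only on the classes of the two
  cells flanking the edge (γ_pp, γ_qq, γ_pq for
  proliferating/proliferating, quiescent/quiescent and mixed pairs) and a
  separate boundary coefficient for outer edges.  Tension is tangential to
  the edge; the force pair sums to zero.
* **Pressure.**  Each cell carries a pressure
  `p = K (A_t − A) / A`, where `A` is its polygon area and `A_t` its
  target size (the "volume" that grows during the cell cycle).  The law is
  gas-like: zero at target, divergent under compression, bounded below by
  −K under stretch.  The net pressure force on an edge is
  `(p_left − p_right) · length`, normal to the edge, directed from the
  higher-pressure side to the lower, split equally between its endpoints.
  The exterior has pressure 0.

We chose the non-saturating `1/A` form after finding that a saturating
elastic law (`p = K (A_t − A)/A_t`) admits no workable stiffness: because
its pressure is bounded by K, any K soft enough to produce realistic
neighbor-exchange rates lets the rim tension crush cells to zero area,
while stiffer values freeze the tissue into an over-ordered state.  The
default `K = 2` was calibrated so that the simulated number of T1
exchanges per division under *random* plane orientation matches the
reported average for that scheme (≈0.11 per division); the hexagon
frequencies below are predictions, not fits.

Dynamics are quasi-static: between topological events, vertices follow
overdamped gradient descent `x ← x + η F` until the largest per-vertex
force drops below `relax_tolerance = 1e-3` or 500 iterations are spent.
The base step is `η = 0.05 ×` mean edge length per unit force.  Two
safeguards stabilize the explicit update: each vertex's displacement per
iteration is capped at 0.3 of its shortest incident edge (very short edges
appear transiently around T1 events and division degeneracies), and a step
that would invert a cell is retried at half step size.  The relaxation
inner loop has a compiled (numba) and a pure-numpy implementation; they
are numerically identical and the test suite asserts so.

## Growth, division, rearrangement

Each engine step: (1) every proliferating cell's target size is multiplied
by `1 + u`, `u ~ Uniform[0.01, 0.08]` drawn independently per cell
(quiescent cells have zero growth rate); (2) relax; (3) divisions;
(4) relax; (5) T1 exchanges; (6) relax.  With this growth range a cell
doubles its target in `log 2 / E[log(1+u)] ≈ 16` steps, so ≈17 steps form
one round of division.

**Division trigger.**  A cell divides once its target size reaches twice
its target at birth and its realized area has kept up with its target
(area/target at least 0.8 of the tissue median of that ratio — an
absolute threshold would permanently block small isolated tissues, where
rim tension holds all cells below target).  Eligible cells divide in
seeded-random order within the step.

**Division geometry.**  The division plane passes through the mother's
mass center with a direction set by the orientation scheme.  The two
boundary edges it crosses are each split at the crossing point, so the
far-side neighbor of each gains exactly one side; a new edge joins the two
cut points, and each daughter receives half the mother's target size.  If
a split would give a daughter less than 35% of the area, the plane is
translated along its normal (orientation preserved) to rebalance.  A cut
falling within ε = 1e-3 × mean edge length of an existing vertex is kept ε
away from it, leaving a very short edge piece — the degeneracy rule that
avoids four-fold junctions.  Four-fold junctions in *input* meshes are
split the same way.

**Orientation schemes.**  `random`: direction uniform on [0, π).
`largest_side`: the plane runs through the midpoint of the cell's longest
edge and the mass center (ties broken by lowest edge id).  `orthogonal`:
the mother's last division axis rotated by 90°; the first division of a
lineage uses a random axis.  Daughters inherit the axis used, their
mother's heritable type (for lineage-typed runs), and an
"all-orthogonal-ancestry" flag.

**T1 exchange.**  After divisions, inner edges shorter than 0.05 × the
mean inner-edge length are candidates, processed shortest-first, at most
one per junction per step.  The edge is removed; the two flanking cells
lose a side; the two cells that met only at its endpoints gain one and
are joined by a new edge orthogonal to the old one.  The new junction is
created at 1.2 × the trigger length: a junction born shorter than the
trigger is re-selected on the next step and the exchange reverses
endlessly, which inflates rearrangement counts by orders of magnitude
without changing the tissue.  Exchanges that would involve the exterior,
a shared neighbor, or a three-sided cell are refused and not counted.

## Experiments

**Natural proliferation.**  Runs start from a single cell (a regular
12-gon of unit area approximating the disk shape of an isolated cell) and
grow to 4,000 cells (~12 rounds), with 5–10 seeded replicates.
Polygon-class distributions are measured over interior cells only —
boundary cells are missing neighbors for geometric reasons; the switch is
exposed.  Measured hexagon frequencies (5 replicates, 4,000 cells):
random 41.6%, largest-side 52.8%, orthogonal 58.4%, against reported
values of about 40%, 45% and 55%.  The ordering and the random-scheme
value reproduce; both regular schemes come out 3–8 points hexagon-richer
than reported.  We probed the T1 trigger, the split rebalancing, the
division gate, an area-based trigger, and a length-free pressure force,
and none closed the gap; we attribute it to force-law details of the
original implementation that the available text does not specify, and
report it as a model limitation rather than hiding it behind a tuned
parameter.

**Cell memory.**  Strategy 1 draws orthogonal-vs-largest-side per division
(probability p); the fraction of cells whose whole ancestry was orthogonal
decays as p^g, and the topological distribution is insensitive to p.
Strategy 2 types four founder cells heritably; the hexagon frequency is
then linear in the initial orthogonal fraction — provided each typed
clone grows to several hundred cells (see the problem-size section).

**Differential proliferation.**  The seed tissue is a centroidally
relaxed Voronoi epithelium (the generator's stand-in for a simulated
natural endpoint), mechanically equilibrated; the innermost ~10% of cells
proliferate, the rest are quiescent.  γ_pp = γ_qq = 1; γ_pq ∈ {0.5, 1.0,
1.5, 2.0}.  At every step the interfacial proliferating (IP) and
interfacial quiescent (IQ) sets are re-identified and their mean
sidedness recorded relative to the t = 0 interface.  Steady state is
taken over rounds 4+.  The model reproduces: the transient IP drop at
γ_pq = 1 that subsides after 3–4 rounds, IQ moving opposite to IP, and a
strictly monotone steady-state ordering in γ_pq (−0.29 at 2.0 on a
1,000-cell seed, against a reported −0.45 at full scale).  It does not
reproduce a *positive* steady-state IP change at γ_pq = 0.5: the early
rounds are positive, but a slow negative drift common to all tensions
takes over as the immortal quiescent shell is stretched around the
exponentially growing clone — each IQ cell spans ever more interface, so
IP cells touch ever fewer quiescent neighbors.  This finite-shell
artifact grows with the number of rounds and is the known main
limitation of the scaled protocol.

## What the synthetic generators do and do not emulate

`single_cell` (regular 12-gon), `honeycomb` (hexagonal patch) and
`voronoi_tissue` (Lloyd-relaxed random tessellation clipped to a disk)
produce valid trivalent meshes with unit mean cell area.  The Voronoi
fixture mimics the geometry of a relaxed epithelium (interior mean
sidedness ≈ 6, unimodal polygon-class distribution) but not its lineage
structure or its division history; conclusions about *memory* therefore
always come from tissues grown by the engine, and the Voronoi fixture is
used only where the protocol calls for "an equilibrated tissue".  None of
the fixtures emulate curved outer boundaries (arcs are approximated by
straight outer edges throughout), cell death, or 3D effects.

## Numerical choices and degenerate inputs

Vertex-merge tolerance in mesh assembly: 1e-9 × bounding-box diagonal.
Zero-length edges are rejected by the single-edge force API
(`DegenerateGeometryError`) and floored at 1e-12 inside the relaxation
kernel.  Exactly-on-vertex division cuts are resolved by the ε-edge rule;
both-cuts-on-one-edge and plane-misses-cell raise and defer the division
by one step.  Relaxation non-convergence is a logged warning, never an
exception.  The event log is append-only and fully determines replicate
reproducibility: identical configs and seeds give bit-identical event
logs and summary tables.

## Problem sizes used by the test suite

Distribution campaigns: 5 replicates per scheme, grown to 1,000 cells in
the test suite and to the protocol's full 4,000 cells in
`scripts/acceptance.py` (1,000-cell endpoints are measurably
hexagon-richer than 4,000-cell ones, by ~2 points).  Probabilistic-mix
memory grid: 1,000 cells, 4 replicates per probability.  Lineage-typed
memory grid: 4,000 cells, 3 replicates per fraction — at 1,000 cells the
typed clones hold only a few hundred cells, too few to express their
heritable type, and the linear relation between hexagon frequency and
initial orthogonal fraction only emerges at full scale (a finite-size
effect worth knowing about when scaling this experiment down).
Differential protocol: 1,000-cell seed, 2 replicates × 4 tensions × 5
rounds.  All campaigns are seeded, so every reported number is exactly
reproducible.
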