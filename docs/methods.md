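# Methods

## Frames, conventions and the bed model

All geometry lives in the *bed-fixed frame*: X̂ lateral (toward the prone
patient's right), Ŷ longitudinal (toward the head), Ẑ up at the neutral bed
position; units are millimetres, angles degrees.  Because the patient lies
prone, +Ẑ is the patient's posterior and cranial is +Ŷ.

The bed rotates about two axes with hard limits |θx| ≤ 90°, |θy| ≤ 60°.
The published description of the device fixes the signs (+X toward
standing, −X inverted, +Y right overturn) and the ranges, but not the
composition order of the two rotations, nor a numeric frame.  We fix the
bed-to-world rotation as `R = R_X(θx) · R_Y(θy)` (lateral axis = outer
gimbal) and define gravity in the bed frame as `ĝ_b = Rᵀ (0, 0, −1)`, which
reduces to

```
ĝ_b(θx, θy) = ( sin θy · cos θx,  −sin θx,  −cos θy · cos θx )
```

Four anchors pin the convention uniquely: ĝ_b(0,0) = (0,0,−1);
ĝ_b(+90,0) = (0,−1,0) (standing, gravity toward the feet);
ĝ_b(−90,0) = (0,+1,0) (inverted); and ĝ_b(0,+θy) has a positive lateral
component (right side down).  This was a genuinely open design choice; any
fixed order that satisfies the published sign conventions would do, and the
tests verify the anchors plus agreement with an independent rotation-library
composition.

**Inverse problem.**  Given a unit target direction t, the solver inverts
the closed form: `θx = atan2(−t_y, √(t_x² + t_z²))` (which always lands in
[−90, 90] since cos θx ≥ 0 there) and `θy = atan2(t_x, −t_z)`.  If θy is out
of range, θy is clamped to ±60° and θx re-optimised in closed form
(maximising `A cos θx + B sin θx` on the interval).  Residuals are measured
with `atan2(‖u×v‖, u·v)`, which is well-conditioned near 0° where
`acos(u·v)` loses half its digits.  Degenerate targets (pure head/foot
gravity, where θy is irrelevant) tie-break to the smallest |θx|, then
smallest |θy|.  Infeasible targets are clamped, never rejected, so the
planner can rank partial solutions; `feasible` means residual ≤ 1°
(configurable).  A 0.25°-step grid search over the full hardware rectangle
serves as the brute-force oracle in tests.

## Collecting-system model

A `CollectingSystemGraph` is a tree (cycles allowed only when flagged) whose
nodes are calyx tips, junctions, the pelvis and exactly one *export* node at
the ureteropelvic junction (UPJ), and whose edges carry 3D polylines plus a
minimum lumen diameter.  The lumen model is a circular tube; a spherical
stone passes an edge iff `stone diameter ≤ min_lumen_diameter`, ignoring the
effective narrowing of bends.  The export trap is placed *at* the UPJ (the
published phantoms removed ureter and bladder; whether their trap sat
exactly at or slightly distal to the UPJ is unstated).

## Synthetic anatomy

The generator emulates the pelvicalyceal layout of the patient-derived
silicone phantoms the study used, which are not available: a pelvis at the
origin; an export trunk running caudal–anterior–medial; three group trunks
(upper: cranial-posterior; middle: lateral; lower: caudal-anterior); and per
group a fan of infundibula ending in calyx tips.  Defaults (chosen once, as
study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| calyces per group | 2/2/2 | six calyces, a typical simplified collecting system |
| infundibulum length | 10–25 mm | anatomically plausible neck lengths |
| infundibulum lumen | 2–8 mm | straddles the 4 mm stone so both passable and impassable branches occur |
| pelvis trunk lumen radius | 3 mm | wide relative to infundibula, narrow enough to skeletonize cleanly |
| craniocaudal span | ≈ 90 mm | adult kidney collecting-system extent |
| lower-pole descent | 20–45° below horizontal | lower tips end below the pelvis |

Lower-pole infundibula descend caudally below the pelvis, so a lower-calyx
stone is gravity-trapped at the neutral orientation — reproducing the
clinical difficulty that motivates inversion, and forcing negative-θx first
groups exactly as the published lower-calyx angle data show.  Uniform draws
are consumed in a fixed order so that the same seed produces comparable
trees as parameter ranges move (this gives the documented monotonicity: the
lumen lower bound never decreases any edge's diameter).

What the generator does **not** emulate: papillary/fornix microanatomy,
non-circular lumens, deformable tissue, urine flow, duplicated systems.
Tests passing on these phantoms therefore validate the geometry and logic of
the pipeline, not clinical performance on real anatomy.

**Voxelization** marks voxels within the per-edge lumen radius of the
centerline (exact point-to-segment distances, per-segment bounding boxes)
and burns in the centerline as a 6-connected staircase so every edge is
6-connected.  Spacing coarser than the smallest lumen radius is refused
rather than silently disconnecting the lumen.  **Mesh export** runs marching
cubes over a fine voxelization and returns a watertight surface in mm
(winding corrected to positive volume); surface extraction at ~0.8 mm keeps
mesh volume within a few percent of the voxel volume.

## Centerline reconstruction

Input is a binary segmentation (one foreground component enforced;
anisotropic volumes are nearest-neighbour resampled to isotropic voxels at
the finest spacing first).  Steps:

1. 3D thinning (Lee-style medial-axis skeletonization) to a 1-voxel curve.
2. Voxel adjacency (26-connectivity); degree-1 voxels are endpoints,
   mutually adjacent degree-≥3 voxels are clustered into junction nodes;
   degree-2 chains are traced into polyline edges.
3. Per-edge lumen = 2 × the minimum Euclidean distance transform along the
   chain, excluding one tube radius at each chain end (where the chain can
   graze cap or junction boundary voxels).
4. Cleanup to a fixpoint: terminal spurs shorter than `min_branch_length`
   (default 3 mm) are pruned; junction clusters joined by a chain shorter
   than `max(2·min_branch_length, 2·lumen)` are merged — thinning resolves a
   4-way branch point inside a wide lumen as two nearby 3-way points, and a
   branch point cannot be localised better than about one lumen diameter —
   with the connecting chain split at its midpoint and grafted onto the
   incident edges so arc length is conserved; pass-through degree-2 nodes
   are dissolved; short thin self-loops (thinning artifacts inside wide
   junction blobs) are dropped.
5. Terminal re-anchoring: the skeleton endpoint is placed one local tube
   radius short of the foreground boundary along the terminal tangent
   (thinning retracts too far on round caps and not at all on flat resampled
   caps).
6. Branch-point refit: each junction is relocated to the least-squares
   intersection of lines fitted to its incident polylines just outside the
   branch zone (1.5 radius + 2 mm), and the in-zone detours are trimmed.
   This removes the systematic drift of thinned branch points into the
   widest meeting tube (2–3 mm before refit, well under 1.5 mm after).
7. Interior vertices get light moving-average smoothing to remove digital
   staircase length inflation.

Validation on seeded phantoms at 0.5 mm spacing: the node-degree multiset
and edge count match the generating tree in ≥ 18 of 20 seeds, and the mean
relative error of matched edge lengths is 3–4 % per seed.  Individual short,
wide edges (e.g. an 11 mm infundibulum with an 8 mm lumen) can still carry
up to ~20 % error — an irreducible ~2 mm (one lumen radius) branch-zone
ambiguity — so the per-seed *mean* is the reported fidelity statistic.

Calyx labelling partitions tips into upper/middle/lower by craniocaudal
(Ŷ) tertiles — a geometric proxy for radiological assignment (no rule is
published).  Stone snapping binds a stone to the nearest polyline vertex,
splitting the edge at that vertex (arc length conserved exactly); user
export designation picks the nearest degree-1 node, ties to the lowest id.

## Planning

Paths are simple stone→export paths whose every edge admits the stone
(trees have exactly one; cyclic graphs are capped at `max_paths`, ordered by
arc length).  A path is split into **angle groups** by greedy maximal-prefix
segmentation: the current segment absorbs path edges while some in-range
orientation keeps *every* polyline step direction of the accumulated segment
within `cone_angle` (default 60°) of ĝ_b.  Feasibility of a bundle is
decided by its minimax orientation — coarse 5° vectorised grid over the
hardware rectangle, refined by Nelder–Mead on the (non-smooth) max-deviation
objective with boundary clamping — seeded by the closed-form solve of the
bundle mean.  Because feasibility is monotone (growing a bundle can only
raise its minimax deviation), greedy maximal-prefix segmentation provably
uses the minimum number of groups under this predicate, and the brute-force
optimal-partition oracle in the tests finds no greedy-vs-optimal gap.

Plans are ranked by (1) fewest groups, (2) total inversion burden
Σ max(0, −θx) — a patient-comfort proxy, since inversion tolerance is the
clinically doubtful quantity — and (3) arc length.

`cone_angle` is kept ≥ 5° inside the simulator's `trap_angle` (validated at
run time), so a planned step can never sit on the drain/trap boundary.  That
alone, however, does not guarantee passage: under a fixed orientation the
quasi-static stone takes the *steepest* admissible step and may divert into
a side branch that descends more steeply than the planned path (the
passage-via-another-calyx phenomenon the published table marks with `#`) and
trap there.  `plan_drainage` therefore replays its best candidate through
the simulator before labelling it `feasible`; if the replay diverts, it
retries with segment breaks forced at path junctions (the calyx→pelvis,
pelvis→ureter staging typical of the published plans), and otherwise demotes
the plan to `partial`.  `feasible` is thus a *guarantee* under the
quasi-static model — the planner–simulator consistency property holds by
construction, and the 300-case sweep exercises it end to end.

## Drainage simulation

The stone is a point on the centerline with a diameter.  At a fixed
orientation it repeatedly takes the steepest admissible step — direction
within `trap_angle` (default 80°, i.e. a step must descend ≥ 10° below
horizontal) of ĝ_b and edge lumen ≥ stone diameter — with deterministic
tie-breaks (lowest edge id, then vertex order), until no admissible step
remains or the export is reached.  Groups are applied in order; the stone's
exact resting vertex persists between groups.  Admissible steps strictly
lose height, so termination is guaranteed and descent is strictly monotone
within a group — the basis of the invariant suite (descent, stone-size and
trap-angle monotonicity, determinism).  The single `trap_angle` threshold
abstracts all friction/wall-geometry physics of a real phantom; no claim is
made that simulated passage rates equal in-vitro rates, and the published
trial outcomes are reproduced only as statistics of the printed table, never
from simulation.

## Trial-table replication

The packaged CSV transcribes the published per-trial table verbatim (60
trials; checksum-verified at load).  Counting conventions, fixed by
reconciliation against the table and stated with every statistic:
`passed_via_other_calyx` counts as passed (forced by the printed per-model
3/3 totals); threshold statistics look at *any* group of a trial;
X-magnitude thresholds are inclusive (θx ≤ −40 for "beyond −40°"); printed
"≥" thresholds are inclusive, printed ">" strict.  Two printed cells are
typographically defective; one (model 19 lower, "(−39), (56,60)") required a
completion decision — transcribed as (−39, 0), (56, 60) and flagged — and no
reported headline statistic depends on it.

Several published narrative counts do not reconcile with the published
per-trial table under any convention we tested (groups-per-trial 49/4
two/three vs a strict recount of 48/5; Y > 40° in 46 vs 43; upper-calyx
negative-X in 2 vs 3; upper Y-threshold counts off by one).  The replication
report prints both numbers and flags each mismatch rather than resolving it;
recomputed values always follow the per-trial data.

## Numerical choices and limitations

* Tolerances: unit-norm checks at 1e−6; arc-length bookkeeping at 1e−6 mm;
  angle comparisons in degrees with the cross/dot `atan2` form.
* Determinism: one seed drives each generator; all iteration orders are
  sorted; JSON serialisation rounds coordinates to 1e−6 mm (angles to 0.1°
  in plan files), making artifacts byte-stable.
* Problem sizes in the validation suites — 500 + 500 bedframe draws against
  a 0.25° grid oracle, 300 planner/simulator cases, 20 reconstruction seeds
  at 0.5 mm — keep the full suite around half a minute while exercising
  every stage end to end.
* Known limitations: point-stone quasi-statics (no rolling, shape, or fluid
  effects); circular-tube lumens; tertile calyx labelling; single stone per
  run; no DICOM/CT ingestion (binary segmentations are the entry point);
  the rotating bed itself is modelled, not controlled.
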