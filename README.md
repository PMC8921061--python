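# renodrain

Postural-drainage planning for residual renal stone fragments.

After ureteroscopy or percutaneous stone surgery, small residual fragments
(≤ 4 mm) often stay behind in the renal calyces — especially the lower pole,
where gravity holds them in place — and a quarter of patients need repeat
intervention.  One clearance strategy is *individualized postural drainage*:
a two-axis rotating bed tips the prone patient through a planned sequence of
inversion (head-down, rotation `X` about the lateral axis, −90°…+90°) and
lateral overturning (rotation `Y` about the longitudinal axis, −60°…+60°)
angles so that gravity points along each successive segment of the path from
the stone to the ureteropelvic junction (UPJ), and the fragment simply falls
out of the collecting system.

`renodrain` implements the software core of that strategy:

* **bedframe** — the rotation conventions of the bed.  With the bed-to-world
  rotation composed as `R = R_X(θx) · R_Y(θy)`, gravity in the bed-fixed
  frame is the closed form
  `ĝ_b = (sin θy cos θx, −sin θx, −cos θy cos θx)`, and the inverse problem
  (find in-range `(θx, θy)` minimizing the angle between `ĝ_b` and a target
  direction) is solved exactly, with boundary clamping and deterministic
  tie-breaks when the target is outside the reachable set.
* **anatomy** — a seeded generator of synthetic pelvicalyceal trees (pelvis,
  upper/middle/lower calyx groups, infundibula with 2–8 mm lumens straddling
  the 4 mm stone size), plus voxel-phantom rasterisation (NIfTI) and
  watertight surface export (STL/OBJ) for physical phantoms.
* **reconstruct** — 3D thinning of a binary collecting-system segmentation
  into a centerline graph: skeleton → voxel adjacency → polyline edges,
  spur pruning, junction-cluster merging, least-squares branch-point refit,
  and per-edge minimum lumen diameter from the Euclidean distance transform.
* **planner** — enumerates lumen-passable stone→UPJ paths and splits the
  chosen path into *angle groups* by greedy maximal-prefix segmentation: a
  group is feasible while some in-range orientation keeps every centerline
  step within a 60° cone of gravity; each group gets the minimax-alignment
  orientation.  Plans are ranked by fewest groups, then total inversion
  burden (a comfort proxy), then path length, and verified by simulation
  before being labelled feasible.
* **simulator** — quasi-static drainage: the stone repeatedly takes the
  steepest centerline step that lies within the trap angle (default 80°) of
  gravity and whose lumen admits it, until it traps or reaches the UPJ.
* **replication** — a packaged transcription of a published 60-trial
  phantom study (20 kidney models × 3 calyces, 4.0 mm stones) with every
  summary statistic recomputed under explicit counting conventions.

## Worked example

```python
import renodrain as rd
from renodrain.graph import Stone

tree = rd.generate_tree(rd.AnatomyParams(seed=1))          # synthetic kidney
labels = rd.label_calyx_groups(tree)
tip = sorted(n for n, g in labels.items() if g == "lower")[0]
stone = Stone(diameter=4.0, node=tip)                      # 4 mm lower-pole stone

plan = rd.plan_drainage(tree, stone)
for i, g in enumerate(plan.groups, 1):
    print(f"group {i}: (X, Y) = ({g.orientation.theta_x:.1f}, {g.orientation.theta_y:.1f})"
          f"  segment {g.segment}")
print(plan.status, rd.simulate_plan(tree, stone, plan).passed)
```

prints

```
group 1: (X, Y) = (-74.7, 60.0)  segment [9, 8, 0]
group 2: (X, Y) = (58.5, -35.8)  segment [0, 1]
feasible True
```

Read: the lower-pole stone first needs strong inversion with full right
overturn, (−74.7°, 60.0°), to fall from the calyx tip through its
infundibulum into the pelvis (nodes 9 → 8 → 0); a second, near-standing
orientation (58.5°, −35.8°) then drains it from the pelvis out through the
UPJ (node 1).  The replayed quasi-static simulation confirms passage.  The
pattern — strongly negative `X` for lower-calyx stones, two groups for a
calyx→pelvis→ureter path — is the same one the published trial table shows.

The same pipeline is scriptable from the shell:

```sh
renodrain synth --seed 1 --out graph.json
renodrain plan --graph graph.json --stone "13.6,-42.6,-23.9,4.0" --out plan.json
renodrain simulate --graph graph.json --stone "13.6,-42.6,-23.9,4.0" \
    --plan plan.json --out traj.json
renodrain replicate          # recompute the 60-trial table statistics
```

`renodrain replicate` prints every published summary statistic next to its
recomputation from the per-trial table and flags the handful of published
narrative counts that do not reconcile with the published table itself.

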