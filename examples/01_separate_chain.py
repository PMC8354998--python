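"""Separate a chain of touching lobes with seed-point region growing.

Builds a synthetic 3-lobe chain (convex lobes fused at small contact patches
with a 60-degree normal crease, emulating adjacent vertebrae), plants the
suggested 5-seed-per-lobe layout and runs the iterative schedule: grow at a
5-degree connectivity threshold, raise by 5 degrees per pass, stop at 55.
"""

import numpy as np

import surfseed as ss

fixture = ss.generate_chain(ss.FixtureSpec(n_lobes=3, crease_angle=60.0))
mesh = fixture.mesh
print(f"chain: {mesh.n_vertices} vertices, {mesh.n_faces} faces, "
      f"{fixture.spec.n_lobes} lobes")

seeds = ss.snap_seeds(mesh, fixture.seeds_5pt)
state = ss.iterative_segment(mesh, seeds, ss.ThresholdSchedule(5, 5, 55))

for rec in state.pass_log:
    print(f"  pass at theta={rec.theta:4.1f} deg: {len(rec.newly_labeled):5d} "
          "vertices newly labelled")

mismatches = int((state.labels != fixture.labels).sum())
print(f"label sizes: {np.bincount(state.labels)[1:]}")
print(f"mismatches against ground truth: {mismatches} of {mesh.n_vertices}")
# Expected: every vertex labelled within two passes and 0 mismatches --
# intra-lobe normal angles stay far below the 55-degree ceiling while the
# 60-degree contact creases block growth between lobes.
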