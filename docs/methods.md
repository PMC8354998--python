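# Methods

This note documents the models, numerical choices and limitations behind
`surfseed`: a seed-point surface region-growing segmenter for separating
touching bone segments on triangle meshes, its surface-distance evaluation
suite, and the synthetic fixtures everything is validated on.

## Surface model

A surface is an indexed triangle mesh in world millimetres. On ingestion,
vertices closer than 1e-6 mm are merged transitively (STL stores three
loose vertices per facet, so deduplication is a precondition for edge
adjacency) and degenerate faces (repeated indices or numerically zero area)
are dropped. Vertex normals are the **area-weighted** mean of incident face
normals, renormalised; area weighting was chosen because marching-cubes
output has highly nonuniform triangle sizes, and the raw edge-cross-product
accumulation implements it for free. A vertex without incident faces gets a
zero normal and is flagged *unsegmentable*: it can never be labelled and is
excluded from termination checks. Non-manifold edges (more than two
incident faces, which marching cubes can emit) are tolerated with a
warning; traversal simply treats all incident faces' vertices as
neighbours.

## Region growing

One pass is a FIFO breadth-first traversal at a fixed connectivity
threshold `theta`: a dequeued vertex labels each of its unlabelled
neighbours whose normal lies within `theta` degrees of its own. The
connectivity test is **local** (dequeued vertex vs neighbour, not neighbour
vs seed), which makes growth transitive along smooth normal gradients. Three
rules make the result a pure function of its inputs:

- the frontier is enqueued sorted ascending by vertex index;
- neighbours are visited in ascending index order;
- a labelled vertex is never relabelled (so when two regions race toward
  the same vertex in one pass, strict FIFO order decides).

The iterative driver starts at `theta_init` (default 5°), raises the
threshold by `theta_step` (default 5°) after each pass and re-grows from the
current region boundaries (labelled vertices with at least one unlabelled
neighbour — equivalent to re-enqueuing everything, but cheaper) until all
segmentable vertices are labelled or `theta_max` is exceeded, in which case
it completes with a warning naming the unlabelled count. An optional hook
runs after every pass and may undo it and/or add seeds; an undone pass
reverts exactly the vertices it labelled, while seeds — user input, not
growth — keep their labels. The pass log replays to the current label
array, which the tests assert.

Seeds are snapped to the nearest mesh vertex; exact ties break to the
lowest index, and two seeds may share a vertex only when they agree on the
label. Segment export writes, per label, the submesh of faces whose three
vertices share that label; faces straddling labels or touching unlabelled
vertices are omitted and counted. Segments are exported as-is — holes
included — because downstream repair is out of scope here.

## Distance evaluation

Distances are *exact* point-to-mesh nearest distances (closest point on a
triangle by barycentric region classification), one sample per vertex of
each mesh, in both directions, so protrusions and missing parts both
register. The accelerated search takes an upper bound from the nearest
reference vertex (KD-tree) and then scans exactly those triangles whose
centroid lies within bound + the largest triangle circumradius — a provable
superset of the optimum, so it equals the exhaustive scan, which the tests
assert to 1e-9 mm against an independent kernel.

The sign of a distance follows the outward normal at the nearest point,
with a pseudonormal (average over all triangles tying for the minimum) when
the nearest point falls on an edge or vertex; positive means the query
point lies outside the reference surface. Statistics (ASSD, AASD, RMS,
max, p95, %-below-tolerance) pool both directions; AASD is the signed
pooled mean. Percentiles use linear interpolation between order statistics.
The tolerance comparison is strict (`< 0.2 mm` by default). Sampling is by
mesh vertex; an optional area-weighted mode (vertex weight = one third of
incident face area) exists for meshes with very uneven triangles but is off
by default because vertex sampling matches marching-cubes density and keeps
every number deterministic.

ICC is the two-way random-effects, absolute-agreement, single-measure form
ICC(2,1), computed directly from the ANOVA sums of squares; it is
cross-checked in the tests against pingouin and the classic
six-subject/four-rater worked table.

## Volume front end

`extract_surface` is deliberately standard: intensity `>= threshold`
defines bone (default 226 HU, a common bone preset, always overridable),
scikit-image's topology-consistent marching cubes triangulates the
iso-surface, vertices map to world millimetres through the volume affine,
and faces are flipped if the enclosed signed volume is negative so normals
point away from bone. NIfTI is read via nibabel and NRRD via SimpleITK.

## Synthetic fixtures

No clinical data ship with the package, so fixtures must reproduce the one
geometric property the method depends on: smooth normals within a segment,
a sharp normal discontinuity at the contacts.

The default lobe is a **spindle**: a solid of revolution whose meridian is
a circular arc. If the meridian slope at the contact ring is `s`, the angle
between vertex normals across the ring is exactly `2*arctan(s)`, so
`crease_angle` is realised by construction and is decoupled from
`contact_radius` and `lobe_radius` (a superellipsoid chain was considered,
but it couples those parameters and only approximates the crease). End
lobes close with hemispherical caps, which are tangent-continuous — no
spurious crease. A fine band of rings just *above* each contact ring biases
the shared ring's area-weighted normals toward the lower lobe; the ring is
then claimed deterministically by the lower lobe (which owns it in the
ground truth, consistent with the nearest-lobe-centre, ties-to-lower rule)
and never acts as a stepping stone across the crease. With the default
1 mm edge length, intra-lobe normal angles stay below ~10° while
cross-contact angles stay above `crease - 2°`, so the default 60° crease
against the 55° schedule ceiling yields exact recovery, which the
acceptance suite asserts.

`lobe_shape="cube"` provides the minimal worked example: grid-subdivided
cubes joined by small square necks, every crease at 90°.

Suggested seed layouts mimic a clinical placement logic: the 5-seed layout
is one body-centre vertex plus four near-contact vertices per lobe; the
12-seed layout has four body and eight near-contact seeds. Holes
(`hole_fraction`) are punched as pairwise non-adjacent faces in the contact
zone, so each punched face opens exactly one boundary loop — emulating the
facet-joint holes that thresholded clinical meshes show. Noise
(`noise_sd`) displaces vertices along their normals by seeded zero-mean
Gaussians. Every output is a pure function of (spec, seed).

### What the fixtures do not emulate

Anatomically realistic vertebra shape, inner cortical surfaces, CT physics
(beam hardening, shoulder artifacts), and partial-volume effects. Passing
the fixture suite therefore shows the *algorithmic* properties — exactness
where the crease/ceiling separation holds, determinism, metric correctness
— not clinical accuracy on real scans.

## In-silico experiments

Two experiment designs in `surfseed.experiments` mirror classic validation
questions at desk scale (3 lobes, 1.5 mm edges, 60° crease):

**Seed count.** Fixtures carry 0.6 mm surface jitter — deliberately large
relative to the edge length so vertex-normal perturbations are comparable
to the 55° ceiling. In that *contested-growth* regime some intra-lobe edges
block until late passes, patches strand, rim leaks become possible, and
seed placement matters; with small jitter both layouts recover every
fixture perfectly and the comparison is vacuous. Accuracy is the ASSD
between each recovered segment and its ground-truth counterpart, averaged
over lobes and 20 fixtures. The dense 12-seed layout is on average at
least as accurate as the sparse 5-seed layout.

**Observer agreement.** Subjects are noise levels from 0.3 to 0.8 mm; each
of two simulated observers rates a subject by the *median* over five
replicate fixtures of the segment-vs-truth ASSD, after jittering every
suggested seed position by an isotropic 0.5 mm Gaussian (click
variability). The median matters: a single fixture's ASSD is heavy-tailed
(a rare growth-race leak is an order of magnitude above typical) and such
events are nearly independent between observers. ICC(2,1) of the resulting
6x2 rating matrix quantifies agreement relative to the between-condition
spread.

## Numerical choices

- Angle tests compare dot products against `cos(theta) - 1e-12`, making
  "angle <= theta" robust at representable boundaries.
- Duplicate-vertex merging is transitive union-find over all pairs within
  the tolerance, not grid rounding, so near-boundary pairs cannot split.
- Marching-cubes orientation is fixed globally by the sign of the enclosed
  volume (the variant is winding-consistent, so one check suffices; it also
  absorbs negative-determinant affines).
- The nearest-point tie set uses a relative threshold
  (`d^2 <= d2_min * (1 + 1e-9)`), which keeps signs scale-invariant.
- Problem sizes in tests and the acceptance script (default chains of ~6000
  vertices, experiment chains of ~2900 at 1.5 mm resolution, 20-fixture
  experiments) were chosen as the smallest sizes at which every geometric
  regime of interest — multi-pass growth, contested races, crease blocking
  — actually occurs.

## Known limitations

- The signed distance uses an averaged facet pseudonormal, not the full
  angle-weighted pseudonormal; for badly non-manifold geometry the sign at
  exactly equidistant interior points can be arbitrary (the magnitude never
  is).
- Region growing offers no automatic leak repair: when surface noise pushes
  a cross-contact edge under the ceiling *and* the invaded territory is not
  yet claimed, the leak persists (undo + extra seeds is the remedy, as in
  interactive use).
- Holes are detected (boundary loops) but never filled.
- PLY/STL store coordinates as 32-bit floats; round-tripping through files
  quantises geometry at the 1e-7 relative level.
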