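# Methods

This note documents the models, conventions and design choices behind
`rxnscheme`, and what the synthetic test conditions do and do not show
about real data.

## Coordinate and image conventions

All geometry is 0-based pixel coordinates, origin top-left, x
rightward, y downward.  Bounding boxes are half-open
`[x0, x1) × [y0, y1)`; annotation files serialize them as COCO-style
`[x, y, width, height]`.  Binarization is a global Otsu threshold on
grayscale with ink as foreground — schemes are high-contrast line art,
so no local thresholding or denoising is attempted.  Connected
components use 8-connectivity (arrowheads touch shafts diagonally) and
are always sorted in reading order `(y0, x0)` so that downstream
tie-breaks are reproducible.

## The scheme engineer

The generator composes schemes from a seeded glyph bank:

* **diagram glyphs** — polygonal ring skeletons (5–7 vertices, radius
  16–24 px) with 1–3 bond-like appendages, stroke width ~3 px; with
  probability 0.5 a small pseudo-text cluster is detached 4–6 px past
  an appendage tip, playing the role of a terminal superatom so that
  diagram completion has real work to do;
* **arrows** — solid, curly (arc with a filled V-head), equilibrium
  (two half-headed shafts) and resonance (double-headed), length 50–70
  px.  In ring layouts solid arrows are re-rendered vectorially along
  the chord direction, because raster-rotating a 3-px shaft can break
  it into fragments;
* **labels / conditions** — rows of procedural pseudo-characters
  (random stroke patterns), 1 row of 2–3 characters for labels, 1–2
  rows of 4–8 characters for conditions;
* **negatives** — plus signs and brackets, drawn between group members
  and scattered on free canvas.

Layout: linear schemes place reactant groups and arrows along rows
(wrapping only when `max_row_width` is set; the canvas is auto-sized
otherwise), labels strictly below their diagram with a 3–6 px gap, and
conditions above the arrow with their center 0.15–0.6 arrow-lengths
from the arrow midpoint (clamped so boxes stay disjoint) — inside the
directionality band by construction.  Cyclic schemes place groups on a
ring whose radius guarantees that adjacent groups clear the chord
arrow between them.  Elements never overlap (4 px margin for
rejection-sampled negatives); every placement draw comes from one
seeded generator, so `(schema, bank, seed)` reproduces images and
annotations byte-for-byte.

Default study conditions used by the tests and the acceptance script:
linear suites with 1–3 steps, 1–2 diagrams per group, `p_label` and
`p_conditions` 0.6, 0–2 negatives; cyclic suites with 3–5 steps.
Augmentation jitters scale (0.85–1.1), rotation (±4°, arrows ±3° so
that head orientation stays meaningful) and optional Gaussian blur.

What this emulates — the element classes, their typical sizes and the
spatial relations (labels below diagrams, conditions near arrow
normals, steps ordered along rows or rings).  What it does not —
publisher fonts and rendering, scan noise and skew, dense multi-row
crowding, chemically meaningful structures, or arrows fused with
surrounding ink.  Passing the synthetic suites therefore validates the
symbolic machinery and the learning setup, not detection performance
on real journal figures.

## Arrow model

A small convolutional network written directly in numpy (im2col
convolutions, manual backprop): three conv3×3+ReLU+maxpool stages
(8/16/32 channels), global average pooling, a 1-unit detector head and
a 32→32→4 classifier branch ("two additional fully connected layers").
Loss `10·BCE + 1·CE`, with the CE term masked for non-arrow patches:
the subtype of a negative is undefined, so it contributes no gradient.
Training: Adam, lr 0.001, 20 epochs, batch 32, light train-time
augmentation (±5° rotation, ±2 px shifts, occasional blur), all from a
single seeded generator — retraining with the same seed reproduces the
parameter hash bit-for-bit.  The reference system used a pretrained
ResNet-18 backbone with transfer learning; at desk scale the
from-scratch small backbone reaches ≥95% detector accuracy on held-out
synthetic patches in seconds, which is the tested claim here.

Proposal filter defaults ("simple criteria"): component area in
[20 px, 5% of the image], and elongation ≥ 2 **or** fill ratio ≤ 0.2.
All bounds are config-exposed; on the generated suites every
ground-truth arrow survives the filter.

## Region detection

Two backends behind one interface.  The oracle backend replays
annotation boxes, optionally perturbed (Gaussian corner jitter, drop
and spurious rates) so that postprocessing robustness can be studied;
with zero perturbation every downstream stage becomes a pure function
of the annotation, which is the harness used for the
annotation-recovery tests.  The learned backend is a **reduced**
detector: proposals are formed by morphological closing (disk radius
8) grouping nearby components, and each proposal patch (32×32) is
classified background/diagram/label/conditions by a conv net trained
with SGD at the published learning rate 0.001; per-class NMS at IoU 0.5
finishes.  The full-scale recipe of the reference detector (Faster
R-CNN, ResNeXt-101, DIoU box loss with RPN/head weights 2.0/10.0, 5000
iterations on 2000 schemes) is recorded as configuration in
`PUBLISHED_RECIPE` but deliberately not trained here; label-vs-
conditions confusion in the reduced detector is expected and is exactly
what the text-postprocessing stage corrects.

## Symbolic postprocessing

**Diagram completion.**  The largest component overlapping the raw box
is dilated with a disk whose radius is locally computed:
`clamp(1.2 × median nearest-neighbor gap of the components inside the
box, 3 px, 0.05 × image diagonal)`.  Components 8-adjacent to the
dilated mask are absorbed (so a radius equal to the empty-gap width
bridges a detached superatom) and the box is refit to the union.  The
operation is idempotent.

**Text reclassification.**  For each text region the nearest diagram
and nearest arrow are found with the box-separation distance; at
exactly equal distances the diagram wins (determinism).  "Below a
diagram" means the region center is under the diagram's bottom edge
with ≥25% horizontal overlap of the narrower box.  The directionality
criterion accepts a region whose center lies within 1.0 arrow-length
along the normal through the arrow center and within 0.6 arrow-length
laterally; both tolerances are declared defaults, not derived values.
Pairing is nearest-neighbor and may be many-to-one; diagrams whose box
lies inside a conditions region are attached to that record.

## Arrow geometry

The minimal rotated rectangle comes from rotating calipers over the
convex hull (principal-axis fallback for collinear pixels).  The head
side is defined when the COM offset along the long axis exceeds 2% of
the length; equilibrium/resonance arrows are oriented the same way but
flagged bidirectional, and a symmetric arrow falls back to the
reading-order direction (rightward, or downward if vertical).

Curly endpoints: probe rectangles of depth 0.2× the perpendicular
bbox dimension along each side pick extremal pixels; picks closer than
`max(5 px, 10% of the bbox diagonal)` merge; erasing a probe-sized
window around a pick must not split the arrow into two components
(mid-arc picks do split it).  A final cluster pass at probe-depth scale
keeps, within each cluster, the pick with the least surrounding ink —
a strongly curving terminus otherwise leaves two survivors from
different probes.  Hook-vs-end classification scans perpendicular to
the local inward direction (taken from the local centroid offset, which
stays on the stroke even at a filled head) and calls "end" when the
scanline-count coefficient of variation over the first 30% of the
stroke is below 0.25.  The reference hook/end pair maximizes the area
of diagrams within 1.5 arrow-lengths of the endpoint.

Known limitation: for arrowheads oriented diagonally, bbox-side probes
can pick head corners whose erasure strands a corner sliver, and the
arrow is then reported unparseable; `analyze_arrow` falls back to the
rotated-rectangle axis with a warning.  Headless strokes — where the
skeleton-degree oracle is exact — are recovered at 100/100 on the
fixture suite.

## Step scanning and graphs

Scan strips are Δ = 0.25 arrow-lengths deep with a lateral half-extent
of 0.8 arrow-lengths, marching from the arrow box edge to at most one
image diagonal.  A box counts as inside the corridor when its lateral
center falls within it or at least half its lateral extent does;
corner-grazing neighbors from other rows or ring positions are ignored
(both for collected diagrams and for the arrows that stop the scan).
A diagram seen on both sides goes to the nearer side, ties to the
reactant side.  An empty side triggers the multi-line fallback: diagram
rows are found by clustering box centers in y; the previous row is
searched when the arrow sits in the lower image half, the next row
otherwise, taking the trailing/leading diagram group (gap threshold
0.75 arrow-lengths, arrows break groups).  Steps become hyperedges
(reactant set → product set); products matching another step's
reactants stitch the chain; multiple products are kept in reading
order; node identity is the diagram region id — merging visually
identical diagrams across a scheme would need structure recognition and
is out of scope.

## Evaluation

Box matching is greedy one-to-one by descending IoU at threshold 0.5
(config-exposed; the exact criteria of the reference evaluation are not
published, so ours are declared).  Graph matching first fixes node
correspondence by diagram-box IoU ≥ 0.5 (identity on shared ids when no
geometry is present), then traverses both graphs from their start
nodes — in cyclic components a seeded random entry node — and counts
steps whose mapped reactant and product sets match exactly.  The result
is invariant to node relabeling and to the cycle entry point.
Diagram-label matching is scored as correct-vs-incorrect pairings
(recall only).  Metrics print as percentages at 0.1 resolution; some
published reference rows appear truncated rather than rounded, so
worked-example tests compare at ±0.1 percentage points.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: 50
linear + 10 cyclic schemes for annotation recovery, 250 patches
(200/50 split) for arrow-model training, 100 stroke fixtures for the
endpoint oracle, and a 20-scheme training set for the reduced region
detector.  These sizes are the package's study conditions; scaling any
of them up is a matter of configuration, not code.
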