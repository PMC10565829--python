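# rxnscheme

Chemical knowledge is routinely published as **reaction schemes**:
figures in which 2-D structure diagrams are connected by reaction
arrows, annotated with conditions text above or below the arrows and
with short alphanumeric labels ("1a") beneath the diagrams.  Such
figures are immediately readable by chemists and opaque to machines.
`rxnscheme` is a toolkit for turning raster images of reaction schemes
into machine-readable reaction graphs, aimed at people building
reaction databases or studying document-level chemical information
extraction.

The package contains both halves of that problem:

* **Scheme engineering** — a synthetic data generator that composes
  annotated artificial reaction schemes (linear rows or catalytic-cycle
  rings) from procedurally drawn diagram glyphs, four arrow types
  (solid, curly, equilibrium, resonance), pseudo-text labels/conditions
  and negative symbols.  Every scheme ships with ground-truth boxes,
  classes, pairings and the reaction graph, so every downstream stage
  can be trained and tested without any external data.
* **The operational pipeline** — binarization and connected-component
  analysis; a two-branch convolutional arrow detector; a pluggable
  region detector for diagrams/labels/conditions (a reduced learned
  detector, plus a ground-truth oracle backend for isolating the
  symbolic stages); dilation-based diagram completion; positional
  reclassification and pairing of text regions; arrow-geometry recovery
  (rotated-rectangle orientation, center of mass, curly-arrow
  endpoints); outward step scanning; and reaction-graph assembly with
  JSON/GraphML export.

## The models in brief

**Arrow detection.** Arrows are isolated connected components.  Each
candidate component is rendered into a centered 64×64 patch and scored
by a small CNN with two heads — a binary detector and a 4-way subtype
classifier — trained with the combined loss

```
L = λ₁ · BCE(detector) + λ₂ · CE(classifier),    λ₁ = 10, λ₂ = 1,
```

for 20 epochs with Adam at learning rate 0.001; the classifier term is
masked on non-arrow patches, where the subtype is undefined.

**Arrow geometry.** A minimal rotated bounding rectangle gives the
arrow axis; the offset of the pixel center of mass from the rectangle
center along that axis marks the product side.  Curly arrows are probed
along their bounding-box sides for up to four endpoints, filtered by a
connectivity test, and classified into hooks (arrowheads) vs ends by
perpendicular scanline profiles.

**Graph formation.** From each arrow, two scans march outward in
equidistant strips collecting diagram boxes and stopping at the next
arrow; empty sides fall back to the previous/next text line.  Steps are
stitched into a directed graph by matching products of one step with
reactants of another.

**Evaluation.** Detections are scored by precision, recall and
F-score, `R = TP/(TP+FN)`, `P = TP/(TP+FP)`, `F = 2PR/(P+R)`; whole
schemes are compared by traversing predicted and ground-truth graphs
from their start nodes (seeded random entry for cycles) and counting
matched, missing, and spurious reaction steps.

## Worked example

```bash
python examples/extract_reaction_graph.py
```

generates a 3-step linear scheme and extracts its graph; the end of the
output reads

```
7 diagram nodes, 3 reaction steps
label pairings      : {1: 0, 3: 2, 7: 6, 9: 8, 13: 12, 15: 14, 19: 18}
conditions pairings : {5: 4, 11: 10, 17: 16}
```

i.e. seven structure diagrams connected by three steps whose products
feed the next step's reactants, each label paired to its diagram and
each conditions block to its arrow.  The JSON printed above it is the
exported graph: `nodes` (diagram regions with boxes and optional
`label_text`/`smiles` fields filled by OCR/OCSR plugins) and `steps`
(`{arrow, reactants, products, conditions}`).  The other examples cover
dataset generation, arrow-model training, and evaluation; the same
capabilities are exposed as a thin CLI
(`rxnscheme generate|train-arrows|train-regions|extract|evaluate`).

## Scope notes

OCR of text and optical chemical structure recognition of diagrams are
deliberately plugin seams (`ocr_ocsr_plugins`), not bundled engines.
Arrows fused to other ink are not isolated components and are missed by
design.  The generated schemes carry no chemical meaning; they model
the image features and spatial relationships the pipeline relies on.
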