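"""Symbolic refinement of raw detections.

Two stages of expert knowledge are injected after detection:

* **Diagram completion** — a detected diagram box is snapped to the ink:
  the largest connected component overlapping the box is dilated with a
  locally sized disk kernel and every component touching the dilated
  mask is absorbed, so detached fragments (terminal superatoms) rejoin
  their diagram and loose box edges are tightened.

* **Text reclassification and pairing** — label and conditions regions
  look alike; what separates them is position.  A text region closest
  to a diagram and sitting below it becomes a label; one closest to an
  arrow and lying near the line normal to the arrow through its center
  (the directionality criterion) becomes a conditions block.  Labels
  then pair with their nearest diagram and conditions blocks with their
  nearest arrow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.morphology import dilation, disk

from .geometry import BBox, BinaryImage, ConnComp, separation
from .regions import PanelRegion
from .arrows import Arrow


@dataclass
class DirectionalityParams:
    """Tolerances of the conditions-block directionality criterion,
    in units of the arrow length."""

    max_normal_distance: float = 1.0
    lateral_tolerance: float = 0.6

    def __post_init__(self):
        if self.max_normal_distance <= 0 or self.lateral_tolerance <= 0:
            raise ValueError("directionality tolerances must be positive")


@dataclass
class CompletionParams:
    """Local dilation-kernel sizing for diagram completion.

    radius = clamp(gap_factor * median nearest-component gap inside the
    raw box, r_min, r_max_frac * image diagonal).
    """

    gap_factor: float = 1.2
    r_min: int = 3
    r_max_frac: float = 0.05


def _local_kernel_radius(comps: list[ConnComp], params: CompletionParams,
                         image_diag: float) -> int:
    r_max = max(params.r_min, int(round(params.r_max_frac * image_diag)))
    if len(comps) < 2:
        return params.r_min
    gaps = []
    for i, a in enumerate(comps):
        nearest = min(separation(a.bbox, b.bbox)
                      for j, b in enumerate(comps) if j != i)
        gaps.append(nearest)
    r = params.gap_factor * float(np.median(gaps))
    return int(np.clip(round(r), params.r_min, r_max))


def complete_diagram(region: PanelRegion, bin_img: BinaryImage,
                     ccs: list[ConnComp],
                     params: CompletionParams | None = None) -> PanelRegion:
    """Snap a diagram region to the ink via locally sized dilation.

    Idempotent: the completed box already covers its components, so a
    second application reproduces the same box.
    """
    if region.cls != "diagram":
        raise ValueError("complete_diagram expects a diagram region")
    params = params or CompletionParams()
    overlapping = [cc for cc in ccs if cc.bbox.intersects(region.bbox)]
    if not overlapping:
        warnings.warn("no connected component overlaps the diagram box", stacklevel=2)
        return region
    seed = max(overlapping, key=lambda c: c.area)
    diag = float(np.hypot(bin_img.width, bin_img.height))
    radius = _local_kernel_radius(overlapping, params, diag)

    # dilate the seed component inside a padded crop, then absorb every
    # component whose pixels touch the dilated mask
    pad = radius + 1
    x0 = max(seed.bbox.x0 - pad, 0)
    y0 = max(seed.bbox.y0 - pad, 0)
    x1 = min(seed.bbox.x1 + pad, bin_img.width)
    y1 = min(seed.bbox.y1 + pad, bin_img.height)
    crop = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    crop[seed.pixels[:, 0] - y0, seed.pixels[:, 1] - x0] = True
    grown = dilation(crop, disk(radius))
    # components 8-adjacent to the dilated mask count as touching, so a
    # kernel radius equal to the empty-gap width bridges the gap
    grown = dilation(grown, np.ones((3, 3), dtype=bool))

    members = [seed]
    for cc in ccs:
        if cc is seed:
            continue
        inside = (cc.pixels[:, 0] >= y0) & (cc.pixels[:, 0] < y1) \
            & (cc.pixels[:, 1] >= x0) & (cc.pixels[:, 1] < x1)
        if not inside.any():
            continue
        pix = cc.pixels[inside]
        if grown[pix[:, 0] - y0, pix[:, 1] - x0].any():
            members.append(cc)
    box = members[0].bbox
    for cc in members[1:]:
        box = box.union(cc.bbox)
    return replace(region, bbox=box, provenance="postprocessed")


# --------------------------------------------------------------------------
# text reclassification
# --------------------------------------------------------------------------

def _nearest(region_box: BBox, boxes: list[BBox]):
    """(index, separation) of the nearest box; reading-order tie-break."""
    best_i, best_d = None, np.inf
    for i, b in enumerate(boxes):
        d = separation(region_box, b)
        if d < best_d - 1e-12:
            best_i, best_d = i, d
    return best_i, best_d


def is_below_diagram(region_box: BBox, diagram_box: BBox,
                     min_overlap_frac: float = 0.25) -> bool:
    """Below = region center under the diagram's bottom edge, with
    horizontal overlap of at least a quarter of the narrower box."""
    cx, cy = region_box.center
    if cy <= diagram_box.y1:
        return False
    ov = min(region_box.x1, diagram_box.x1) - max(region_box.x0, diagram_box.x0)
    return ov >= min_overlap_frac * min(region_box.width, diagram_box.width)


def _arrow_axis(arrow: Arrow) -> tuple[np.ndarray, np.ndarray, float]:
    """(center, unit long-axis direction, length) from the arrow bbox."""
    b = arrow.bbox
    c = np.array(b.center)
    if b.width >= b.height:
        u = np.array([1.0, 0.0])
        length = float(b.width)
    else:
        u = np.array([0.0, 1.0])
        length = float(b.height)
    return c, u, length


def satisfies_directionality(region_box: BBox, arrow: Arrow,
                             params: DirectionalityParams) -> bool:
    """True when the region center lies near the line normal to the
    arrow through its center: normal-line distance from the arrow center
    within ``max_normal_distance`` arrow lengths, lateral offset along
    the arrow within ``lateral_tolerance`` arrow lengths."""
    c, u, length = _arrow_axis(arrow)
    v = np.array(region_box.center) - c
    lateral = abs(float(v @ u))              # along the arrow
    normal = abs(float(v[0] * -u[1] + v[1] * u[0]))  # along the normal
    return (normal <= params.max_normal_distance * length
            and lateral <= params.lateral_tolerance * length)


def reclassify_text_region(region: PanelRegion,
                           diagrams: list[PanelRegion],
                           arrows: list[Arrow],
                           params: DirectionalityParams | None = None) -> PanelRegion:
    """Re-decide label vs conditions from scheme geometry.

    At exactly equal separations the diagram rule wins (determinism).
    With neither diagrams nor arrows present the prior class is kept.
    """
    if region.cls not in ("label", "conditions"):
        raise ValueError("reclassify_text_region expects a text region")
    params = params or DirectionalityParams()
    if not diagrams and not arrows:
        warnings.warn("no diagrams or arrows to reclassify against", stacklevel=2)
        return region
    di, dd = _nearest(region.bbox, [d.bbox for d in diagrams]) if diagrams else (None, np.inf)
    ai, ad = _nearest(region.bbox, [a.bbox for a in arrows]) if arrows else (None, np.inf)
    if di is not None and dd <= ad:  # tie -> diagram wins
        if is_below_diagram(region.bbox, diagrams[di].bbox):
            return replace(region, cls="label", provenance="postprocessed")
        return region
    if ai is not None and satisfies_directionality(region.bbox, arrows[ai], params):
        return replace(region, cls="conditions", provenance="postprocessed")
    return region


def pair_regions(labels: list[PanelRegion], conditions: list[PanelRegion],
                 diagrams: list[PanelRegion], arrows: list[Arrow]):
    """Pair finalized text regions with their parents.

    Returns ``(label_of, conditions_of, diagrams_of_conditions)``:
    label index -> diagram index, conditions index -> arrow index, and
    conditions index -> [diagram indices] for diagrams whose box falls
    inside a conditions region (species drawn within the annotation).
    Many-to-one pairings are permitted; unpairable regions are omitted.
    """
    label_of: dict[int, int] = {}
    conditions_of: dict[int, int] = {}
    diagrams_of_conditions: dict[int, list[int]] = {}
    dboxes = [d.bbox for d in diagrams]
    aboxes = [a.bbox for a in arrows]
    for i, lab in enumerate(labels):
        j, _ = _nearest(lab.bbox, dboxes)
        if j is not None:
            label_of[i] = j
    for i, cond in enumerate(conditions):
        j, _ = _nearest(cond.bbox, aboxes)
        if j is not None:
            conditions_of[i] = j
        inside = [k for k, db in enumerate(dboxes)
                  if cond.bbox.intersection_area(db) >= 0.9 * db.area]
        if inside:
            diagrams_of_conditions[i] = inside
    return label_of, conditions_of, diagrams_of_conditions
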