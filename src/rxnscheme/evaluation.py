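"""Detection and graph-level evaluation.

Performance is summarized with precision, recall and F-score computed
from true positives (correctly extracted data), false positives
(incorrect extractions) and false negatives (missed data):

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F         = 2 * P * R / (P + R)

Region detections are matched one-to-one to ground truth greedily by
descending IoU at a configurable threshold.  Whole reaction schemes are
compared by graph traversal: node correspondence is fixed by diagram-box
IoU, both graphs are traversed from their starting nodes (or, for
cyclic schemes with no start, from a seeded random node around the
cycle), and the reaction steps encountered are counted as matched,
missing, or spurious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BBox
from .graphs import ReactionGraph, ReactionStep


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp)


def prf_metrics(c: ConfusionCounts):
    """(recall %, precision %, F %); a metric with a zero denominator is
    returned as None (reported as N/A)."""
    recall = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    if recall is None or precision is None or (precision + recall) == 0:
        f = None
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return recall, precision, f


def format_metric(value) -> str:
    return "N/A" if value is None else f"{value:.1f}%"


def match_regions(pred: list[BBox], gt: list[BBox],
                  iou_threshold: float = 0.5) -> ConfusionCounts:
    """Greedy one-to-one box matching by descending IoU."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    pairs = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            iou = p.iou(g)
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_g = set(), set()
    tp = 0
    for iou, i, j in pairs:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fn=len(gt) - tp, fp=len(pred) - tp)


# --------------------------------------------------------------------------
# graph matching
# --------------------------------------------------------------------------

def _node_correspondence(pred: ReactionGraph, gt: ReactionGraph,
                         iou_threshold: float) -> dict[int, int]:
    """pred node id -> gt node id by diagram-box IoU (greedy, highest first)."""
    def boxes(g):
        out = {}
        for i, info in g.nodes.items():
            if info.get("bbox") is not None:
                out[i] = BBox.from_coco(info["bbox"])
        return out

    pb, gb = boxes(pred), boxes(gt)
    pairs = []
    for i, b1 in pb.items():
        for j, b2 in gb.items():
            iou = b1.iou(b2)
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used_g = set()
    for iou, i, j in pairs:
        if i in mapping or j in used_g:
            continue
        mapping[i] = j
        used_g.add(j)
    return mapping


def _traversal_steps(graph: ReactionGraph, seed: int) -> list[ReactionStep]:
    """Steps in traversal order from the start nodes.

    Start nodes are diagrams that appear as reactants but never as
    products.  A cyclic component has no start node; a seeded random
    member node is chosen and the cycle walked back to it.
    """
    all_reac = set().union(*[s.reactants for s in graph.steps]) if graph.steps else set()
    all_prod = set().union(*[s.products for s in graph.steps]) if graph.steps else set()
    starts = sorted(all_reac - all_prod)
    rng = np.random.default_rng(seed)
    remaining = list(graph.steps)
    ordered: list[ReactionStep] = []

    def walk(frontier: set[int]):
        while True:
            nxt = [s for s in remaining if s.reactants & frontier]
            if not nxt:
                return
            for s in sorted(nxt, key=lambda s: s.arrow_id):
                remaining.remove(s)
                ordered.append(s)
                frontier = frontier | set(s.products)

    walk(set(starts))
    # cyclic leftovers: pick a seeded random entry node, walk around
    while remaining:
        entry = sorted(remaining, key=lambda s: s.arrow_id)
        s0 = entry[int(rng.integers(len(entry)))]
        remaining.remove(s0)
        ordered.append(s0)
        walk(set(s0.products))
    return ordered


def match_graphs(pred: ReactionGraph, gt: ReactionGraph,
                 iou_threshold: float = 0.5, seed: int = 0,
                 node_map: dict[int, int] | None = None) -> ConfusionCounts:
    """Compare reaction graphs step-by-step after node correspondence.

    ``node_map`` (pred id -> gt id) overrides the IoU-based node
    correspondence; when node ids already agree, an identity map over
    shared ids is used as a fallback for graphs without box geometry.
    """
    if node_map is None:
        have_boxes = any(i.get("bbox") is not None for i in pred.nodes.values()) \
            and any(i.get("bbox") is not None for i in gt.nodes.values())
        if have_boxes:
            node_map = _node_correspondence(pred, gt, iou_threshold)
        else:
            node_map = {i: i for i in pred.nodes if i in gt.nodes}

    gt_steps = _traversal_steps(gt, seed)
    pred_steps = _traversal_steps(pred, seed)

    unmatched_gt = list(gt_steps)
    tp = fp = 0
    for ps in pred_steps:
        reac = frozenset(node_map.get(i) for i in ps.reactants)
        prod = frozenset(node_map.get(i) for i in ps.products)
        hit = None
        for gs in unmatched_gt:
            if reac == gs.reactants and prod == gs.products:
                hit = gs
                break
        if hit is not None:
            unmatched_gt.remove(hit)
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fn=len(unmatched_gt), fp=fp)


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

def evaluation_report(per_class_counts: dict[str, ConfusionCounts],
                      iou_threshold: float = 0.5) -> dict:
    """Tabular report: per-deliverable counts plus formatted metrics."""
    rows = {}
    for name, c in per_class_counts.items():
        r, p, f = prf_metrics(c)
        rows[name] = {
            "tp": c.tp, "fn": c.fn, "fp": c.fp,
            "recall": r, "precision": p, "f_score": f,
            "recall_str": format_metric(r),
            "precision_str": format_metric(p),
            "f_score_str": format_metric(f),
        }
    return {"iou_threshold": iou_threshold, "rows": rows}
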