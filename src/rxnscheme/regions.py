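"""Detection of diagram / label / conditions regions.

Two interchangeable backends sit behind ``detect_regions``:

* an **oracle** backend that replays ground-truth annotation boxes
  (optionally perturbed by Gaussian box jitter, random drops and
  spurious boxes) — the harness for isolating the symbolic stages; and
* a **learned** backend: a reduced detector that groups nearby connected
  components into region proposals by morphological closing and scores
  each proposal patch with a small CNN, followed by per-class NMS.

The published full-scale recipe (Faster R-CNN with a ResNeXt-101
backbone, DIoU box loss with RPN/head weights 2.0/10.0, SGD at lr 0.001,
5000 iterations on 2000 generated schemes) is recorded in
``PUBLISHED_RECIPE`` as configuration; the reduced detector trains the
proposal classifier with the same optimizer family and learning rate at
desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.morphology import closing, disk
from skimage import measure
from skimage.transform import resize

from .geometry import BBox, BinaryImage, binarize, find_connected_components
from .engineer import SchemeAnnotation, CATEGORY_NAMES
from . import nn

REGION_CLASSES = ("diagram", "label", "conditions")
_CLASS_INDEX = {"background": 0, "diagram": 1, "label": 2, "conditions": 3}
_INDEX_CLASS = {v: k for k, v in _CLASS_INDEX.items()}

#: The full-scale training configuration of the reference detector,
#: kept as serialized defaults (not trained at desk scale).
PUBLISHED_RECIPE = {
    "architecture": "faster-rcnn",
    "backbone": "resnext-101",
    "box_loss": "diou",
    "rpn_box_loss_weight": 2.0,
    "head_box_loss_weight": 10.0,
    "optimizer": "sgd",
    "lr": 0.001,
    "iterations": 5000,
    "n_training_schemes": 2000,
    "transfer_learning": True,
}

REGION_PATCH = 32


@dataclass
class PanelRegion:
    """A classified image region with provenance."""

    bbox: BBox
    cls: str  # diagram | label | conditions
    score: float = 1.0
    provenance: str = "oracle"  # learned | oracle | postprocessed
    id: int = -1

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


# --------------------------------------------------------------------------
# oracle backend
# --------------------------------------------------------------------------

@dataclass
class OracleBackend:
    """Replays annotation boxes, optionally perturbed to emulate detector
    error: Gaussian jitter of box corners (sigma px), random drops, and
    spurious uniform boxes."""

    annotation: SchemeAnnotation
    jitter_sigma: float = 0.0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    seed: int = 0


@dataclass
class LearnedBackend:
    model: "RegionModel"
    score_threshold: float = 0.5
    nms_iou: float = 0.5


def _jitter_box(b: BBox, sigma: float, rng, w: int, h: int) -> BBox:
    d = rng.normal(0, sigma, 4)
    x0 = int(np.clip(round(b.x0 + d[0]), 0, w - 2))
    y0 = int(np.clip(round(b.y0 + d[1]), 0, h - 2))
    x1 = int(np.clip(round(b.x1 + d[2]), x0 + 1, w))
    y1 = int(np.clip(round(b.y1 + d[3]), y0 + 1, h))
    return BBox(x0, y0, x1, y1)


def detect_regions(image: np.ndarray, backend, config=None) -> list[PanelRegion]:
    """Detect diagram/label/conditions regions with the given backend."""
    if isinstance(backend, OracleBackend):
        ann = backend.annotation
        if ann is None:
            raise ValueError("oracle backend requires an annotation")
        rng = np.random.default_rng(backend.seed)
        out = []
        for r in ann.regions:
            if r.cls not in REGION_CLASSES:
                continue
            if backend.drop_rate and rng.random() < backend.drop_rate:
                continue
            b = r.bbox
            if backend.jitter_sigma:
                b = _jitter_box(b, backend.jitter_sigma, rng, ann.width, ann.height)
            out.append(PanelRegion(b, r.cls, 1.0, "oracle", id=r.id))
        if backend.spurious_rate:
            n_spur = rng.poisson(backend.spurious_rate)
            for k in range(n_spur):
                w = int(rng.integers(10, max(11, ann.width // 4)))
                h = int(rng.integers(10, max(11, ann.height // 4)))
                x = int(rng.integers(0, max(1, ann.width - w)))
                y = int(rng.integers(0, max(1, ann.height - h)))
                out.append(PanelRegion(BBox(x, y, x + w, y + h),
                                       REGION_CLASSES[k % 3], 1.0, "oracle",
                                       id=10_000 + k))
        return out
    if isinstance(backend, LearnedBackend):
        return _detect_learned(image, backend)
    raise TypeError(f"unknown backend {type(backend).__name__}")


# --------------------------------------------------------------------------
# learned backend
# --------------------------------------------------------------------------

def propose_regions(bin_img: BinaryImage, group_radius: int = 8,
                    min_area: int = 12) -> list[BBox]:
    """Group nearby components into region proposals via closing."""
    closed = closing(bin_img.mask, disk(group_radius))
    labels = measure.label(closed, connectivity=2)
    boxes = []
    for reg in measure.regionprops(labels):
        # tight box over the original ink inside the grouped blob
        rr = bin_img.mask[reg.bbox[0]:reg.bbox[2], reg.bbox[1]:reg.bbox[3]]
        sel = np.zeros_like(rr)
        sel[reg.coords[:, 0] - reg.bbox[0], reg.coords[:, 1] - reg.bbox[1]] = True
        ink = rr & sel
        if ink.sum() < min_area:
            continue
        ys, xs = np.nonzero(ink)
        boxes.append(BBox(reg.bbox[1] + int(xs.min()), reg.bbox[0] + int(ys.min()),
                          reg.bbox[1] + int(xs.max()) + 1, reg.bbox[0] + int(ys.max()) + 1))
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


def _region_patch(bin_img: BinaryImage, box: BBox) -> np.ndarray:
    crop = bin_img.mask[box.y0:box.y1, box.x0:box.x1].astype(np.float64)
    h, w = crop.shape
    side = max(h, w)
    sq = np.zeros((side, side))
    sq[(side - h) // 2:(side - h) // 2 + h, (side - w) // 2:(side - w) // 2 + w] = crop
    out = resize(sq, (REGION_PATCH, REGION_PATCH), order=1, anti_aliasing=side > REGION_PATCH)
    return np.clip(out, 0, 1)


class RegionModel:
    """Proposal-patch classifier: conv backbone + 4-way softmax head."""

    def __init__(self, channels: tuple[int, ...] = (8, 16, 32), seed: int = 0,
                 group_radius: int = 8):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.group_radius = group_radius
        self.backbone = nn.conv_backbone(self.channels, rng)
        self.head = nn.Dense(self.channels[-1], 4, rng)
        self.recipe = dict(PUBLISHED_RECIPE)
        self.history: list[float] = []

    def forward(self, x):
        feat = self.backbone.forward(x[:, None, :, :])
        return self.head.forward(feat)

    def backward(self, dy):
        self.backbone.backward(self.head.backward(dy))

    def params(self):
        return self.backbone.params() + self.head.params()

    def grads(self):
        return self.backbone.grads() + self.head.grads()

    def predict_proba(self, patches):
        return nn.softmax(self.forward(np.asarray(patches, dtype=np.float64)))

    def hash(self) -> str:
        return nn.params_hash(self.params())

    def save(self, path) -> None:
        nn.save_params(path, self.params())

    @classmethod
    def load(cls, path, channels=(8, 16, 32)) -> "RegionModel":
        m = cls(channels=channels)
        nn.load_params_into(path, m.params())
        return m


def nms(regions: list[PanelRegion], iou: float = 0.5) -> list[PanelRegion]:
    """Greedy per-class non-maximum suppression by score."""
    kept: list[PanelRegion] = []
    for cls in REGION_CLASSES:
        cand = sorted([r for r in regions if r.cls == cls],
                      key=lambda r: (-r.score, r.bbox.y0, r.bbox.x0))
        for r in cand:
            if all(r.bbox.iou(k.bbox) < iou for k in kept if k.cls == cls):
                kept.append(r)
    kept.sort(key=lambda r: (r.bbox.y0, r.bbox.x0))
    return kept


def _detect_learned(image: np.ndarray, backend: LearnedBackend) -> list[PanelRegion]:
    bin_img = binarize(image)
    boxes = propose_regions(bin_img, backend.model.group_radius)
    if not boxes:
        return []
    patches = np.stack([_region_patch(bin_img, b) for b in boxes])
    probs = backend.model.predict_proba(patches)
    out = []
    for b, p in zip(boxes, probs):
        k = int(np.argmax(p))
        if k == 0:
            continue
        score = float(p[k])
        if score >= backend.score_threshold:
            out.append(PanelRegion(b, _INDEX_CLASS[k], score, "learned"))
    out = nms(out, backend.nms_iou)
    for i, r in enumerate(out):
        r.id = i
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class RegionTrainConfig:
    iterations: int = 400
    lr: float = 1e-3  # matches the published optimizer lr
    batch_size: int = 32
    seed: int = 0
    channels: tuple[int, ...] = (8, 16, 32)
    group_radius: int = 8
    match_iou: float = 0.4


def _load_dataset(manifest_path) -> list[tuple[np.ndarray, SchemeAnnotation]]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as f:
        manifest = json.load(f)
    out = []
    for entry in manifest["schemes"]:
        img = np.asarray(Image.open(root / entry["image"]).convert("L"))
        with open(root / entry["graph"]) as f:
            ann = SchemeAnnotation.from_dict(json.load(f))
        out.append((img, ann))
    return out


def train_region_model(manifest_path, config: RegionTrainConfig | None = None) -> RegionModel:
    """Train the reduced region detector on a generated dataset.

    Proposals are matched to annotation boxes at IoU >= ``match_iou`` to
    obtain class targets (unmatched proposals become background); the
    classifier is optimized with SGD at the published learning rate.
    """
    config = config or RegionTrainConfig()
    data = _load_dataset(manifest_path)
    if not data:
        raise ValueError("empty dataset")
    X, y = [], []
    for img, ann in data:
        bin_img = binarize(img)
        gt = [(r.bbox, r.cls) for r in ann.regions if r.cls in REGION_CLASSES]
        for box in propose_regions(bin_img, config.group_radius):
            best_iou, best_cls = 0.0, "background"
            for gb, gc in gt:
                v = box.iou(gb)
                if v > best_iou:
                    best_iou, best_cls = v, gc
            if best_iou < config.match_iou:
                best_cls = "background"
            X.append(_region_patch(bin_img, box))
            y.append(_CLASS_INDEX[best_cls])
    X = np.stack(X)
    y = np.array(y)
    model = RegionModel(channels=config.channels, seed=config.seed,
                        group_radius=config.group_radius)
    if config.iterations == 0:
        return model
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.SGD(model.params(), lr=config.lr)
    n = len(y)
    for _it in range(config.iterations):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        logits = model.forward(X[idx])
        loss, dz = nn.ce_with_logits(logits, y[idx])
        model.backward(dz)
        opt.step(model.grads())
        model.history.append(loss)
    return model
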