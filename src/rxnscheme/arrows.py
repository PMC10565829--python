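"""Reaction-arrow detection: connected-component proposals and a
two-branch convolutional classifier.

Arrows are assumed to be isolated connected components (an arrow fused
to other ink is out of scope and will be missed).  Candidate components
pass a cheap geometric filter, are rendered into centered 64x64 patches,
and a small CNN with two heads scores them: a binary detector head ("is
this an arrow?") and a 4-way classifier head over arrow subtypes (solid,
curly, equilibrium, resonance).  Training minimizes

    L = lambda1 * BCE(detector) + lambda2 * CE(classifier),

with lambda1 = 10 and lambda2 = 1 by default; the classifier term is
masked out on non-arrow patches, where the subtype is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from scipy import ndimage

from .geometry import BinaryImage, ConnComp, find_connected_components
from . import nn

SUBTYPE_OF_LABEL = {1: "solid", 2: "curly", 3: "equilibrium", 4: "resonance"}
LABEL_OF_SUBTYPE = {v: k for k, v in SUBTYPE_OF_LABEL.items()}
PATCH_SIZE = 64


@dataclass
class ArrowPatch:
    """A centered, isotropically rescaled 64x64 patch of one component."""

    pixels: np.ndarray  # float64 (64, 64) in [0, 1]
    source: ConnComp | None = None


@dataclass
class Arrow:
    """A detected reaction arrow."""

    comp: ConnComp
    subtype: str | None
    score: float

    @property
    def bbox(self):
        return self.comp.bbox


@dataclass
class ProposalFilter:
    """Bounds for the component pre-filter ("simple criteria").

    Components qualify when their pixel count lies within
    [min_area, max_area_frac * image area] and they are either elongated
    (bbox max/min side ratio >= min_elongation) or sparse
    (area / bbox area <= max_fill).
    """

    min_area: int = 20
    max_area_frac: float = 0.05
    min_elongation: float = 2.0
    max_fill: float = 0.2


def propose_arrow_candidates(ccs: list[ConnComp], image_shape: tuple[int, int],
                             filt: ProposalFilter | None = None) -> list[ConnComp]:
    """Keep components that could plausibly be arrows; order preserved."""
    filt = filt or ProposalFilter()
    h, w = image_shape
    max_area = filt.max_area_frac * h * w
    out = []
    for cc in ccs:
        if not (filt.min_area <= cc.area <= max_area):
            continue
        sides = (cc.bbox.width, cc.bbox.height)
        elong = max(sides) / min(sides)
        fill = cc.area / cc.bbox.area
        if elong >= filt.min_elongation or fill <= filt.max_fill:
            out.append(cc)
    return out


def extract_patch(bin_img: BinaryImage | None, cc: ConnComp) -> ArrowPatch:
    """Render a component into a 64x64 patch.

    Only the component's own pixels are included, so adjacent ink never
    leaks in; the crop is padded to a square (aspect preserved) and
    resized.  ``bin_img`` is accepted for interface symmetry but the
    patch is rebuilt purely from the component's pixel set.
    """
    mask = cc.to_mask()
    h, w = mask.shape
    side = max(h, w)
    sq = np.zeros((side, side), dtype=np.float64)
    y0, x0 = (side - h) // 2, (side - w) // 2
    sq[y0:y0 + h, x0:x0 + w] = mask
    if side == PATCH_SIZE:
        out = sq
    else:
        out = resize(sq, (PATCH_SIZE, PATCH_SIZE), order=1, anti_aliasing=side > PATCH_SIZE)
    return ArrowPatch(np.clip(out, 0.0, 1.0), cc)


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def combined_arrow_loss(det_out: float, cls_out, label: int,
                        lambda1: float = 10.0, lambda2: float = 1.0) -> float:
    """Two-branch loss on probabilities for a single patch.

    ``det_out`` is P(arrow); ``cls_out`` a distribution over the four
    subtypes.  For label 0 (non-arrow) the classifier term is dropped.
    """
    det_out = float(det_out)
    if not 0.0 <= det_out <= 1.0:
        raise ValueError("det_out must be a probability in [0, 1]")
    if not 0 <= int(label) <= 4:
        raise ValueError("label must be in 0..4")
    is_arrow = 1.0 if label > 0 else 0.0
    p = det_out if is_arrow else 1.0 - det_out
    bce = -np.log(np.clip(p, 1e-300, None))
    loss = lambda1 * bce
    if label > 0:
        cls_out = np.asarray(cls_out, dtype=float)
        if cls_out.shape != (4,) or np.any(cls_out < 0) or np.any(cls_out > 1):
            raise ValueError("cls_out must be 4 probabilities in [0, 1]")
        loss += lambda2 * -np.log(np.clip(cls_out[label - 1], 1e-300, None))
    return float(loss)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclass
class ArrowTrainConfig:
    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 32
    lambda1: float = 10.0
    lambda2: float = 1.0
    seed: int = 0
    channels: tuple[int, ...] = (8, 16, 32)
    augment: bool = True


class ArrowModel:
    """Small conv backbone with a detector head and a subtype head."""

    def __init__(self, channels: tuple[int, ...] = (8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.backbone = nn.conv_backbone(self.channels, rng)
        feat = self.channels[-1]
        self.det_head = nn.Dense(feat, 1, rng)
        # "two additional fully connected layers" for the subtype branch
        self.cls_hidden = nn.Dense(feat, feat, rng)
        self.cls_relu = nn.ReLU()
        self.cls_head = nn.Dense(feat, 4, rng)

    # ---- forward/backward ----
    def forward(self, x: np.ndarray):
        """x: (N, 64, 64) -> (det_logits (N,), cls_logits (N, 4))."""
        feat = self.backbone.forward(x[:, None, :, :])
        det = self.det_head.forward(feat).ravel()
        h = self.cls_relu.forward(self.cls_hidden.forward(feat))
        cls = self.cls_head.forward(h)
        self._n = x.shape[0]
        return det, cls

    def backward(self, ddet: np.ndarray, dcls: np.ndarray):
        dfeat = self.det_head.backward(ddet.reshape(self._n, 1))
        dh = self.cls_head.backward(dcls)
        dfeat = dfeat + self.cls_hidden.backward(self.cls_relu.backward(dh))
        self.backbone.backward(dfeat)

    def params(self):
        return (self.backbone.params() + self.det_head.params()
                + self.cls_hidden.params() + self.cls_head.params())

    def grads(self):
        return (self.backbone.grads() + self.det_head.grads()
                + self.cls_hidden.grads() + self.cls_head.grads())

    # ---- inference ----
    def predict(self, patches: np.ndarray):
        """Returns (P(arrow) (N,), subtype distribution (N, 4))."""
        det, cls = self.forward(np.asarray(patches, dtype=np.float64))
        return nn.sigmoid(det), nn.softmax(cls)

    def hash(self) -> str:
        return nn.params_hash(self.params())

    def save(self, path) -> None:
        nn.save_params(path, self.params())

    @classmethod
    def load(cls, path, channels: tuple[int, ...] = (8, 16, 32)) -> "ArrowModel":
        model = cls(channels=channels)
        nn.load_params_into(path, model.params())
        return model


def _augment_patch(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Light train-time jitter: small affine shift/rotation + optional blur."""
    out = patch
    ang = rng.uniform(-5, 5)
    if abs(ang) > 0.1:
        out = ndimage.rotate(out, ang, reshape=False, order=1, mode="constant")
    shift = rng.integers(-2, 3, size=2)
    if np.any(shift):
        out = ndimage.shift(out, shift, order=0, mode="constant")
    if rng.random() < 0.3:
        out = ndimage.gaussian_filter(out, rng.uniform(0.3, 0.8))
    return np.clip(out, 0.0, 1.0)


def train_arrow_model(dataset: list[tuple[np.ndarray, int]],
                      config: ArrowTrainConfig | None = None) -> ArrowModel:
    """Train the two-branch model on (64x64 patch, label 0..4) pairs.

    Follows the published recipe at reduced scale: Adam, learning rate
    0.001, 20 epochs, combined loss with lambda1=10, lambda2=1.  The
    subtype branch receives no gradient from non-arrow patches.
    """
    config = config or ArrowTrainConfig()
    labels = np.array([int(l) for _, l in dataset])
    if len(dataset) == 0 or (labels > 0).all() or (labels == 0).all():
        raise ValueError("dataset must contain both arrow and non-arrow patches")
    X = np.stack([np.asarray(p, dtype=np.float64) for p, _ in dataset])
    model = ArrowModel(channels=config.channels, seed=config.seed)
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.params(), lr=config.lr)
    n = len(dataset)
    model.history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            if config.augment:
                xb = np.stack([_augment_patch(x, rng) for x in xb])
            yb = labels[idx]
            det, cls = model.forward(xb)
            l_det, ddet = nn.bce_with_logits(det, (yb > 0).astype(float))
            mask = yb > 0
            l_cls, dcls = nn.ce_with_logits(cls, np.maximum(yb - 1, 0), mask)
            loss = config.lambda1 * l_det + config.lambda2 * l_cls
            model.backward(config.lambda1 * ddet, config.lambda2 * dcls)
            opt.step(model.grads())
            ep_loss += loss * len(idx)
        model.history.append(ep_loss / n)
    return model


def detect_arrows(bin_img: BinaryImage, model: ArrowModel,
                  threshold: float = 0.5,
                  filt: ProposalFilter | None = None,
                  ccs: list[ConnComp] | None = None) -> list[Arrow]:
    """Full detection pipeline: components -> proposals -> patches -> model."""
    if ccs is None:
        ccs = find_connected_components(bin_img)
    cands = propose_arrow_candidates(ccs, (bin_img.height, bin_img.width), filt)
    if not cands:
        return []
    patches = np.stack([extract_patch(bin_img, cc).pixels for cc in cands])
    p_det, p_cls = model.predict(patches)
    out = []
    for cc, pd, pc in zip(cands, p_det, p_cls):
        if pd >= threshold:
            out.append(Arrow(cc, SUBTYPE_OF_LABEL[int(np.argmax(pc)) + 1], float(pd)))
    return out


# --------------------------------------------------------------------------
# synthetic patch dataset
# --------------------------------------------------------------------------

def build_patch_dataset(n_arrows: int = 100, n_negatives: int = 100,
                        seed: int = 0) -> list[tuple[np.ndarray, int]]:
    """Patches sampled from generated glyphs: arrows of all four subtypes
    as positives; diagram fragments, pseudo-text and negative symbols as
    class-0 patches."""
    from . import engineer
    from .geometry import binarize

    rng = np.random.default_rng(seed)
    data: list[tuple[np.ndarray, int]] = []
    aug = engineer.AugmentParams(scale=(0.85, 1.15), rot_deg=(-8, 8), p_blur=0.3)

    def glyph_to_patch(g):
        mask = g.mask
        cc = ConnComp(np.argwhere(mask))
        return extract_patch(None, cc).pixels

    for i in range(n_arrows):
        st = engineer.ARROW_SUBTYPES[i % 4]
        g = engineer.make_arrow_glyph(rng, st)
        g = engineer.augment_glyph(g, rng, aug)
        data.append((glyph_to_patch(g), LABEL_OF_SUBTYPE[st]))
    makers = (
        lambda: engineer.make_diagram_glyph(rng, with_superatom=False),
        lambda: engineer.make_label_glyph(rng),
        lambda: engineer.make_conditions_glyph(rng),
        lambda: engineer.make_negative_glyph(rng),
    )
    for i in range(n_negatives):
        g = makers[i % len(makers)]()
        g = engineer.augment_glyph(g, rng, aug)
        # take the largest connected piece so each patch is one component
        b = binarize(255 - g.mask.astype(np.uint8) * 255)
        comps = find_connected_components(b)
        cc = max(comps, key=lambda c: c.area)
        data.append((extract_patch(None, cc).pixels, 0))
    return data
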