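"""Pixel-space geometry primitives shared by every pipeline stage.

Coordinate convention (fixed across the package): 0-based integer pixel
coordinates, origin at the top-left corner, ``x`` increasing rightward and
``y`` increasing downward.  Bounding boxes are half-open,
``[x0, x1) x [y0, y1)``, so ``width = x1 - x0`` and a box never has zero
area.  Annotation files serialize boxes in the COCO dialect
``[x0, y0, width, height]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class BBox:
    """Axis-aligned half-open bounding box in pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def to_coco(self) -> list[int]:
        return [self.x0, self.y0, self.width, self.height]

    @classmethod
    def from_coco(cls, xywh) -> "BBox":
        x, y, w, h = (int(round(v)) for v in xywh)
        return cls(x, y, x + w, y + h)

    def intersects(self, other: "BBox") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    def intersection_area(self, other: "BBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return w * h if (w > 0 and h > 0) else 0

    def iou(self, other: "BBox") -> float:
        inter = self.intersection_area(other)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)

    def union(self, other: "BBox") -> "BBox":
        return BBox(
            min(self.x0, other.x0),
            min(self.y0, other.y0),
            max(self.x1, other.x1),
            max(self.y1, other.y1),
        )

    def expand(self, margin: int) -> "BBox":
        return BBox(self.x0 - margin, self.y0 - margin, self.x1 + margin, self.y1 + margin)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class BinaryImage:
    """Binarized scheme raster; ``mask`` is True where there is ink."""

    mask: np.ndarray  # bool, shape (height, width)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ConnComp:
    """One 8-connected component of foreground ink.

    ``pixels`` holds (row, col) coordinates; ``centroid`` is (x, y) to match
    the package-wide convention.
    """

    pixels: np.ndarray  # int, shape (n, 2) as (row, col)
    bbox: BBox = field(init=False)
    area: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1:
            raise ValueError("component needs >= 1 pixel")
        rows, cols = self.pixels[:, 0], self.pixels[:, 1]
        self.bbox = BBox(int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)
        self.area = int(self.pixels.shape[0])
        self.centroid = (float(cols.mean()), float(rows.mean()))

    def to_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Render the component as a boolean mask.

        With ``shape=None`` the mask is cropped to the component's bbox.
        """
        if shape is None:
            h, w = self.bbox.height, self.bbox.width
            mask = np.zeros((h, w), dtype=bool)
            mask[self.pixels[:, 0] - self.bbox.y0, self.pixels[:, 1] - self.bbox.x0] = True
        else:
            mask = np.zeros(shape, dtype=bool)
            mask[self.pixels[:, 0], self.pixels[:, 1]] = True
        return mask


def binarize(image: np.ndarray) -> BinaryImage:
    """Binarize a grayscale raster so that dark ink becomes foreground.

    Uses a global Otsu threshold; reaction schemes are high-contrast line
    art on a light background, for which a global threshold is adequate.
    A perfectly uniform image yields an empty foreground with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:  # collapse RGB(A) to luma
        image = image[..., :3].mean(axis=2)
    image = image.astype(np.float64)
    lo, hi = image.min(), image.max()
    if lo == hi:
        warnings.warn("uniform image: no foreground", stacklevel=2)
        return BinaryImage(np.zeros(image.shape, dtype=bool))
    thr = threshold_otsu(image)
    return BinaryImage(image < thr)


def find_connected_components(bin_img: BinaryImage) -> list[ConnComp]:
    """8-connected component decomposition, sorted in reading order.

    Components are disjoint and jointly cover the whole foreground; the
    (bbox.y0, bbox.x0) sort makes downstream tie-breaks reproducible.
    """
    labels = measure.label(bin_img.mask, connectivity=2)
    comps = []
    for region in measure.regionprops(labels):
        comps.append(ConnComp(region.coords))
    comps.sort(key=lambda c: (c.bbox.y0, c.bbox.x0))
    return comps


def separation(a: BBox, b: BBox) -> float:
    """Minimal Euclidean distance between two boxes' point sets.

    Zero iff the (closed) boxes touch or overlap; symmetric by construction.
    """
    dx = max(a.x0 - b.x1, b.x0 - a.x1, 0)
    dy = max(a.y0 - b.y1, b.y0 - a.y1, 0)
    return float(np.hypot(dx, dy))
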