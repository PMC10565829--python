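"""Arrow geometry: orientation, center of mass, and endpoints.

For headed arrows (solid, equilibrium, resonance) the orientation comes
from a minimal rotated bounding rectangle fitted to the pixel contour
(rotating calipers over the convex hull); the arrowhead makes the pixel
center of mass sit off the rectangle center along the long axis, which
tells the product side from the reactant side.  Equilibrium and
resonance arrows are oriented the same way but flagged bidirectional.

Curly arrows curve, so a rotated rectangle does not capture their
direction.  Instead their 2-4 physical endpoints are recovered by
probing thin rectangles along the four sides of the (unrotated)
bounding box, merging duplicate picks, and rejecting mid-arc picks with
a connectivity test; a perpendicular scanline profile then separates
arrowheads ("hooks") from plain stroke termini ("ends").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .geometry import BBox, separation
from .arrows import Arrow


# --------------------------------------------------------------------------
# minimal rotated rectangle
# --------------------------------------------------------------------------

def min_area_rect(points: np.ndarray):
    """Minimum-area oriented rectangle over 2-D points (x, y).

    Returns (center, length, width, angle_deg) with length >= width and
    angle the long-axis direction in [0, 180) degrees.  Degenerate
    (collinear) point sets fall back to a principal-axis fit.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points")
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:
        hull = None
    if hull is None:  # collinear: principal axis
        c = pts.mean(axis=0)
        d = pts - c
        u = d[np.argmax(np.abs(d).sum(axis=1))]
        u = u / (np.linalg.norm(u) or 1.0)
        proj = d @ u
        length = float(proj.max() - proj.min()) + 1.0
        center = c + u * (proj.max() + proj.min()) / 2
        ang = float(np.degrees(np.arctan2(u[1], u[0]))) % 180.0
        return center, length, 1.0, ang
    best = None
    n = len(hull)
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        norm = np.linalg.norm(e)
        if norm == 0:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        pu = hull @ u
        pv = hull @ v
        du, dv = pu.max() - pu.min(), pv.max() - pv.min()
        area = du * dv
        if best is None or area < best[0]:
            cu, cv = (pu.max() + pu.min()) / 2, (pv.max() + pv.min()) / 2
            best = (area, cu * u + cv * v, du, dv, u, v)
    _, center, du, dv, u, v = best
    if du >= dv:
        length, width, axis = du, dv, u
    else:
        length, width, axis = dv, du, v
    ang = float(np.degrees(np.arctan2(axis[1], axis[0]))) % 180.0
    return center, float(length) + 1.0, float(width) + 1.0, ang


@dataclass
class ArrowFrame:
    """Recovered geometry of one arrow."""

    arrow: Arrow
    center: np.ndarray          # rotated-rect center (x, y)
    length: float               # long side
    width: float                # short side
    angle_deg: float            # long-axis angle, [0, 180)
    com: np.ndarray             # pixel center of mass (x, y)
    direction: np.ndarray       # unit vector toward the product side
    head_defined: bool          # False when COM offset is negligible
    bidirectional: bool
    endpoints: list[np.ndarray] = field(default_factory=list)
    endpoint_tags: list[str] = field(default_factory=list)  # hook | end | unknown
    ref_hook: np.ndarray | None = None
    ref_end: np.ndarray | None = None


_HEAD_OFFSET_FRAC = 0.02  # min |COM offset| / length for a defined head side


def fit_arrow_frame(arrow: Arrow) -> ArrowFrame:
    """Orient an arrow from its rotated rectangle and center of mass."""
    pts = arrow.comp.pixels[:, ::-1].astype(float)  # (x, y)
    if len(pts) < 2:
        raise ValueError("degenerate arrow: < 2 pixels")
    center, length, width, ang = min_area_rect(pts)
    com = pts.mean(axis=0)
    axis = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
    offset = float((com - center) @ axis)
    head_defined = abs(offset) > _HEAD_OFFSET_FRAC * length
    if head_defined:
        direction = axis if offset > 0 else -axis
    else:
        # canonical orientation: rightward, or downward for vertical arrows
        direction = axis if (axis[0] > 1e-9 or (abs(axis[0]) <= 1e-9 and axis[1] > 0)) \
            else -axis
    bidir = arrow.subtype in ("equilibrium", "resonance")
    half = direction * length / 2
    frame = ArrowFrame(
        arrow=arrow, center=center, length=length, width=width, angle_deg=ang,
        com=com, direction=direction, head_defined=head_defined, bidirectional=bidir,
        endpoints=[center + half, center - half],
        endpoint_tags=["hook", "end"] if head_defined else ["unknown", "unknown"],
    )
    if head_defined:
        frame.ref_hook, frame.ref_end = frame.endpoints[0], frame.endpoints[1]
    return frame


# --------------------------------------------------------------------------
# curly-arrow endpoints
# --------------------------------------------------------------------------

def _probe_regions(h: int, w: int, f: float):
    """Four probe slices (name, row slice, col slice) along the bbox sides."""
    dw = max(1, int(round(f * w)))
    dh = max(1, int(round(f * h)))
    return [
        ("left", slice(0, h), slice(0, dw)),
        ("right", slice(0, h), slice(w - dw, w)),
        ("top", slice(0, dh), slice(0, w)),
        ("bottom", slice(h - dh, h), slice(0, w)),
    ]


def find_arrow_endpoints(arrow: Arrow, probe_frac: float = 0.2,
                         merge_radius: float | None = None) -> list[np.ndarray]:
    """Endpoints of a (typically curly) arrow, image coordinates (x, y).

    Probes the four bbox sides for extremal pixels, merges picks closer
    than the merge radius (one physical end spanning two probes), then
    drops mid-arc picks: erasing a probe region around a true endpoint
    leaves the arrow connected, while erasing around a mid-arc pick
    splits it in two.
    """
    mask = arrow.comp.to_mask()
    h, w = mask.shape
    b = arrow.bbox
    if merge_radius is None:
        merge_radius = max(5.0, 0.1 * float(np.hypot(w, h)))
    picks = []  # (point rc, probe index)
    probes = _probe_regions(h, w, probe_frac)
    for pi, (name, rs, cs) in enumerate(probes):
        sub = mask[rs, cs]
        if not sub.any():
            continue
        rr, cc = np.nonzero(sub)
        rr = rr + rs.start
        cc = cc + cs.start
        if name == "left":
            k = np.lexsort((rr, cc))[0]          # min col, then min row
        elif name == "right":
            k = np.lexsort((rr, -cc))[0]         # max col, then min row
        elif name == "top":
            k = np.lexsort((cc, rr))[0]          # min row, then min col
        else:
            k = np.lexsort((cc, -rr))[0]         # max row, then min col
        picks.append((np.array([rr[k], cc[k]], dtype=float), pi))

    # stage 1: merge near-duplicate picks
    merged = []
    for p, pi in picks:
        if all(np.linalg.norm(p - q) > merge_radius for q, _ in merged):
            merged.append((p, pi))

    # stage 2: connectivity test against mid-arc picks.  The erasure is
    # restricted to the probe region near the pick: deleting ink around a
    # true endpoint leaves the arrow connected, while deleting around a
    # mid-arc pick splits it in two.
    survivors = []
    for p, pi in merged:
        _, rs, cs = probes[pi]
        depth = (rs.stop - rs.start) if pi >= 2 else (cs.stop - cs.start)
        window = max(merge_radius, depth)
        rr, cc = np.nonzero(mask)
        near = (np.abs(rr - p[0]) <= window) & (np.abs(cc - p[1]) <= window)
        erased = mask.copy()
        erased[rr[near], cc[near]] = False
        if not erased.any():
            survivors.append(p)
            continue
        n_comp = measure.label(erased, connectivity=2).max()
        if n_comp <= 1:
            survivors.append(p)

    # final dedup: a strongly curving terminus can leave two survivors from
    # different probes; cluster at probe-depth scale and keep the member
    # with the least surrounding ink (the actual stroke terminus)
    dw = max(1, int(round(probe_frac * w)))
    dh = max(1, int(round(probe_frac * h)))
    r3 = max(merge_radius, dw, dh) + 2

    def local_ink(q):
        rr = mask[max(0, int(q[0]) - 3):int(q[0]) + 4,
                  max(0, int(q[1]) - 3):int(q[1]) + 4]
        return int(rr.sum())

    final: list[np.ndarray] = []
    for p in survivors:
        clustered = False
        for k, q in enumerate(final):
            if np.linalg.norm(p - q) <= r3:
                if local_ink(p) < local_ink(q):
                    final[k] = p
                clustered = True
                break
        if not clustered:
            final.append(p)
    if len(final) < 2:
        raise ValueError("unparseable arrow: fewer than 2 endpoints survive")
    # (x, y) in full-image coordinates
    return [np.array([c + b.x0, r + b.y0]) for r, c in final]


# --------------------------------------------------------------------------
# hook / end classification
# --------------------------------------------------------------------------

def _scanline_profile(pts: np.ndarray, endpoint: np.ndarray, u: np.ndarray,
                      t_max: float, lateral: float) -> np.ndarray:
    """Pixel counts in unit-width scanlines perpendicular to ``u``,
    moving inward from ``endpoint``."""
    d = pts - endpoint
    proj = d @ u
    perp = np.abs(d @ np.array([-u[1], u[0]]))
    counts = []
    t = 1.0
    while t <= t_max:
        counts.append(int(((proj >= t - 0.5) & (proj < t + 0.5) & (perp <= lateral)).sum()))
        t += 1.0
    return np.array(counts)


def classify_endpoint(arrow: Arrow, endpoint: np.ndarray,
                      cv_threshold: float = 0.25) -> str:
    """'end' when the perpendicular scan profile is near-constant
    (coefficient of variation below the threshold over the first 30% of
    the stroke), else 'hook' (an arrowhead widens the profile)."""
    pts = arrow.comp.pixels[:, ::-1].astype(float)
    b = arrow.bbox
    diag = float(np.hypot(b.width, b.height))
    r_loc = max(8.0, 0.15 * diag)
    local = pts[np.linalg.norm(pts - endpoint, axis=1) <= r_loc]
    if len(local) < 3:
        return "end"
    # inward line direction from the local centroid offset; this tracks the
    # stroke even at a filled arrowhead, where a principal-axis fit can
    # align with the head base instead of the shaft
    u = local.mean(axis=0) - endpoint
    n = np.linalg.norm(u)
    if n < 1e-9:
        return "end"
    u = u / n
    t_max = max(6.0, 0.3 * diag)
    counts = _scanline_profile(pts, endpoint, u, t_max, lateral=8.0)
    counts = counts[counts > 0]
    if len(counts) < 3:
        return "end"
    cv = counts.std() / counts.mean()
    return "end" if cv < cv_threshold else "hook"


def classify_endpoints(arrow: Arrow, endpoints: list[np.ndarray],
                       diagrams: list | None = None,
                       cv_threshold: float = 0.25,
                       nearby_factor: float = 1.5) -> ArrowFrame:
    """Tag endpoints as hooks/ends and pick the reference (hook, end)
    pair with the largest diagrams nearby (the main product / reactant
    of the step).  ``diagrams`` are PanelRegions; when absent or when
    every endpoint classifies identically, tags fall back to the
    rotated-rectangle axis with a warning."""
    frame = fit_arrow_frame(arrow)
    tags = [classify_endpoint(arrow, e, cv_threshold) for e in endpoints]
    if len(set(tags)) < 2:
        warnings.warn("endpoints classify identically; falling back to frame axis",
                      stacklevel=2)
        return frame
    frame.endpoints = list(endpoints)
    frame.endpoint_tags = tags

    def nearby_area(pt: np.ndarray) -> float:
        if not diagrams:
            return 0.0
        x, y = int(round(pt[0])), int(round(pt[1]))
        pb = BBox(x, y, x + 1, y + 1)
        areas = [d.bbox.area for d in diagrams
                 if separation(pb, d.bbox) < nearby_factor * frame.length]
        return float(max(areas, default=0.0))

    hooks = [(e, nearby_area(e)) for e, t in zip(endpoints, tags) if t == "hook"]
    ends = [(e, nearby_area(e)) for e, t in zip(endpoints, tags) if t == "end"]
    frame.ref_hook = max(hooks, key=lambda x: x[1])[0]
    frame.ref_end = max(ends, key=lambda x: x[1])[0]
    mid = np.array(arrow.bbox.center)
    d = frame.ref_hook - mid
    n = np.linalg.norm(d)
    if n > 1e-9:
        frame.direction = d / n
        frame.head_defined = True
    return frame


def analyze_arrow(arrow: Arrow, diagrams: list | None = None) -> ArrowFrame:
    """Frame fit plus, for curly arrows, endpoint recovery/classification."""
    if arrow.subtype == "curly":
        try:
            endpoints = find_arrow_endpoints(arrow)
            return classify_endpoints(arrow, endpoints, diagrams)
        except ValueError:
            warnings.warn("curly endpoint recovery failed; using frame axis",
                          stacklevel=2)
    return fit_arrow_frame(arrow)


def scan_directions(frame: ArrowFrame) -> tuple[np.ndarray, np.ndarray]:
    """(reactant direction, product direction) unit vectors for scanning.

    Curly arrows use the slopes from the bbox midpoint to the reference
    end and hook; headed arrows use the +-long-axis ordered by the COM
    offset.  With an undefined head (symmetric arrow) the canonical
    reading-order direction stands in."""
    if frame.ref_hook is not None and frame.ref_end is not None \
            and frame.arrow.subtype == "curly":
        mid = np.array(frame.arrow.bbox.center)
        prod = frame.ref_hook - mid
        reac = frame.ref_end - mid
        pn, rn = np.linalg.norm(prod), np.linalg.norm(reac)
        if pn > 1e-9 and rn > 1e-9:
            return reac / rn, prod / pn
    return -frame.direction, frame.direction
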