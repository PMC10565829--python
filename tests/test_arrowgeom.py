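"""Arrow orientation, curly endpoints, hook/end classification."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from rxnscheme import fit_arrow_frame, find_arrow_endpoints, classify_endpoints
from rxnscheme.arrows import Arrow
from rxnscheme.arrowgeom import classify_endpoint, min_area_rect, scan_directions
from rxnscheme.engineer import (Glyph, _line, _thicken, _tight,
                                glyph_pointing, make_arrow_glyph,
                                make_curly_stroke)
from rxnscheme.geometry import BBox, ConnComp
from rxnscheme.regions import PanelRegion


def to_arrow(mask, subtype="curly"):
    return Arrow(ConnComp(np.argwhere(mask)), subtype, 1.0)


def skeleton_endpoints(mask):
    """Brute-force oracle: skeleton pixels with exactly one neighbor."""
    sk = skeletonize(mask)
    nb = ndi.convolve(sk.astype(int), np.ones((3, 3)), mode="constant")
    return np.argwhere(sk & (nb == 2))[:, ::-1].astype(float)  # (x, y)


class TestArrowFrame:
    def test_headless_shaft_com_centered_and_flagged(self):
        mask = np.zeros((5, 100), dtype=bool)
        mask[2, :] = True
        frame = fit_arrow_frame(to_arrow(mask, "solid"))
        assert not frame.head_defined
        assert frame.com[0] == pytest.approx(49.5)

    def test_com_offset_marks_head_side(self):
        rng = np.random.default_rng(0)
        g = make_arrow_glyph(rng, "solid")
        arrow = to_arrow(g.mask, "solid")
        frame = fit_arrow_frame(arrow)
        # pixel-mean oracle
        pts = arrow.comp.pixels[:, ::-1].astype(float)
        assert np.allclose(frame.com, pts.mean(axis=0))
        assert frame.head_defined
        assert frame.direction[0] > 0.9  # head drawn on the right

    def test_rotation_equivariance_45_degrees(self):
        rng = np.random.default_rng(0)
        g = make_arrow_glyph(rng, "solid")
        f0 = fit_arrow_frame(to_arrow(g.mask, "solid"))
        ang = np.radians(45)
        g45 = glyph_pointing(g, (np.cos(ang), np.sin(ang)))
        f45 = fit_arrow_frame(to_arrow(g45.mask, "solid"))
        d = (f45.angle_deg - f0.angle_deg) % 180
        assert min(d, 180 - d) == pytest.approx(45, abs=2)

    def test_quarter_turn_equivariance(self):
        """Frames of 90-degree rotated copies agree modulo 180 degrees."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = make_curly_stroke(rng)
            f0 = fit_arrow_frame(to_arrow(g.mask))
            f90 = fit_arrow_frame(to_arrow(np.rot90(g.mask)))
            d = (f90.angle_deg - f0.angle_deg) % 180
            assert min(d, 180 - d) == pytest.approx(90, abs=2) or \
                f0.width / f0.length > 0.95  # near-square fits are angle-free

    def test_single_pixel_arrow_rejected(self):
        with pytest.raises(ValueError):
            fit_arrow_frame(to_arrow(np.ones((1, 1), dtype=bool)))

    def test_com_lies_inside_bbox(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = make_curly_stroke(rng)
            a = to_arrow(g.mask)
            f = fit_arrow_frame(a)
            assert a.bbox.x0 <= f.com[0] < a.bbox.x1
            assert a.bbox.y0 <= f.com[1] < a.bbox.y1

    def test_min_area_rect_matches_known_rectangle(self):
        pts = np.array([[x, y] for x in range(30) for y in range(10)], float)
        _, length, width, ang = min_area_rect(pts)
        assert length == pytest.approx(30, abs=0.5)
        assert width == pytest.approx(10, abs=0.5)
        assert ang % 180 == pytest.approx(0, abs=1e-6)


class TestFindEndpoints:
    def test_straight_stroke_ends_left_and_right(self):
        mask = np.zeros((4, 80), dtype=bool)
        mask[1:3, :] = True
        eps = find_arrow_endpoints(to_arrow(mask))
        xs = sorted(p[0] for p in eps)
        assert len(eps) == 2
        assert xs[0] == 0 and xs[-1] == 79

    def test_l_shape_has_two_free_ends(self):
        mask = np.zeros((60, 60), dtype=bool)
        _line(mask, 5, 5, 5, 50)
        _line(mask, 5, 50, 50, 50)
        mask = _thicken(mask, 1)
        a = to_arrow(_tight(mask))
        eps = find_arrow_endpoints(a)
        oracle = skeleton_endpoints(a.comp.to_mask())
        oracle += [a.bbox.x0, a.bbox.y0]
        assert len(eps) == len(oracle) == 2
        for e in eps:
            assert min(np.linalg.norm(e - o) for o in oracle) <= 8

    def test_midarc_bulge_removed_by_connectivity_filter(self):
        # shallow arc: its apex touches the top bbox side mid-arc
        mask = np.zeros((90, 90), dtype=bool)
        t = np.linspace(np.pi / 4, 3 * np.pi / 4, 70)
        for (r0, c0), (r1, c1) in zip(
                np.c_[70 - 60 * np.sin(t[:-1]), 45 + 60 * np.cos(t[:-1])],
                np.c_[70 - 60 * np.sin(t[1:]), 45 + 60 * np.cos(t[1:])]):
            _line(mask, r0, c0, r1, c1)
        mask = _tight(_thicken(mask, 1))
        eps = find_arrow_endpoints(to_arrow(mask))
        assert len(eps) == 2
        # both picks sit near the bottom corners, none at the apex
        h = mask.shape[0]
        for e in eps:
            assert e[1] > h * 0.6

    def test_skeleton_oracle_agreement_on_100_strokes(self):
        ok = 0
        for i in range(100):
            rng = np.random.default_rng(5000 + i)
            g = make_curly_stroke(rng)
            a = to_arrow(g.mask)
            oracle = skeleton_endpoints(g.mask) + [a.bbox.x0, a.bbox.y0]
            try:
                eps = find_arrow_endpoints(a)
            except ValueError:
                continue
            if len(eps) == len(oracle) and all(
                    min(np.linalg.norm(e - o) for o in oracle) <= 8 for e in eps):
                ok += 1
        assert ok >= 95

    def test_unparseable_blob_raises(self):
        # a compact blob: every probe pick merges into a single cluster,
        # leaving fewer than the two endpoints an arrow must have
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            find_arrow_endpoints(to_arrow(mask))


class TestClassifyEndpoints:
    @staticmethod
    def headed_shaft():
        """Horizontal shaft with a filled V-head on the right."""
        from skimage import draw as skdraw
        mask = np.zeros((24, 90), dtype=bool)
        mask[11:13, 0:80] = True
        rr, cc = skdraw.polygon([12, 5, 19], [89, 76, 76], shape=mask.shape)
        mask[rr, cc] = True
        return _tight(mask)

    def test_plain_terminus_is_end_by_scanline_counts(self):
        mask = np.zeros((6, 70), dtype=bool)
        mask[2:4, :] = True
        a = to_arrow(mask)
        assert classify_endpoint(a, np.array([0.0, 2.5])) == "end"

    def test_v_head_terminus_is_hook(self):
        mask = self.headed_shaft()
        a = to_arrow(mask)
        # scanline-count oracle: pixel count per column grows inside the head
        cols = mask.sum(axis=0)
        assert cols[-6] > cols[10]  # the head really widens
        eps = sorted(find_arrow_endpoints(a), key=lambda p: p[0])
        assert classify_endpoint(a, eps[-1]) == "hook"
        assert classify_endpoint(a, eps[0]) == "end"

    def test_reference_pair_prefers_largest_nearby_diagram(self):
        mask = self.headed_shaft()
        a = to_arrow(mask)
        eps = find_arrow_endpoints(a)
        small = PanelRegion(BBox(-40, 0, -18, 23), "diagram", 1.0, "oracle")
        big = PanelRegion(BBox(100, -8, 140, 30), "diagram", 1.0, "oracle")
        frame = classify_endpoints(a, eps, [small, big])
        assert frame.ref_hook is not None and frame.ref_end is not None
        assert frame.ref_hook[0] > frame.ref_end[0]  # hook at the headed side
        reac, prod = scan_directions(frame)
        assert prod[0] > 0 > reac[0]

    def test_identical_classes_fall_back_to_frame_axis(self):
        mask = np.zeros((4, 80), dtype=bool)
        mask[1:3, :] = True
        a = to_arrow(mask)
        eps = find_arrow_endpoints(a)
        with pytest.warns(UserWarning):
            frame = classify_endpoints(a, eps, [])
        assert frame.endpoint_tags in (["hook", "end"], ["unknown", "unknown"])
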