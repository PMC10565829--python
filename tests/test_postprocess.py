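"""Diagram completion and text reclassification/pairing."""

import numpy as np
import pytest

from rxnscheme import (
    Arrow,
    CompletionParams,
    DirectionalityParams,
    OracleBackend,
    PanelRegion,
    SchemaSpec,
    binarize,
    complete_diagram,
    compose_scheme,
    detect_regions,
    find_connected_components,
    pair_regions,
    reclassify_text_region,
)
from rxnscheme.geometry import BBox, ConnComp
from conftest import mask_to_image


def scene(mask):
    b = binarize(mask_to_image(mask))
    return b, find_connected_components(b)


def hbar_arrow(x0, y, x1):
    """A minimal synthetic horizontal arrow stand-in for pairing geometry."""
    pix = [(yy, xx) for xx in range(x0, x1) for yy in (y, y + 1)]
    return Arrow(ConnComp(np.array(pix)), "solid", 1.0)


class TestCompleteDiagram:
    def test_isolated_component_is_fixed_point(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:40, 20:40] = True
        b, ccs = scene(mask)
        region = PanelRegion(BBox(18, 18, 42, 42), "diagram", 1.0, "oracle")
        out = complete_diagram(region, b, ccs)
        assert out.bbox == BBox(20, 20, 40, 40)
        assert out.provenance == "postprocessed"

    def test_detached_superatom_absorbed(self):
        # skeleton blob + text cluster 6 px away; kernel radius >= 6
        mask = np.zeros((60, 90), dtype=bool)
        mask[20:40, 10:40] = True
        mask[26:34, 46:60] = True  # detached cluster, gap = 6
        b, ccs = scene(mask)
        region = PanelRegion(BBox(10, 20, 40, 40), "diagram", 1.0, "oracle")
        out = complete_diagram(region, b, ccs,
                               CompletionParams(gap_factor=1.2, r_min=6))
        assert out.bbox == BBox(10, 20, 60, 40)

    def test_distant_neighbor_not_merged(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[20:40, 10:40] = True
        mask[20:40, 140:170] = True  # 100 px away
        b, ccs = scene(mask)
        region = PanelRegion(BBox(10, 20, 40, 40), "diagram", 1.0, "oracle")
        out = complete_diagram(region, b, ccs, CompletionParams(r_min=10))
        assert out.bbox == BBox(10, 20, 40, 40)

    def test_idempotent(self, bank):
        img, ann = compose_scheme(SchemaSpec(n_steps=1, p_label=1.0), bank, seed=9)
        b = binarize(img)
        ccs = find_connected_components(b)
        for r in detect_regions(img, OracleBackend(ann)):
            if r.cls != "diagram":
                continue
            once = complete_diagram(r, b, ccs)
            twice = complete_diagram(once, b, ccs)
            assert twice.bbox == once.bbox

    def test_no_overlapping_component_warns_and_keeps(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:5, 2:5] = True
        b, ccs = scene(mask)
        region = PanelRegion(BBox(20, 20, 30, 30), "diagram", 1.0, "oracle")
        with pytest.warns(UserWarning):
            out = complete_diagram(region, b, ccs)
        assert out.bbox == region.bbox


class TestReclassify:
    def test_text_above_arrow_becomes_conditions(self):
        arrow = hbar_arrow(100, 100, 160)
        region = PanelRegion(BBox(110, 80, 150, 92), "label", 1.0, "oracle")
        diagrams = [PanelRegion(BBox(300, 90, 340, 130), "diagram", 1.0, "oracle")]
        out = reclassify_text_region(region, diagrams, [arrow])
        assert out.cls == "conditions"

    def test_text_below_diagram_becomes_label(self):
        arrow = hbar_arrow(300, 20, 360)
        diagrams = [PanelRegion(BBox(20, 20, 70, 70), "diagram", 1.0, "oracle")]
        region = PanelRegion(BBox(30, 76, 60, 88), "conditions", 1.0, "oracle")
        out = reclassify_text_region(region, diagrams, [arrow])
        assert out.cls == "label"

    def test_rule_grid_matches_brute_force(self):
        """Decision agrees with direct evaluation of the two placement
        rules over a grid of text positions (tie -> diagram wins)."""
        from rxnscheme.geometry import separation
        from rxnscheme.postprocess import is_below_diagram, satisfies_directionality

        arrow = hbar_arrow(140, 100, 200)
        diagram = PanelRegion(BBox(20, 60, 70, 110), "diagram", 1.0, "oracle")
        params = DirectionalityParams()
        for gx in range(0, 260, 20):
            for gy in range(0, 200, 20):
                region = PanelRegion(BBox(gx, gy, gx + 24, gy + 10),
                                     "label", 1.0, "oracle")
                out = reclassify_text_region(region, [diagram], [arrow], params)
                d_dia = separation(region.bbox, diagram.bbox)
                d_arr = separation(region.bbox, arrow.bbox)
                if d_dia <= d_arr:
                    expect = "label" if is_below_diagram(region.bbox, diagram.bbox) \
                        else "label" if region.cls == "label" else "conditions"
                elif satisfies_directionality(region.bbox, arrow, params):
                    expect = "conditions"
                else:
                    expect = "label"  # prior kept
                assert out.cls == expect, (gx, gy)

    def test_no_context_keeps_prior_with_warning(self):
        region = PanelRegion(BBox(0, 0, 10, 10), "label", 1.0, "oracle")
        with pytest.warns(UserWarning):
            out = reclassify_text_region(region, [], [])
        assert out.cls == "label"

    def test_never_invents_or_deletes_regions(self, bank):
        img, ann = compose_scheme(SchemaSpec(n_steps=2, p_label=1.0,
                                             p_conditions=1.0), bank, seed=23)
        regions = detect_regions(img, OracleBackend(ann))
        diagrams = [r for r in regions if r.cls == "diagram"]
        b = binarize(img)
        ccs = find_connected_components(b)
        from rxnscheme.pipeline import _oracle_arrows
        arrows = _oracle_arrows(ann, ccs)
        texts = [r for r in regions if r.cls in ("label", "conditions")]
        outs = [reclassify_text_region(r, diagrams, arrows) for r in texts]
        assert len(outs) == len(texts)
        for before, after in zip(texts, outs):
            assert after.bbox == before.bbox  # only cls/provenance may change


class TestPairing:
    def test_single_label_single_diagram(self):
        labels = [PanelRegion(BBox(30, 76, 60, 88), "label", 1.0, "oracle")]
        diagrams = [PanelRegion(BBox(20, 20, 70, 70), "diagram", 1.0, "oracle")]
        label_of, conditions_of, _ = pair_regions(labels, [], diagrams, [])
        assert label_of == {0: 0}
        assert conditions_of == {}

    def test_two_labels_may_share_a_diagram(self):
        labels = [PanelRegion(BBox(30, 76, 60, 88), "label", 1.0, "oracle"),
                  PanelRegion(BBox(30, 95, 60, 107), "label", 1.0, "oracle")]
        diagrams = [PanelRegion(BBox(20, 20, 70, 70), "diagram", 1.0, "oracle")]
        label_of, _, _ = pair_regions(labels, [], diagrams, [])
        assert label_of == {0: 0, 1: 0}

    def test_oracle_pairing_recovers_annotation(self, bank):
        schema = SchemaSpec(n_steps=2, p_label=1.0, p_conditions=1.0)
        img, ann = compose_scheme(schema, bank, seed=31)
        regions = detect_regions(img, OracleBackend(ann))
        diagrams = [r for r in regions if r.cls == "diagram"]
        labels = [r for r in regions if r.cls == "label"]
        conditions = [r for r in regions if r.cls == "conditions"]
        b = binarize(img)
        from rxnscheme import find_connected_components
        from rxnscheme.pipeline import _oracle_arrows
        arrows = _oracle_arrows(ann, find_connected_components(b))
        label_of, conditions_of, _ = pair_regions(labels, conditions,
                                                  diagrams, arrows)
        got_labels = {labels[i].id: diagrams[j].id for i, j in label_of.items()}
        got_conds = {conditions[i].id: arrows[j].id
                     for i, j in conditions_of.items()}
        assert got_labels == ann.label_of
        assert got_conds == ann.conditions_of
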