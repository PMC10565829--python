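"""End-to-end scheme extraction.

The operational pipeline runs top to bottom: binarize -> region
detection (learned or oracle backend) and arrow detection (model or
oracle) in parallel conceptually -> diagram completion -> text-region
reclassification and pairing -> arrow geometry -> step scanning ->
reaction-graph assembly.  Optical character / structure recognition is
a plugin seam only: adapters may fill ``label_text`` and ``smiles``
fields after extraction, and the core pipeline never depends on them.

Per-image failures in batch mode raise ``SchemeSkip`` internally and
are reported as skips instead of aborting the batch.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import BBox, binarize, find_connected_components, ConnComp
from .engineer import SchemeAnnotation
from .arrows import Arrow, ArrowModel, detect_arrows, ProposalFilter
from .regions import (OracleBackend, LearnedBackend, PanelRegion, RegionModel,
                      detect_regions)
from .postprocess import (CompletionParams, DirectionalityParams,
                          complete_diagram, pair_regions, reclassify_text_region)
from .arrowgeom import analyze_arrow
from .graphs import (ReactionGraph, ScanParams, build_reaction_graph,
                     export_graph, scan_reaction_step)

logger = logging.getLogger("rxnscheme")


class SchemeSkip(RuntimeError):
    """Raised when an image cannot be processed; batches log and move on."""


@dataclass
class PipelineConfig:
    backend: str = "oracle"              # oracle | learned
    arrow_source: str = "oracle"         # oracle | model
    annotation_path: str | None = None
    region_model_path: str | None = None
    arrow_model_path: str | None = None
    arrow_threshold: float = 0.5
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    oracle_jitter_sigma: float = 0.0
    oracle_drop_rate: float = 0.0
    oracle_spurious_rate: float = 0.0
    seed: int = 0
    debug: bool = False
    completion: CompletionParams = field(default_factory=CompletionParams)
    directionality: DirectionalityParams = field(default_factory=DirectionalityParams)
    scan: ScanParams = field(default_factory=ScanParams)
    proposal: ProposalFilter = field(default_factory=ProposalFilter)

    def __post_init__(self):
        if self.backend not in ("oracle", "learned"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.arrow_source not in ("oracle", "model"):
            raise ValueError(f"unknown arrow source {self.arrow_source!r}")
        for name in ("arrow_threshold", "score_threshold", "nms_iou"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_file(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as f:
            if str(path).endswith((".yaml", ".yml")):
                import yaml
                yaml.safe_dump(doc, f)
            else:
                json.dump(doc, f, indent=1)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as f:
            if str(path).endswith((".yaml", ".yml")):
                import yaml
                doc = yaml.safe_load(f)
            else:
                doc = json.load(f)
        for key, sub in (("completion", CompletionParams),
                         ("directionality", DirectionalityParams),
                         ("scan", ScanParams), ("proposal", ProposalFilter)):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = sub(**doc[key])
        return cls(**doc)


@dataclass
class ExtractionResult:
    graph: ReactionGraph
    regions: list[PanelRegion]
    arrows: list[Arrow]
    label_of: dict[int, int]       # label region id -> diagram region id
    conditions_of: dict[int, int]  # conditions region id -> arrow id
    report: dict


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        try:
            return np.asarray(Image.open(image).convert("L"))
        except Exception as e:  # unreadable file -> skip signal
            raise SchemeSkip(f"unreadable image {image}: {e}") from e
    return np.asarray(image)


def _oracle_arrows(ann: SchemeAnnotation, ccs: list[ConnComp]) -> list[Arrow]:
    """Ground-truth arrows: for each annotated arrow box, the component
    with the most pixels inside the box."""
    out = []
    for r in ann.regions:
        if r.cls != "arrow":
            continue
        best, best_n = None, 0
        for cc in ccs:
            if not cc.bbox.intersects(r.bbox):
                continue
            inside = ((cc.pixels[:, 0] >= r.bbox.y0) & (cc.pixels[:, 0] < r.bbox.y1)
                      & (cc.pixels[:, 1] >= r.bbox.x0) & (cc.pixels[:, 1] < r.bbox.x1))
            n = int(inside.sum())
            if n > best_n:
                best, best_n = cc, n
        if best is not None:
            arrow = Arrow(best, r.subtype or "solid", 1.0)
            arrow.id = r.id
            out.append(arrow)
    return out


def extract_scheme(image, config: PipelineConfig | None = None,
                   annotation: SchemeAnnotation | None = None,
                   region_model: RegionModel | None = None,
                   arrow_model: ArrowModel | None = None) -> ExtractionResult:
    """Run the full extraction pipeline on one image."""
    config = config or PipelineConfig()
    img = _load_image(image)
    report: dict = {"stages": {}}

    bin_img = binarize(img)
    ccs = find_connected_components(bin_img)
    report["stages"]["connected_components"] = len(ccs)

    # region detection
    if config.backend == "oracle":
        if annotation is None:
            if config.annotation_path is None:
                raise SchemeSkip("oracle backend requires an annotation")
            with open(config.annotation_path) as f:
                annotation = SchemeAnnotation.from_dict(json.load(f))
        backend = OracleBackend(annotation, config.oracle_jitter_sigma,
                                config.oracle_drop_rate,
                                config.oracle_spurious_rate, config.seed)
    else:
        if region_model is None:
            if config.region_model_path is None:
                raise SchemeSkip("learned backend requires a region model")
            region_model = RegionModel.load(config.region_model_path)
        backend = LearnedBackend(region_model, config.score_threshold, config.nms_iou)
    regions = detect_regions(img, backend)
    report["stages"]["raw_regions"] = len(regions)

    # arrow detection
    if config.arrow_source == "oracle":
        if annotation is None:
            raise SchemeSkip("oracle arrows require an annotation")
        arrows = _oracle_arrows(annotation, ccs)
    else:
        if arrow_model is None:
            if config.arrow_model_path is None:
                raise SchemeSkip("model arrow source requires an arrow model")
            arrow_model = ArrowModel.load(config.arrow_model_path)
        arrows = detect_arrows(bin_img, arrow_model, config.arrow_threshold,
                               config.proposal, ccs=ccs)
        base = 1 + max([r.id for r in regions], default=-1)
        for k, a in enumerate(arrows):
            a.id = base + k
    report["stages"]["arrows"] = len(arrows)
    if not arrows:
        warnings.warn("no arrows found: graph will hold isolated diagrams",
                      stacklevel=2)

    # symbolic postprocessing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diagrams = [complete_diagram(r, bin_img, ccs, config.completion)
                    for r in regions if r.cls == "diagram"]
        texts = [reclassify_text_region(r, diagrams, arrows, config.directionality)
                 for r in regions if r.cls in ("label", "conditions")]
    labels = [r for r in texts if r.cls == "label"]
    conditions = [r for r in texts if r.cls == "conditions"]
    label_of_idx, conditions_of_idx, _ = pair_regions(labels, conditions,
                                                      diagrams, arrows)
    label_of = {labels[i].id: diagrams[j].id for i, j in label_of_idx.items()}
    conditions_of = {conditions[i].id: getattr(arrows[j], "id", j)
                     for i, j in conditions_of_idx.items()}
    report["stages"]["diagrams"] = len(diagrams)
    report["stages"]["labels"] = len(labels)
    report["stages"]["conditions"] = len(conditions)

    # arrow geometry and step scanning
    diagram_boxes = {d.id: d.bbox for d in diagrams}
    arrow_boxes = {getattr(a, "id", k): a.bbox for k, a in enumerate(arrows)}
    steps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, a in enumerate(arrows):
            aid = getattr(a, "id", k)
            frame = analyze_arrow(a, diagrams)
            conds = tuple(cid for cid, tid in conditions_of.items() if tid == aid)
            step = scan_reaction_step(frame, diagram_boxes, arrow_boxes,
                                      (bin_img.height, bin_img.width),
                                      arrow_id=aid, conditions=conds,
                                      params=config.scan)
            steps.append(step)
    node_info = {d.id: {"bbox": d.bbox.to_coco()} for d in diagrams}
    graph = build_reaction_graph(steps, node_info)
    # diagrams untouched by any step remain as isolated nodes
    for d in diagrams:
        if d.id not in graph.nodes:
            graph.nodes[d.id] = {"bbox": d.bbox.to_coco(),
                                 "label_text": None, "smiles": None}
    report["stages"]["steps"] = len(steps)
    return ExtractionResult(graph, diagrams + labels + conditions, arrows,
                            label_of, conditions_of, report)


def extract_batch(images, config: PipelineConfig | None = None, **models):
    """Process many images; failures are logged and skipped.

    Returns (results dict keyed by input, skips dict input -> reason).
    """
    results, skips = {}, {}
    for image in images:
        try:
            results[image] = extract_scheme(image, config, **models)
        except SchemeSkip as e:
            logger.warning("skipping %s: %s", image, e)
            skips[image] = str(e)
    return results, skips


# --------------------------------------------------------------------------
# OCR / OCSR plugin seam
# --------------------------------------------------------------------------

def ocr_ocsr_plugins(result: ExtractionResult, image,
                     ocr=None, ocsr=None) -> ReactionGraph:
    """Annotate a graph with plugin output.

    ``ocr(crop) -> str`` decodes text crops (labels, conditions);
    ``ocsr(crop) -> str`` converts diagram crops to a structure line
    notation.  Missing adapters leave fields ``None``; an adapter
    exception nulls only the affected field.
    """
    img = _load_image(image)

    def crop(b: BBox):
        return img[b.y0:b.y1, b.x0:b.x1]

    graph = result.graph
    region_by_id = {r.id: r for r in result.regions}
    for nid, info in graph.nodes.items():
        if ocsr is not None and nid in region_by_id:
            try:
                info["smiles"] = ocsr(crop(region_by_id[nid].bbox))
            except Exception as e:
                logger.warning("ocsr failed on node %s: %s", nid, e)
                info["smiles"] = None
        if ocr is not None:
            lids = [l for l, d in result.label_of.items() if d == nid]
            if lids and lids[0] in region_by_id:
                try:
                    info["label_text"] = ocr(crop(region_by_id[lids[0]].bbox))
                except Exception as e:
                    logger.warning("ocr failed on label %s: %s", lids[0], e)
                    info["label_text"] = None
    return graph
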