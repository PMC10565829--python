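"""Reaction-step assembly and graph construction.

Each arrow defines a reaction step.  Starting from the arrow, two scan
directions are derived (reactant side and product side); the scanner
marks equidistant strips perpendicular to each direction, moving away
from the arrow, and collects the diagram boxes it crosses.  A scan
terminates when it encounters another arrow's box (that arrow belongs
to a different step) or leaves the image.  If one side collects nothing
the step is assumed to wrap across text lines, and the previous or next
line of diagrams is searched instead.  Steps are finally stitched into
a directed reaction graph by matching the products of one step with the
reactants of another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .geometry import BBox
from .arrowgeom import ArrowFrame, scan_directions


@dataclass
class ReactionStep:
    arrow_id: int
    reactants: frozenset[int]
    products: frozenset[int]
    conditions: tuple[int, ...] = ()

    def __post_init__(self):
        self.reactants = frozenset(self.reactants)
        self.products = frozenset(self.products)
        self.conditions = tuple(sorted(self.conditions))
        if self.reactants & self.products:
            raise ValueError("reactant and product sets must be disjoint")


@dataclass
class ReactionGraph:
    """Diagram nodes + reaction steps (hyperedges reactants -> products)."""

    nodes: dict[int, dict] = field(default_factory=dict)  # id -> {bbox, label_text, smiles}
    steps: list[ReactionStep] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        """Group-level digraph: nodes are frozensets of diagram ids."""
        g = nx.DiGraph()
        for s in self.steps:
            g.add_edge(s.reactants, s.products, arrow=s.arrow_id,
                       conditions=s.conditions)
        return g

    def __eq__(self, other):
        if not isinstance(other, ReactionGraph):
            return NotImplemented
        return self.nodes == other.nodes and \
            sorted(self.steps, key=lambda s: s.arrow_id) == \
            sorted(other.steps, key=lambda s: s.arrow_id)


@dataclass
class ScanParams:
    strip_frac: float = 0.25       # strip width, in arrow lengths
    lateral_frac: float = 0.8      # half-extent perpendicular to the scan
    max_extent_frac: float = 1.0   # of the image diagonal
    group_gap_frac: float = 0.75   # line-fallback grouping gap, in arrow lengths


def _box_proj_range(box: BBox, origin: np.ndarray, u: np.ndarray):
    corners = np.array([[box.x0, box.y0], [box.x1, box.y0],
                        [box.x0, box.y1], [box.x1, box.y1]], dtype=float)
    proj = (corners - origin) @ u
    return proj.min(), proj.max()


def _lateral_ok(pv: tuple[float, float], lateral: float) -> bool:
    """A box counts as inside the scan corridor when its lateral center
    falls within the corridor or at least half its lateral extent does —
    corner-grazing neighbors from other rows are ignored."""
    lo, hi = pv
    if hi < -lateral or lo > lateral:
        return False
    center = (lo + hi) / 2
    if abs(center) <= lateral:
        return True
    overlap = min(hi, lateral) - max(lo, -lateral)
    return overlap >= 0.5 * (hi - lo)


def _scan_side(direction: np.ndarray, frame: ArrowFrame,
               diagram_boxes: dict[int, BBox], arrow_boxes: dict[int, BBox],
               image_dims: tuple[int, int], params: ScanParams) -> set[int]:
    """Collect diagram ids in strips along ``direction`` until another
    arrow or the image edge stops the scan."""
    h, w = image_dims
    origin = np.array(frame.arrow.bbox.center)
    u = direction / np.linalg.norm(direction)
    v = np.array([-u[1], u[0]])
    delta = max(params.strip_frac * frame.length, 2.0)
    lateral = params.lateral_frac * frame.length
    max_extent = params.max_extent_frac * float(np.hypot(w, h))

    # precompute projections
    d_ranges = {}
    for i, b in diagram_boxes.items():
        pu = _box_proj_range(b, origin, u)
        pv = _box_proj_range(b, origin, v)
        if not _lateral_ok(pv, lateral):
            continue
        d_ranges[i] = pu
    a_ranges = {}
    for i, b in arrow_boxes.items():
        if b == frame.arrow.bbox:
            continue
        pu = _box_proj_range(b, origin, u)
        pv = _box_proj_range(b, origin, v)
        if not _lateral_ok(pv, lateral):
            continue
        a_ranges[i] = pu

    start = max(_box_proj_range(frame.arrow.bbox, origin, u)[1], 0.0)
    collected: set[int] = set()
    s = start
    while s < max_extent:
        s_hi = s + delta
        # stop when a strip reaches another arrow
        if any(lo < s_hi and hi > s for (lo, hi) in a_ranges.values()):
            break
        for i, (lo, hi) in d_ranges.items():
            if lo < s_hi and hi > s:
                collected.add(i)
        s = s_hi
    return collected


def _line_bands(diagram_boxes: dict[int, BBox], gap: float) -> list[list[int]]:
    """Cluster diagrams into horizontal text lines by vertical position."""
    order = sorted(diagram_boxes, key=lambda i: diagram_boxes[i].center[1])
    bands: list[list[int]] = []
    last_y = None
    for i in order:
        cy = diagram_boxes[i].center[1]
        if last_y is None or cy - last_y > gap:
            bands.append([])
        bands[-1].append(i)
        last_y = cy
    return bands


def _fallback_line_search(frame: ArrowFrame, side: str,
                          diagram_boxes: dict[int, BBox],
                          arrow_boxes: dict[int, BBox],
                          image_dims: tuple[int, int],
                          params: ScanParams,
                          exclude: set[int]) -> set[int]:
    """Search the previous or next diagram line for a wrapped step side.

    The previous line is searched when the arrow sits in the lower half
    of the image, the next line otherwise.  Within the fallback line the
    trailing (for the previous line) or leading (next line) diagram
    group in reading order is taken.
    """
    h, _w = image_dims
    if not diagram_boxes:
        return set()
    heights = [b.height for b in diagram_boxes.values()]
    band_gap = 0.75 * float(np.median(heights))
    bands = _line_bands(diagram_boxes, band_gap)
    acy = frame.arrow.bbox.center[1]
    # the arrow's own band = the one closest in y
    band_y = [float(np.mean([diagram_boxes[i].center[1] for i in b])) for b in bands]
    k = int(np.argmin([abs(y - acy) for y in band_y]))
    go_prev = acy >= h / 2
    k2 = k - 1 if go_prev else k + 1
    if not (0 <= k2 < len(bands)):
        k2 = k - 1 if not go_prev else k + 1  # other side as a last resort
        if not (0 <= k2 < len(bands)):
            return set()
    band = [i for i in bands[k2] if i not in exclude]
    if not band:
        return set()
    band.sort(key=lambda i: diagram_boxes[i].center[0])
    gap_max = params.group_gap_frac * frame.length
    if go_prev:
        band = band[::-1]  # take the trailing group
    group = [band[0]]
    for i in band[1:]:
        a, b = diagram_boxes[group[-1]], diagram_boxes[i]
        gap = (b.x0 - a.x1) if not go_prev else (a.x0 - b.x1)
        if gap > gap_max:
            break
        # an arrow between two diagrams separates groups
        lo_x = min(a.x1, b.x1)
        hi_x = max(a.x0, b.x0)
        if any(ab.x0 >= lo_x and ab.x1 <= hi_x for ab in arrow_boxes.values()):
            break
        group.append(i)
    return set(group)


def scan_reaction_step(frame: ArrowFrame,
                       diagram_boxes: dict[int, BBox],
                       arrow_boxes: dict[int, BBox],
                       image_dims: tuple[int, int],
                       arrow_id: int | None = None,
                       conditions: tuple[int, ...] = (),
                       params: ScanParams | None = None) -> ReactionStep:
    """Recover one reaction step by scanning outward from an arrow."""
    params = params or ScanParams()
    reac_dir, prod_dir = scan_directions(frame)
    reac = _scan_side(reac_dir, frame, diagram_boxes, arrow_boxes, image_dims, params)
    prod = _scan_side(prod_dir, frame, diagram_boxes, arrow_boxes, image_dims, params)
    # a diagram seen on both sides goes to the nearer one; tie -> reactants
    both = reac & prod
    c = np.array(frame.arrow.bbox.center)
    for i in both:
        ctr = np.array(diagram_boxes[i].center)
        d = ctr - c
        if d @ prod_dir > d @ reac_dir:
            reac.discard(i)
        else:
            prod.discard(i)
    if not reac:
        reac = _fallback_line_search(frame, "reactants", diagram_boxes, arrow_boxes,
                                     image_dims, params, exclude=prod)
        if not reac:
            warnings.warn("reactant side empty after line fallback", stacklevel=2)
    if not prod:
        prod = _fallback_line_search(frame, "products", diagram_boxes, arrow_boxes,
                                     image_dims, params, exclude=reac)
        if not prod:
            warnings.warn("product side empty after line fallback", stacklevel=2)
    aid = arrow_id if arrow_id is not None else -1
    return ReactionStep(aid, frozenset(reac), frozenset(prod - reac), conditions)


def build_reaction_graph(steps: list[ReactionStep],
                         node_info: dict[int, dict] | None = None) -> ReactionGraph:
    """Stitch steps into the reaction graph (nodes = diagram ids)."""
    seen = set()
    for s in steps:
        if s.arrow_id in seen:
            raise ValueError(f"duplicate arrow id {s.arrow_id}")
        seen.add(s.arrow_id)
    nodes: dict[int, dict] = {}
    for s in sorted(steps, key=lambda s: s.arrow_id):
        for i in sorted(s.reactants | s.products):
            if i not in nodes:
                info = dict(node_info.get(i, {})) if node_info else {}
                info.setdefault("label_text", None)
                info.setdefault("smiles", None)
                nodes[i] = info
    return ReactionGraph(nodes=nodes,
                         steps=sorted(steps, key=lambda s: s.arrow_id))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

GRAPH_JSON_SCHEMA = {
    "type": "object",
    "required": ["nodes", "steps"],
    "nodes": {"required": ["id"], "optional": ["bbox", "label_text", "smiles"]},
    "steps": {"required": ["arrow", "reactants", "products", "conditions"]},
}


def validate_graph_json(doc: dict) -> None:
    """Structural validation against the bundled graph schema."""
    if not isinstance(doc, dict) or "nodes" not in doc or "steps" not in doc:
        raise ValueError("graph JSON must contain 'nodes' and 'steps'")
    ids = set()
    for n in doc["nodes"]:
        if "id" not in n:
            raise ValueError("node missing 'id'")
        ids.add(n["id"])
    for s in doc["steps"]:
        for key in ("arrow", "reactants", "products", "conditions"):
            if key not in s:
                raise ValueError(f"step missing {key!r}")
        for i in list(s["reactants"]) + list(s["products"]):
            if i not in ids:
                raise ValueError(f"step references unknown node {i}")


def graph_to_dict(graph: ReactionGraph) -> dict:
    nodes = []
    for i, info in sorted(graph.nodes.items()):
        n = {"id": i}
        for k in ("bbox", "label_text", "smiles"):
            if k in info:
                n[k] = info[k]
        nodes.append(n)
    steps = [{"arrow": s.arrow_id,
              "reactants": sorted(s.reactants),
              "products": sorted(s.products),
              "conditions": list(s.conditions)} for s in graph.steps]
    return {"nodes": nodes, "steps": steps}


def graph_from_dict(doc: dict) -> ReactionGraph:
    validate_graph_json(doc)
    nodes = {}
    for n in doc["nodes"]:
        info = {k: n[k] for k in ("bbox", "label_text", "smiles") if k in n}
        info.setdefault("label_text", None)
        info.setdefault("smiles", None)
        nodes[n["id"]] = info
    steps = [ReactionStep(s["arrow"], frozenset(s["reactants"]),
                          frozenset(s["products"]), tuple(s["conditions"]))
             for s in doc["steps"]]
    return ReactionGraph(nodes=nodes, steps=sorted(steps, key=lambda s: s.arrow_id))


def export_graph(graph: ReactionGraph, path, fmt: str = "json") -> None:
    """Write a graph as JSON (native) or GraphML (bipartite encoding)."""
    if fmt == "json":
        with open(path, "w") as f:
            json.dump(graph_to_dict(graph), f, indent=1, sort_keys=True)
    elif fmt == "graphml":
        g = nx.DiGraph()
        for i, info in graph.nodes.items():
            g.add_node(f"d{i}", kind="diagram",
                       label_text=info.get("label_text") or "",
                       smiles=info.get("smiles") or "")
        for s in graph.steps:
            sid = f"s{s.arrow_id}"
            g.add_node(sid, kind="step",
                       conditions=",".join(map(str, s.conditions)))
            for i in sorted(s.reactants):
                g.add_edge(f"d{i}", sid)
            for i in sorted(s.products):
                g.add_edge(sid, f"d{i}")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_graph(path, fmt: str = "json") -> ReactionGraph:
    if fmt == "json":
        with open(path) as f:
            return graph_from_dict(json.load(f))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes: dict[int, dict] = {}
        steps = []
        for n, data in g.nodes(data=True):
            if data.get("kind") == "diagram":
                nodes[int(n[1:])] = {"label_text": data.get("label_text") or None,
                                     "smiles": data.get("smiles") or None}
        for n, data in g.nodes(data=True):
            if data.get("kind") != "step":
                continue
            arrow = int(n[1:])
            reac = frozenset(int(p[1:]) for p in g.predecessors(n))
            prod = frozenset(int(p[1:]) for p in g.successors(n))
            conds = tuple(int(c) for c in data.get("conditions", "").split(",") if c)
            steps.append(ReactionStep(arrow, reac, prod, conds))
        return ReactionGraph(nodes=nodes, steps=sorted(steps, key=lambda s: s.arrow_id))
    raise ValueError(f"unknown format {fmt!r}")


def annotation_graph(ann) -> ReactionGraph:
    """The ground-truth ReactionGraph recorded in a SchemeAnnotation."""
    steps = [ReactionStep(s["arrow"], frozenset(s["reactants"]),
                          frozenset(s["products"]), tuple(s["conditions"]))
             for s in ann.graph["steps"]]
    node_info = {r.id: {"bbox": r.bbox.to_coco()} for r in ann.by_class("diagram")}
    return build_reaction_graph(steps, node_info)
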