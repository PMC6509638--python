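"""Experiment-gene graph construction, seeded layout, subsetting, highlighting.

Each input list becomes one hub (EXPERIMENT) node; every distinct gene
becomes one GENE node connected to each experiment containing it, with the
edge carrying that experiment's direction code. Gene nodes are colored red
(up everywhere), blue (down everywhere) or yellow (discordant).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

from .errors import EmptySubsetError, LayoutError, NetVennError
from .genelist_io import ExperimentList
from .set_model import DirectionClass, MembershipProfile, classify_direction

logger = logging.getLogger(__name__)

# colorblind-safe 8-color palette (Okabe-Ito), assigned to experiments by
# input order
EXPERIMENT_PALETTE = (
    "#e69f00",
    "#56b4e9",
    "#009e73",
    "#f0e442",
    "#0072b2",
    "#d55e00",
    "#cc79a7",
    "#999999",
)

GENE_COLORS = {
    DirectionClass.UP: "#d62728",        # red
    DirectionClass.DOWN: "#1f77b4",      # blue
    DirectionClass.DISCORDANT: "#ffdd33",  # yellow
}
_COLOR_TO_CLASS = {v: k for k, v in GENE_COLORS.items()}

EDGE_COLORS = {1: "#d62728", 2: "#1f77b4"}

# above this many gene nodes, labels default to hidden
LABEL_AUTO_THRESHOLD = 200

DEFAULT_SEED = 20190503


@dataclass(frozen=True)
class GraphNode:
    node_id: str
    kind: str  # "EXPERIMENT" | "GENE"
    color: str  # hex fill color
    shape: str = "circle"  # "circle" | "square"
    label: str = ""
    label_visible: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("EXPERIMENT", "GENE"):
            raise ValueError(f"bad node kind {self.kind!r}")
        if self.shape not in ("circle", "square"):
            raise ValueError(f"bad node shape {self.shape!r}")
        if self.kind == "EXPERIMENT" and (self.shape != "circle" or not self.label_visible):
            raise ValueError("experiment nodes are always labelled circles")

    @property
    def direction_class(self) -> DirectionClass | None:
        return _COLOR_TO_CLASS.get(self.color) if self.kind == "GENE" else None


@dataclass(frozen=True)
class GraphEdge:
    experiment: str
    gene: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (1, 2):
            raise ValueError(f"bad edge direction {self.direction!r}")


@dataclass
class GraphModel:
    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    @property
    def experiment_nodes(self) -> list[GraphNode]:
        return [n for n in self.nodes if n.kind == "EXPERIMENT"]

    @property
    def gene_nodes(self) -> list[GraphNode]:
        return [n for n in self.nodes if n.kind == "GENE"]

    @property
    def gene_ids(self) -> set[str]:
        return {n.node_id for n in self.nodes if n.kind == "GENE"}

    def node(self, node_id: str) -> GraphNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def memberships(self) -> dict[str, dict[str, int]]:
        """Reconstruct gene -> {experiment: code} from the edge list."""
        out: dict[str, dict[str, int]] = {}
        for e in self.edges:
            out.setdefault(e.gene, {})[e.experiment] = e.direction
        return out

    def validate(self) -> None:
        ids = {n.node_id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise NetVennError("duplicate node ids in graph model")
        for e in self.edges:
            if e.experiment not in ids or e.gene not in ids:
                raise NetVennError(f"edge ({e.experiment}, {e.gene}) has missing endpoint")


@dataclass
class Layout:
    positions: dict[str, tuple[float, float]]
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


def build_graph(
    lists: list[ExperimentList],
    profiles: Mapping[str, MembershipProfile],
    *,
    seed: int = DEFAULT_SEED,
    labels: str = "auto",
) -> GraphModel:
    """Assemble the bipartite experiment-gene graph with color semantics.

    ``labels`` is ``on``/``off``/``auto``; ``auto`` hides gene labels once
    the graph has more than 200 gene nodes.
    """
    if labels not in ("on", "off", "auto"):
        raise ValueError(f"labels must be on/off/auto, got {labels!r}")
    gene_ids = sorted(profiles)
    if labels == "auto":
        gene_labels_on = len(gene_ids) <= LABEL_AUTO_THRESHOLD
    else:
        gene_labels_on = labels == "on"

    nodes: list[GraphNode] = []
    for i, exp in enumerate(lists):
        nodes.append(
            GraphNode(
                node_id=exp.name,
                kind="EXPERIMENT",
                color=EXPERIMENT_PALETTE[i % len(EXPERIMENT_PALETTE)],
                label=exp.name,
            )
        )
    for g in gene_ids:
        cls = classify_direction(profiles[g])
        nodes.append(
            GraphNode(
                node_id=g,
                kind="GENE",
                color=GENE_COLORS[cls],
                label=g,
                label_visible=gene_labels_on,
            )
        )
    edges = [
        GraphEdge(exp.name, rec.gene_id, rec.direction)
        for exp in lists
        for rec in exp.records
    ]
    model = GraphModel(nodes=nodes, edges=edges, seed=seed)
    model.validate()
    return model


def layout_graph(
    model: GraphModel,
    iterations: int = 50,
    seed: int | None = None,
    *,
    pin_experiments: bool = False,
) -> Layout:
    """Seeded Fruchterman-Reingold spring embedding.

    Identical (model, iterations, seed) yields bit-identical coordinates.
    With ``pin_experiments`` the hub nodes are fixed on a circle, which
    stabilizes large graphs.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    if not model.nodes:
        raise LayoutError("cannot lay out an empty graph")
    if seed is None:
        seed = model.seed

    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in model.nodes)
    g.add_edges_from((e.experiment, e.gene) for e in model.edges)

    fixed = None
    pos0 = None
    if pin_experiments:
        hubs = [n.node_id for n in model.experiment_nodes]
        if hubs:
            pos0 = {}
            for i, h in enumerate(hubs):
                theta = 2.0 * math.pi * i / len(hubs)
                pos0[h] = (math.cos(theta), math.sin(theta))
            fixed = hubs

    raw = nx.spring_layout(g, iterations=iterations, seed=seed, pos=pos0, fixed=fixed)
    positions = {nid: (float(xy[0]), float(xy[1])) for nid, xy in raw.items()}
    for nid, (x, y) in positions.items():
        if not (math.isfinite(x) and math.isfinite(y)):
            raise LayoutError(f"non-finite coordinate for node {nid}")
    xs = [p[0] for p in positions.values()]
    ys = [p[1] for p in positions.values()]
    return Layout(positions, (min(xs), min(ys), max(xs), max(ys)))


def subset_graph(model: GraphModel, gene_subset: Iterable[str]) -> GraphModel:
    """Induced subgraph on the given genes plus still-connected experiments.

    Experiment nodes left without edges are dropped (logged); an empty
    intersection with the model's genes is an error.
    """
    keep_genes = set(gene_subset) & model.gene_ids
    if not keep_genes:
        raise EmptySubsetError("gene subset does not intersect the graph")
    edges = [e for e in model.edges if e.gene in keep_genes]
    live_experiments = {e.experiment for e in edges}
    dropped = [n.node_id for n in model.experiment_nodes if n.node_id not in live_experiments]
    if dropped:
        logger.info("dropping experiment node(s) with no remaining edges: %s",
                    ", ".join(sorted(dropped)))
    nodes = [
        n
        for n in model.nodes
        if (n.kind == "GENE" and n.node_id in keep_genes)
        or (n.kind == "EXPERIMENT" and n.node_id in live_experiments)
    ]
    sub = GraphModel(nodes=nodes, edges=edges, seed=model.seed)
    sub.validate()
    return sub


def highlight_genes(model: GraphModel, gene_subset: Iterable[str]) -> GraphModel:
    """Return a copy with the given gene nodes drawn as squares (idempotent)."""
    subset = set(gene_subset)
    unknown = subset - {n.node_id for n in model.nodes}
    if unknown:
        logger.warning("%d unknown gene(s) ignored in highlight", len(unknown))
    nodes = [
        replace(n, shape="square") if n.kind == "GENE" and n.node_id in subset else n
        for n in model.nodes
    ]
    return GraphModel(nodes=nodes, edges=list(model.edges), seed=model.seed)


def to_json(model: GraphModel) -> str:
    """Serialize to the stable JSON graph document (deterministic bytes)."""
    doc = {
        "nodes": [
            {
                "id": n.node_id,
                "kind": n.kind,
                "color": n.color,
                "shape": n.shape,
                "label": n.label,
                "label_visible": n.label_visible,
            }
            for n in model.nodes
        ],
        "links": [
            {"source": e.experiment, "target": e.gene, "direction": e.direction}
            for e in model.edges
        ],
        "seed": model.seed,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def from_json(text: str) -> GraphModel:
    """Inverse of :func:`to_json`."""
    try:
        doc = json.loads(text)
        nodes = [
            GraphNode(
                node_id=d["id"],
                kind=d["kind"],
                color=d["color"],
                shape=d.get("shape", "circle"),
                label=d.get("label", d["id"]),
                label_visible=bool(d.get("label_visible", True)),
            )
            for d in doc["nodes"]
        ]
        edges = [
            GraphEdge(d["source"], d["target"], int(d["direction"]))
            for d in doc["links"]
        ]
        model = GraphModel(nodes=nodes, edges=edges, seed=int(doc.get("seed", DEFAULT_SEED)))
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise NetVennError(f"malformed graph JSON document: {exc}") from exc
    model.validate()
    return model
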