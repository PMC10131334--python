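"""Project capped change scores onto pathway graphs and export colored networks.

Metabolite nodes are filled from a five-point diverging color scale over the
capped log2FC range [−3, +3]: strong-down, mild-down, neutral, mild-up,
strong-up, with the inner/outer boundary at ±1.5 so values at or beyond ±1.5
read as "high (abnormal)".  Nodes without a score — unmeasured metabolites,
proteins, disorders — are gray.  Graphs are written as GraphML (attributes on
nodes) or SIF plus a node-attribute TSV, both re-readable into the same
structure, for rendering in external network tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .pathways import PathwayModel
from .scoring import ChangeScore

__all__ = [
    "ColorScale",
    "DEFAULT_SCALE",
    "color_for",
    "bin_for",
    "OverlayNode",
    "OverlayEdge",
    "OverlayGraph",
    "build_overlay",
    "write_graphml",
    "read_graphml",
    "write_sif_with_attrs",
]

BINS = ("strong_down", "mild_down", "neutral", "mild_up", "strong_up")


@dataclass(frozen=True)
class ColorScale:
    """Five-point diverging scale plus gray for missing values.

    ``inner`` separates mild from strong changes; ``outer`` is the capped
    maximum.  The inner bins are open at ±inner and the outer bins closed,
    so a value of exactly ±inner counts as strong (abnormal).
    """

    inner: float = 1.5
    outer: float = 3.0
    colors: dict[str, str] = field(
        default_factory=lambda: {
            "strong_down": "#2166AC",
            "mild_down": "#92C5DE",
            "neutral": "#F7F7F7",
            "mild_up": "#F4A582",
            "strong_up": "#B2182B",
            "missing": "#C0C0C0",
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.inner < self.outer:
            raise ValueError("need 0 < inner < outer")
        required = set(BINS) | {"missing"}
        if not required <= set(self.colors):
            raise ValueError(f"color scale missing entries: {sorted(required - set(self.colors))}")


DEFAULT_SCALE = ColorScale()


def bin_for(capped_log2fc: float | None, scale: ColorScale = DEFAULT_SCALE) -> str:
    """Bin name for a capped log2FC; ``missing`` for None."""
    if capped_log2fc is None:
        return "missing"
    v = float(capped_log2fc)
    if abs(v) > scale.outer:
        raise ValueError(f"|log2FC| {v} exceeds the cap {scale.outer}; cap scores first")
    if v == 0:
        return "neutral"
    if v >= scale.inner:
        return "strong_up"
    if v > 0:
        return "mild_up"
    if v <= -scale.inner:
        return "strong_down"
    return "mild_down"


def color_for(capped_log2fc: float | None, scale: ColorScale = DEFAULT_SCALE) -> str:
    """Fill color for a capped log2FC; gray for None (no value available)."""
    return scale.colors[bin_for(capped_log2fc, scale)]


@dataclass(frozen=True)
class OverlayNode:
    node_id: str
    node_class: str  # metabolite | protein | disorder
    label: str
    xref: str
    log2fc: float | None
    fill_color: str


@dataclass(frozen=True)
class OverlayEdge:
    source: str
    target: str
    edge_class: str  # conversion | catalysis
    rhea_id: str | None
    directed: bool


@dataclass
class OverlayGraph:
    """Colored pathway graph ready for export.

    ``scale_max`` records the absolute highest capped log2FC present, the
    value a renderer should use as the extreme of its color gradient.
    """

    pathway_id: str
    title: str
    nodes: list[OverlayNode]
    edges: list[OverlayEdge]
    scale_max: float

    def node_ids(self) -> set[str]:
        return {n.node_id for n in self.nodes}

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(
            pathway_id=self.pathway_id, title=self.title, scale_max=self.scale_max
        )
        for n in self.nodes:
            attrs = {
                "node_class": n.node_class,
                "label": n.label,
                "xref": n.xref,
                "fill_color": n.fill_color,
            }
            if n.log2fc is not None:
                attrs["log2fc"] = float(n.log2fc)
            g.add_node(n.node_id, **attrs)
        for i, e in enumerate(self.edges):
            g.add_edge(
                e.source,
                e.target,
                key=i,
                edge_class=e.edge_class,
                rhea_id=e.rhea_id or "",
                directed=e.directed,
            )
        return g


def build_overlay(
    pathway: PathwayModel,
    scores: Iterable[ChangeScore],
    scale: ColorScale = DEFAULT_SCALE,
) -> OverlayGraph:
    """Color a pathway's nodes by the sample's capped log2 fold changes.

    Every pathway node becomes a graph node; metabolites with a capped score
    get a value and a bin color, everything else is gray.  Interactions
    expand to conversion edges (substrate → product) and catalysis edges
    (catalyst → substrate).
    """
    by_chebi: dict[str, float] = {
        s.chebi_id: s.capped_log2fc for s in scores if s.capped_log2fc is not None
    }
    nodes = []
    for chebi in sorted(pathway.metabolite_nodes):
        value = by_chebi.get(chebi)
        nodes.append(
            OverlayNode(
                node_id=chebi,
                node_class="metabolite",
                label=pathway.metabolite_labels.get(chebi, chebi),
                xref=chebi,
                log2fc=value,
                fill_color=color_for(value, scale),
            )
        )
    for hgnc, uniprot in sorted(pathway.protein_nodes, key=lambda t: t[0]):
        nodes.append(
            OverlayNode(
                node_id=hgnc,
                node_class="protein",
                label=hgnc,
                xref=uniprot or hgnc,
                log2fc=None,
                fill_color=scale.colors["missing"],
            )
        )
    for omim in sorted(pathway.disorders):
        nodes.append(
            OverlayNode(
                node_id=omim,
                node_class="disorder",
                label=omim,
                xref=omim,
                log2fc=None,
                fill_color=scale.colors["missing"],
            )
        )
    edges = []
    for ix in pathway.interactions:
        for sub in ix.substrates:
            for prod in ix.products:
                edges.append(
                    OverlayEdge(sub, prod, "conversion", ix.rhea_id, ix.directed)
                )
        for catalyst in ix.catalysts:
            for sub in ix.substrates:
                edges.append(OverlayEdge(catalyst, sub, "catalysis", None, False))
    scored_values = [
        v for chebi, v in by_chebi.items() if chebi in pathway.metabolite_nodes
    ]
    scale_max = max((abs(v) for v in scored_values), default=0.0)
    return OverlayGraph(
        pathway_id=pathway.pathway_id,
        title=pathway.title,
        nodes=nodes,
        edges=edges,
        scale_max=scale_max,
    )


def write_graphml(graph: OverlayGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def read_graphml(path: str | Path) -> OverlayGraph:
    g = nx.read_graphml(str(path))
    nodes = [
        OverlayNode(
            node_id=nid,
            node_class=data["node_class"],
            label=data["label"],
            xref=data["xref"],
            log2fc=float(data["log2fc"]) if "log2fc" in data else None,
            fill_color=data["fill_color"],
        )
        for nid, data in sorted(g.nodes(data=True))
    ]
    edges = [
        OverlayEdge(
            source=u,
            target=v,
            edge_class=data["edge_class"],
            rhea_id=data["rhea_id"] or None,
            directed=bool(data["directed"]),
        )
        for u, v, data in g.edges(data=True)
    ]
    return OverlayGraph(
        pathway_id=g.graph.get("pathway_id", ""),
        title=g.graph.get("title", ""),
        nodes=nodes,
        edges=edges,
        scale_max=float(g.graph.get("scale_max", 0.0)),
    )


def write_sif_with_attrs(graph: OverlayGraph, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.sif (one line per edge) and <prefix>.nodes.tsv attributes."""
    prefix = Path(path_prefix)
    sif_path = prefix.with_suffix(".sif")
    attrs_path = prefix.parent / (prefix.name + ".nodes.tsv")
    with open(sif_path, "w") as fh:
        for e in graph.edges:
            fh.write(f"{e.source}\t{e.edge_class}\t{e.target}\n")
    pd.DataFrame(
        [
            {
                "node_id": n.node_id,
                "node_class": n.node_class,
                "label": n.label,
                "xref": n.xref,
                "log2fc": "" if n.log2fc is None else repr(n.log2fc),
                "fill_color": n.fill_color,
            }
            for n in graph.nodes
        ]
    ).to_csv(attrs_path, sep="\t", index=False)
    return sif_path, attrs_path
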