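"""Metabolic pathway models: GPML subset import, JSON dialect, coverage index.

A pathway model is a graph of metabolites (ChEBI), proteins (HGNC/UniProt),
enzymatic conversions (optionally annotated with Rhea reaction IDs) and
associated disorders (OMIM).  Two on-disk forms are supported:

* a GPML subset — the WikiPathways XML exchange format, of which only
  DataNode/Xref identity, Interaction connectivity (Points, Anchors) and
  Groups are consumed; all layout and graphics are ignored;
* a JSON dialect, the canonical internal form, simple enough to write
  fixtures by hand::

      {"id": "WP0001", "title": "...",
       "nodes": [{"id": "CHEBI:1", "class": "metabolite", "label": "..."},
                 {"id": "ENZ1", "class": "protein", "hgnc": "ENZ1",
                  "uniprot": "P00001"}],
       "edges": [{"substrates": ["CHEBI:1"], "products": ["CHEBI:2"],
                  "catalysts": ["ENZ1"], "rhea": "RHEA:10000",
                  "directed": true}],
       "disorders": ["OMIM:100000"]}

Direction of a conversion comes from a directed Rhea annotation when present,
else from GPML arrowheads, else the edge is recorded undirected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .reference import normalize_biomarker_id

__all__ = [
    "Interaction",
    "PathwayModel",
    "read_gpml",
    "write_gpml",
    "read_pathway_json",
    "write_pathway_json",
    "MarkerPathwayIndex",
    "build_index",
    "CoverageReport",
    "coverage_report",
]


@dataclass(frozen=True)
class Interaction:
    """One conversion: substrates → products, optionally catalyzed and Rhea-annotated."""

    substrates: tuple[str, ...]
    products: tuple[str, ...]
    catalysts: tuple[str, ...] = ()
    rhea_id: str | None = None
    directed: bool = True


@dataclass
class PathwayModel:
    """Annotated pathway graph with identity-level content only (no layout)."""

    pathway_id: str
    title: str = ""
    metabolite_nodes: set[str] = field(default_factory=set)
    protein_nodes: set[tuple[str, str | None]] = field(default_factory=set)
    interactions: list[Interaction] = field(default_factory=list)
    disorders: set[str] = field(default_factory=set)
    metabolite_labels: dict[str, str] = field(default_factory=dict)
    skip_report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ix in self.interactions:
            for m in (*ix.substrates, *ix.products):
                if m not in self.metabolite_nodes:
                    raise ValueError(
                        f"{self.pathway_id}: interaction references undeclared metabolite {m}"
                    )
            declared = {h for h, _ in self.protein_nodes}
            for c in ix.catalysts:
                if c not in declared:
                    raise ValueError(
                        f"{self.pathway_id}: interaction references undeclared protein {c}"
                    )

    @property
    def protein_symbols(self) -> set[str]:
        return {h for h, _ in self.protein_nodes}

    def n_expanded_edges(self) -> int:
        """Edge count after expanding each interaction to pairwise edges.

        Conversions contribute one edge per (substrate, product) pair and
        catalysis one edge per (catalyst, substrate) pair — the expansion an
        overlay graph uses.
        """
        n = 0
        for ix in self.interactions:
            n += len(ix.substrates) * len(ix.products)
            n += len(ix.catalysts) * len(ix.substrates)
        return n

    def __eq__(self, other: object) -> bool:  # skip/skip_report excluded
        if not isinstance(other, PathwayModel):
            return NotImplemented
        return (
            self.pathway_id == other.pathway_id
            and self.title == other.title
            and self.metabolite_nodes == other.metabolite_nodes
            and self.protein_nodes == other.protein_nodes
            and sorted(map(_interaction_key, self.interactions))
            == sorted(map(_interaction_key, other.interactions))
            and self.disorders == other.disorders
        )


def _interaction_key(ix: Interaction):
    return (ix.substrates, ix.products, ix.catalysts, ix.rhea_id or "", ix.directed)


# ---------------------------------------------------------------------------
# JSON dialect


def write_pathway_json(model: PathwayModel, path: str | Path) -> None:
    nodes = [
        {
            "id": m,
            "class": "metabolite",
            "label": model.metabolite_labels.get(m, ""),
        }
        for m in sorted(model.metabolite_nodes)
    ]
    nodes += [
        {"id": hgnc, "class": "protein", "hgnc": hgnc, "uniprot": uniprot}
        for hgnc, uniprot in sorted(model.protein_nodes, key=lambda t: t[0])
    ]
    payload = {
        "id": model.pathway_id,
        "title": model.title,
        "nodes": nodes,
        "edges": [
            {
                "substrates": list(ix.substrates),
                "products": list(ix.products),
                "catalysts": list(ix.catalysts),
                "rhea": ix.rhea_id,
                "directed": ix.directed,
            }
            for ix in model.interactions
        ],
        "disorders": sorted(model.disorders),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, ensure_ascii=False)
        fh.write("\n")


def read_pathway_json(path: str | Path) -> PathwayModel:
    with open(path) as fh:
        payload = json.load(fh)
    metabolites: set[str] = set()
    labels: dict[str, str] = {}
    proteins: set[tuple[str, str | None]] = set()
    for node in payload.get("nodes", ()):
        cls = node.get("class")
        if cls == "metabolite":
            mid = normalize_biomarker_id(node["id"])
            metabolites.add(mid)
            if node.get("label"):
                labels[mid] = node["label"]
        elif cls == "protein":
            proteins.add((node.get("hgnc") or node["id"], node.get("uniprot")))
        else:
            raise ValueError(f"{path}: unknown node class {cls!r}")
    interactions = [
        Interaction(
            substrates=tuple(normalize_biomarker_id(s) for s in edge.get("substrates", ())),
            products=tuple(normalize_biomarker_id(p) for p in edge.get("products", ())),
            catalysts=tuple(edge.get("catalysts", ())),
            rhea_id=edge.get("rhea"),
            directed=bool(edge.get("directed", True)),
        )
        for edge in payload.get("edges", ())
    ]
    return PathwayModel(
        pathway_id=payload["id"],
        title=payload.get("title", ""),
        metabolite_nodes=metabolites,
        protein_nodes=proteins,
        interactions=interactions,
        disorders=set(payload.get("disorders", ())),
        metabolite_labels=labels,
    )


# ---------------------------------------------------------------------------
# GPML subset

_GPML_NS = "http://pathvisio.org/GPML/2013a"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_gpml(path: str | Path) -> PathwayModel:
    """Parse the identity/connectivity subset of a GPML file.

    Metabolite DataNodes need a ChEBI Xref to enter the model; nodes without
    one are listed in ``skip_report``.  Catalysis is recognized from
    ``mim-catalysis`` arrowheads pointing at an Anchor of a conversion
    interaction.  Invalid XML raises; a pathway without any annotated
    metabolite parses to an empty metabolite set.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if _local(root.tag) != "Pathway":
        raise ValueError(f"{path}: not a GPML pathway document")
    title = root.get("Name", "")
    pathway_id = root.get("PathwayID") or Path(path).stem

    metabolites: set[str] = set()
    labels: dict[str, str] = {}
    proteins: set[tuple[str, str | None]] = set()
    disorders: set[str] = set()
    skip: list[str] = []
    graphid_to_node: dict[str, tuple[str, str]] = {}  # GraphId -> (class, id)
    group_members: dict[str, list[str]] = {}  # GroupId -> [GraphId]
    group_graphids: dict[str, str] = {}  # Group GraphId -> GroupId

    for el in root:
        tag = _local(el.tag)
        if tag == "DataNode":
            node_type = el.get("Type", "")
            label = el.get("TextLabel", "")
            graph_id = el.get("GraphId")
            xref = next((c for c in el if _local(c.tag) == "Xref"), None)
            db = (xref.get("Database") or "").lower() if xref is not None else ""
            xid = (xref.get("ID") or "") if xref is not None else ""
            if node_type == "Metabolite":
                if db == "chebi" and xid:
                    chebi = normalize_biomarker_id(xid)
                    metabolites.add(chebi)
                    labels[chebi] = label
                    if graph_id:
                        graphid_to_node[graph_id] = ("metabolite", chebi)
                else:
                    skip.append(f"metabolite {label!r} without ChEBI Xref")
            elif node_type in ("Protein", "GeneProduct"):
                uniprot = xid if db == "uniprot" and xid else None
                hgnc = xid if db == "hgnc" and xid else label
                if not hgnc:
                    skip.append(f"protein node {graph_id!r} without identifier")
                    continue
                proteins.add((hgnc, uniprot))
                if graph_id:
                    graphid_to_node[graph_id] = ("protein", hgnc)
            elif node_type == "Disease":
                if db == "omim" and xid:
                    disorders.add(f"OMIM:{xid}" if not xid.upper().startswith("OMIM") else xid)
                else:
                    skip.append(f"disease node {label!r} without OMIM Xref")
            else:
                skip.append(f"unhandled DataNode type {node_type!r} ({label!r})")
            group_ref = el.get("GroupRef")
            if group_ref and graph_id:
                group_members.setdefault(group_ref, []).append(graph_id)
        elif tag == "Group":
            gid, graphid = el.get("GroupId"), el.get("GraphId")
            if gid and graphid:
                group_graphids[graphid] = gid

    # first pass over interactions: collect anchors and raw endpoints
    raw: list[dict] = []
    anchor_to_interaction: dict[str, int] = {}
    for el in root:
        if _local(el.tag) != "Interaction":
            continue
        graphics = next((c for c in el if _local(c.tag) == "Graphics"), None)
        if graphics is None:
            continue
        points = [c for c in graphics if _local(c.tag) == "Point"]
        anchors = [c for c in graphics if _local(c.tag) == "Anchor"]
        xref = next((c for c in el if _local(c.tag) == "Xref"), None)
        rhea = None
        if xref is not None and (xref.get("Database") or "").lower() == "rhea":
            rhea = f"RHEA:{xref.get('ID')}" if xref.get("ID") else None
        if len(points) < 2:
            continue
        entry = {
            "start": points[0].get("GraphRef"),
            "end": points[-1].get("GraphRef"),
            "arrow": points[-1].get("ArrowHead", ""),
            "rhea": rhea,
        }
        idx = len(raw)
        raw.append(entry)
        for anchor in anchors:
            aid = anchor.get("GraphId")
            if aid:
                anchor_to_interaction[aid] = idx

    def _resolve(ref: str | None) -> list[tuple[str, str]]:
        """GraphRef -> [(class, id)]; groups flatten to their members."""
        if ref is None:
            return []
        if ref in graphid_to_node:
            return [graphid_to_node[ref]]
        if ref in group_graphids:
            out = []
            for member in group_members.get(group_graphids[ref], ()):
                out.extend(_resolve(member))
            return out
        return []

    conversions: dict[int, dict] = {}
    catalyses: list[tuple[str, int]] = []  # (protein, conversion index)
    for idx, entry in enumerate(raw):
        start_nodes = _resolve(entry["start"])
        arrow = entry["arrow"]
        if arrow == "mim-catalysis" and entry["end"] in anchor_to_interaction:
            for cls, nid in start_nodes:
                if cls == "protein":
                    catalyses.append((nid, anchor_to_interaction[entry["end"]]))
            continue
        end_nodes = _resolve(entry["end"])
        subs = tuple(nid for cls, nid in start_nodes if cls == "metabolite")
        prods = tuple(nid for cls, nid in end_nodes if cls == "metabolite")
        if subs and prods:
            directed = bool(entry["rhea"]) or arrow in ("Arrow", "mim-conversion")
            conversions[idx] = {
                "substrates": subs,
                "products": prods,
                "catalysts": [],
                "rhea": entry["rhea"],
                "directed": directed,
            }
    for protein, target in catalyses:
        if target in conversions:
            conversions[target]["catalysts"].append(protein)

    interactions = [
        Interaction(
            substrates=c["substrates"],
            products=c["products"],
            catalysts=tuple(sorted(c["catalysts"])),
            rhea_id=c["rhea"],
            directed=c["directed"],
        )
        for c in conversions.values()
    ]
    return PathwayModel(
        pathway_id=pathway_id,
        title=title,
        metabolite_nodes=metabolites,
        protein_nodes=proteins,
        interactions=interactions,
        disorders=disorders,
        metabolite_labels=labels,
        skip_report=skip,
    )


def write_gpml(model: PathwayModel, path: str | Path) -> None:
    """Emit the model as minimal GPML (identity + connectivity, dummy layout)."""
    nsmap = {None: _GPML_NS}
    root = etree.Element(f"{{{_GPML_NS}}}Pathway", nsmap=nsmap)
    root.set("Name", model.title)
    root.set("PathwayID", model.pathway_id)
    root.set("Version", "1")

    graph_ids: dict[str, str] = {}

    def _add_datanode(label: str, node_type: str, db: str, xid: str, key: str) -> None:
        gid = f"n{len(graph_ids):04d}"
        graph_ids[key] = gid
        dn = etree.SubElement(root, f"{{{_GPML_NS}}}DataNode")
        dn.set("TextLabel", label)
        dn.set("Type", node_type)
        dn.set("GraphId", gid)
        etree.SubElement(dn, f"{{{_GPML_NS}}}Graphics", CenterX="0", CenterY="0", Width="80", Height="20")
        etree.SubElement(dn, f"{{{_GPML_NS}}}Xref", Database=db, ID=xid)

    for chebi in sorted(model.metabolite_nodes):
        _add_datanode(
            model.metabolite_labels.get(chebi, chebi),
            "Metabolite",
            "ChEBI",
            chebi,
            chebi,
        )
    for hgnc, uniprot in sorted(model.protein_nodes, key=lambda t: t[0]):
        if uniprot:
            _add_datanode(hgnc, "Protein", "Uniprot", uniprot, f"protein:{hgnc}")
        else:
            _add_datanode(hgnc, "Protein", "HGNC", hgnc, f"protein:{hgnc}")
    for omim in sorted(model.disorders):
        _add_datanode(omim, "Disease", "OMIM", omim.split(":", 1)[-1], f"disorder:{omim}")

    def _add_line(start_gid: str, end_ref: str, arrow: str, rhea: str | None, anchor: str | None):
        ix = etree.SubElement(root, f"{{{_GPML_NS}}}Interaction")
        gfx = etree.SubElement(ix, f"{{{_GPML_NS}}}Graphics")
        etree.SubElement(gfx, f"{{{_GPML_NS}}}Point", X="0", Y="0", GraphRef=start_gid)
        end = etree.SubElement(gfx, f"{{{_GPML_NS}}}Point", X="1", Y="1", GraphRef=end_ref)
        end.set("ArrowHead", arrow)
        if anchor:
            etree.SubElement(gfx, f"{{{_GPML_NS}}}Anchor", Position="0.5", GraphId=anchor)
        if rhea:
            etree.SubElement(ix, f"{{{_GPML_NS}}}Xref", Database="Rhea", ID=rhea.split(":", 1)[-1])

    n_anchor = 0
    for ix in model.interactions:
        # conversions: one line per (substrate, product) pair; the first line
        # carries the anchor catalysis lines attach to
        anchor_id = None
        if ix.catalysts:
            anchor_id = f"a{n_anchor:04d}"
            n_anchor += 1
        first = True
        for sub in ix.substrates:
            for prod in ix.products:
                _add_line(
                    graph_ids[sub],
                    graph_ids[prod],
                    "mim-conversion" if ix.directed else "Line",
                    ix.rhea_id if first else None,
                    anchor_id if first else None,
                )
                first = False
        for catalyst in ix.catalysts:
            if anchor_id is not None:
                _add_line(graph_ids[f"protein:{catalyst}"], anchor_id, "mim-catalysis", None, None)

    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Marker → pathway index and coverage


@dataclass
class MarkerPathwayIndex:
    """Local replacement for a pathway-database query: ChEBI → pathways."""

    index: dict[str, set[str]]
    pathways: dict[str, PathwayModel]

    def pathways_for(self, chebi_id: str) -> set[str]:
        return self.index.get(chebi_id, set())

    def markers_of(self, pathway_id: str) -> set[str]:
        return self.pathways[pathway_id].metabolite_nodes


def build_index(models: Iterable[PathwayModel]) -> MarkerPathwayIndex:
    models = list(models)
    if not models:
        raise ValueError("cannot index an empty pathway collection")
    pathways: dict[str, PathwayModel] = {}
    index: dict[str, set[str]] = {}
    for model in models:
        if model.pathway_id in pathways:
            raise ValueError(f"duplicate pathway id {model.pathway_id}")
        pathways[model.pathway_id] = model
        for chebi in model.metabolite_nodes:
            index.setdefault(chebi, set()).add(model.pathway_id)
    return MarkerPathwayIndex(index=index, pathways=pathways)


@dataclass
class CoverageReport:
    """How a set of changed biomarkers is distributed over indexed pathways."""

    per_pathway: dict[str, int]
    not_in_any_pathway: set[str]
    n_pathways_with_match: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.per_pathway.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["pathway_id", "n_changed_markers"],
        )


def coverage_report(
    changed: Iterable[str], index: MarkerPathwayIndex
) -> CoverageReport:
    changed = set(changed)
    per_pathway = {
        pid: len(model.metabolite_nodes & changed)
        for pid, model in index.pathways.items()
    }
    covered = {m for m in changed if index.pathways_for(m)}
    return CoverageReport(
        per_pathway=per_pathway,
        not_in_any_pathway=changed - covered,
        n_pathways_with_match=sum(1 for n in per_pathway.values() if n > 0),
    )
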