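"""Assembly and export of the TF-centric regulatory network.

The network centres on a transcription-factor hub (MYB3R1-style): the hub's
transcriptional targets (from a TF->target gene set), its direct protein
interactors (from a confidence-filtered protein-protein interaction table),
and miRNA->target edges that touch any included node.  Nodes carry the log2
fold change and DE status from the expression contrast; nodes without a DEG
record are kept and marked not differentially expressed.

Edge vocabulary: ``tf_target`` (directed, hub -> gene), ``tf_protein`` and
``protein_protein`` (undirected), ``mirna_target`` (directed, miRNA ->
gene).  Exports: GraphML (full attributes), SIF (edge type as the
relation), and node/edge TSVs; export -> parse round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from budmir.integrate import DEGRecord

EDGE_TYPES = ("tf_target", "tf_protein", "protein_protein", "mirna_target")
NODE_TYPES = ("tf", "protein", "gene", "mirna")
_UNDIRECTED = {"tf_protein", "protein_protein"}


@dataclass
class RegNetwork:
    """Typed regulatory graph with fold-change annotations."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add_node(self, node_id: str, node_type: str,
                 log2fc: Optional[float] = None,
                 de_status: str = "not_DE") -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.nodes[node_id] = {"node_type": node_type, "log2fc": log2fc,
                               "de_status": de_status}

    def add_edge(self, source: str, target: str, edge_type: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        if source == target:
            raise ValueError(f"self-loop on {source!r} rejected")
        if source not in self.nodes or target not in self.nodes:
            raise ValueError("edge endpoints must be added as nodes first")
        if edge_type == "mirna_target" and \
                self.nodes[source]["node_type"] != "mirna":
            raise ValueError("mirna_target edges must originate from mirna nodes")
        if edge_type in _UNDIRECTED and (target, source, edge_type) in self.edges:
            return
        self.edges.add((source, target, edge_type))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegNetwork):
            return NotImplemented
        return self.nodes == other.nodes and \
            _canonical_edges(self.edges) == _canonical_edges(other.edges)


def _canonical_edges(edges: Iterable[tuple[str, str, str]]) -> set:
    canon = set()
    for s, t, et in edges:
        if et in _UNDIRECTED and t < s:
            s, t = t, s
        canon.add((s, t, et))
    return canon


def filter_ppi(edges: pd.DataFrame, min_score: int = 700) -> pd.DataFrame:
    """Keep interactions with confidence score strictly above ``min_score``.

    Expects columns protein_a, protein_b, score (0-1000 scale); undirected
    duplicates ((a,b) vs (b,a)) collapse to one edge.
    """
    for col in ("protein_a", "protein_b", "score"):
        if col not in edges.columns:
            raise ValueError(f"PPI table missing column {col!r}")
    scores = pd.to_numeric(edges["score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2  # 1-based + header
        raise ValueError(f"non-numeric PPI score at line {line}")
    kept = edges.loc[scores > min_score].copy()
    kept["score"] = scores[scores > min_score].astype(int)
    pair = kept.apply(
        lambda r: tuple(sorted((str(r["protein_a"]), str(r["protein_b"])))),
        axis=1)
    kept = kept.loc[~pair.duplicated()].reset_index(drop=True)
    return kept


def assemble_network(hub: str, tf_sets: Mapping[str, dict],
                     ppi: pd.DataFrame,
                     mirna_edges: pd.DataFrame,
                     degs: Sequence[DEGRecord]) -> RegNetwork:
    """Build the 1-hop hub network with fold-change annotations.

    Included: the hub, its transcriptional targets (members of the hub's
    gene set in ``tf_sets``), its direct protein interactors (from the
    already-filtered ``ppi`` table), protein-protein edges among included
    interactors, and miRNA->target edges (columns mirna_id, gene_id)
    whose target is already included.
    """
    targets = set(tf_sets.get(hub, {}).get("members", set()))
    interactors = set()
    for row in ppi.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        if a == hub:
            interactors.add(b)
        elif b == hub:
            interactors.add(a)
    if not targets and not interactors:
        raise ValueError(f"hub {hub!r} absent from TF gene sets and PPI table")

    deg_by_gene = {d.gene_id: d for d in degs}

    def annotation(node_id: str) -> tuple[Optional[float], str]:
        d = deg_by_gene.get(node_id)
        if d is None:
            return None, "not_DE"
        return d.log2fc_sd_vs_ld, d.status

    net = RegNetwork()
    fc, st = annotation(hub)
    net.add_node(hub, "tf", fc, st)
    for g in sorted(targets - {hub}):
        fc, st = annotation(g)
        net.add_node(g, "gene", fc, st)
    for p in sorted(interactors - {hub} - targets):
        fc, st = annotation(p)
        net.add_node(p, "protein", fc, st)

    for g in sorted(targets - {hub}):
        net.add_edge(hub, g, "tf_target")
    for p in sorted(interactors - {hub}):
        net.add_edge(hub, p, "tf_protein")
    # protein-protein edges among included (non-hub) nodes
    included = set(net.nodes)
    for row in ppi.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        if hub in (a, b):
            continue
        if a in included and b in included and a != b:
            net.add_edge(*sorted((a, b)), "protein_protein")

    if mirna_edges is not None and len(mirna_edges):
        for col in ("mirna_id", "gene_id"):
            if col not in mirna_edges.columns:
                raise ValueError(f"miRNA edge table missing column {col!r}")
        for row in mirna_edges.sort_values(
                ["mirna_id", "gene_id"]).itertuples(index=False):
            gene = str(row.gene_id)
            if gene not in included:
                continue
            mirna = str(row.mirna_id)
            if mirna not in net.nodes:
                net.add_node(mirna, "mirna", None, "not_DE")
            net.add_edge(mirna, gene, "mirna_target")
    return net


def _to_networkx(net: RegNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for node_id in sorted(net.nodes):
        attrs = net.nodes[node_id]
        g.add_node(node_id, node_type=attrs["node_type"],
                   de_status=attrs["de_status"],
                   **({"log2fc": float(attrs["log2fc"])}
                      if attrs["log2fc"] is not None else {}))
    for s, t, et in sorted(_canonical_edges(net.edges)):
        g.add_edge(s, t, edge_type=et)
    return g


def export_graph(net: RegNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, SIF, or a node+edge TSV pair.

    For ``fmt="tsv"`` two files are written: ``<path>`` with edges and
    ``<path>`` suffixed ``.nodes.tsv`` with node attributes.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_networkx(net), str(path))
    elif fmt == "sif":
        with open(path, "w") as fh:
            for s, t, et in sorted(_canonical_edges(net.edges)):
                fh.write(f"{s}\t{et}\t{t}\n")
    elif fmt == "tsv":
        edges = pd.DataFrame(sorted(_canonical_edges(net.edges)),
                             columns=["source", "target", "edge_type"])
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame([
            {"node_id": nid, **attrs} for nid, attrs in sorted(net.nodes.items())
        ])
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> RegNetwork:
    """Parse a GraphML export back into a RegNetwork (round-trip inverse)."""
    g = nx.read_graphml(str(path))
    net = RegNetwork()
    for node_id, attrs in g.nodes(data=True):
        net.add_node(str(node_id), attrs["node_type"],
                     attrs.get("log2fc"), attrs.get("de_status", "not_DE"))
    for s, t, attrs in g.edges(data=True):
        net.add_edge(str(s), str(t), attrs["edge_type"])
    return net
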