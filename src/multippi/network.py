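"""Multi-source molecular association network.

Nodes are biomolecules of five classes (protein, miRNA, lncRNA, drug,
disease); undirected edges carry one of the eight association-type labels
(miRNA-disease, drug-protein, miRNA-lncRNA, lncRNA-disease, drug-disease,
protein-disease, miRNA-protein, lncRNA-protein).  Identifiers are namespaced
by molecule type ("protein:P53"), so ids only need to be unique within a
type.  Known protein-protein interaction edges are excluded from the
embedding graph by default: they are the prediction labels, and embedding
them would leak the answer into the features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "MOLECULE_TYPES",
    "ASSOCIATION_TYPES",
    "EdgeRecord",
    "HeteroGraph",
    "node_key",
    "load_edge_list",
    "load_manifest",
    "build_graph",
    "graph_stats",
    "write_edge_list",
    "write_stats",
]

logger = logging.getLogger(__name__)

MOLECULE_TYPES = ("protein", "mirna", "lncrna", "drug", "disease")

ASSOCIATION_TYPES = (
    "mirna-disease", "drug-protein", "mirna-lncrna", "lncrna-disease",
    "drug-disease", "protein-disease", "mirna-protein", "lncrna-protein",
)


def node_key(molecule_type: str, raw_id: str) -> str:
    if molecule_type not in MOLECULE_TYPES:
        raise ValueError(f"unknown molecule type {molecule_type!r}")
    return f"{molecule_type}:{raw_id}"


@dataclass(frozen=True)
class EdgeRecord:
    """One typed, namespaced association edge."""

    source: str          # node_key
    target: str          # node_key
    label: str           # association-type label

    def canonical(self) -> tuple[str, str]:
        a, b = sorted((self.source, self.target))
        return a, b


@dataclass
class HeteroGraph:
    """Undirected typed association graph backed by networkx.

    Adjacency is exposed as sorted neighbor lists so random walks are
    reproducible regardless of insertion order.
    """

    g: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def molecule_type(self, key: str) -> str:
        return self.g.nodes[key]["molecule_type"]

    def neighbors(self, key: str) -> list[str]:
        return sorted(self.g.neighbors(key))

    def has_edge(self, a: str, b: str) -> bool:
        return self.g.has_edge(a, b)

    def edge_label(self, a: str, b: str) -> str:
        return self.g.edges[a, b]["label"]

    def add_node(self, key: str) -> None:
        mtype = key.split(":", 1)[0]
        existing = self.g.nodes.get(key)
        if existing is not None and existing["molecule_type"] != mtype:
            raise ValueError(f"conflicting molecule type for node {key!r}")
        self.g.add_node(key, molecule_type=mtype)

    def add_edge(self, rec: EdgeRecord) -> None:
        if rec.source == rec.target:
            raise ValueError(f"self-loop rejected: {rec.source!r}")
        self.add_node(rec.source)
        self.add_node(rec.target)
        self.g.add_edge(rec.source, rec.target, label=rec.label)

    def edge_hash(self) -> str:
        """Stable digest of the edge set, for walk-corpus provenance."""
        import hashlib
        h = hashlib.sha256()
        for a, b in sorted(tuple(sorted(e)) for e in self.g.edges):
            h.update(f"{a}\t{b}\n".encode())
        return h.hexdigest()[:16]


def load_edge_list(path, source_type: str, target_type: str, assoc_label: str,
                   header: bool = False,
                   synonyms: Mapping[str, str] | None = None) -> list[EdgeRecord]:
    """Parse a two-column TSV of raw ids into typed, namespaced edges.

    Blank lines and duplicate edges are dropped; same-id pairs of equal type
    are rejected as self-loops with a warning.  ``synonyms`` maps alias ->
    canonical raw id, applied before namespacing.
    """
    synonyms = synonyms or {}
    records: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            src_raw = synonyms.get(parts[0], parts[0])
            tgt_raw = synonyms.get(parts[1], parts[1])
            src = node_key(source_type, src_raw)
            tgt = node_key(target_type, tgt_raw)
            if src == tgt:
                logger.warning("%s: line %d: self-loop %r dropped", path, lineno, src)
                n_dropped += 1
                continue
            key = tuple(sorted((src, tgt)))
            if key in seen:
                continue
            seen.add(key)
            records.append(EdgeRecord(src, tgt, assoc_label))
    logger.info("%s: %d %s edges (%d self-loops dropped)",
                path, len(records), assoc_label, n_dropped)
    return records


def load_synonyms(path) -> dict[str, str]:
    """Read an alias -> canonical id map from a two-column TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def load_manifest(path) -> list[dict]:
    """Read a YAML manifest listing edge files.

    Each entry: {path, source_type, target_type, label, header?}.  Relative
    paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a list of file entries")
    out = []
    for e in entries:
        e = dict(e)
        e["path"] = str((base / e["path"]).resolve())
        out.append(e)
    return out


def build_graph(edge_collections: Iterable[Sequence[EdgeRecord]],
                exclude_assoc_labels: Iterable[str] = ("protein-protein",),
                extra_nodes: Iterable[str] = ()) -> HeteroGraph:
    """Merge typed edge collections into one undirected graph.

    Edges whose label is in ``exclude_assoc_labels`` contribute nothing (the
    default drops protein-protein edges, the leakage guard).  Duplicate edges
    across collections collapse.  ``extra_nodes`` registers isolated nodes.
    """
    exclude = set(exclude_assoc_labels)
    graph = HeteroGraph()
    for coll in edge_collections:
        for rec in coll:
            if rec.label in exclude:
                continue
            graph.add_edge(rec)
    for key in extra_nodes:
        graph.add_node(key)
    return graph


def graph_stats(graph: HeteroGraph) -> dict:
    """Per-type node counts and per-label edge counts."""
    node_counts = {t: 0 for t in MOLECULE_TYPES}
    for key in graph.g.nodes:
        node_counts[graph.molecule_type(key)] += 1
    edge_counts: dict[str, int] = {}
    for a, b, data in graph.g.edges(data=True):
        edge_counts[data["label"]] = edge_counts.get(data["label"], 0) + 1
    return {
        "nodes": node_counts,
        "total_nodes": graph.n_nodes,
        "edges": edge_counts,
        "total_edges": graph.n_edges,
    }


def write_edge_list(graph: HeteroGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted((a, b))) for a, b in graph.g.edges):
            fh.write(f"{a}\t{b}\t{graph.edge_label(a, b)}\n")


def read_merged_edge_list(path) -> HeteroGraph:
    """Read a merged node_key TSV (node_key, node_key, label) back to a graph."""
    graph = HeteroGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            graph.add_edge(EdgeRecord(parts[0], parts[1], parts[2]))
    return graph


def write_stats(graph: HeteroGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_stats(graph), fh, indent=2, sort_keys=True)
        fh.write("\n")
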