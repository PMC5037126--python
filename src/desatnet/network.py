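"""The sequence similarity network: thresholds, components, exports.

An SSN is an undirected graph whose nodes are representative nodes and
whose edges carry the logE of the representative-vs-representative
alignment.  Families and subfamilies emerge as connected components as the
stringency (the logE threshold) is tightened: every stricter edge set is a
subset of the looser one, so the component partitions form a filtration in
which clusters only ever split, never merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape, quoteattr

import networkx as nx

from .align import PairAlignment, read_edge_table, write_edge_table
from .repnode import NodeSummary, RepNode, node_effective_annotation
from .seqio import ProteinRecord

EXPORT_FORMATS = ("edge-tsv", "xgmml", "graphml")

#: The stringencies used figure-by-figure in the published analysis:
#: overview at -13, FE split at -20, ME split at -30, FD major clusters at
#: -56, FE1 sub-resolution at -65.
PAPER_SWEEP = (-13.0, -20.0, -30.0, -56.0, -65.0)


@dataclass(frozen=True)
class SSN:
    """Graph of representative nodes with logE-weighted edges at a stated
    stringency.  Nodes persist across thresholding; only edges drop."""

    graph: nx.Graph
    stringency: float

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d["logE"])
            for u, v, d in self.graph.edges(data=True)
        )

    def node(self, rep_id: str) -> RepNode:
        return self.graph.nodes[rep_id]["repnode"]

    def summary(self, rep_id: str) -> NodeSummary:
        return self.graph.nodes[rep_id]["summary"]

    def record(self, rep_id: str) -> ProteinRecord:
        return self.graph.nodes[rep_id]["record"]


@dataclass(frozen=True)
class ClusterInfo:
    label: str
    node_ids: tuple[str, ...]
    node_count: int
    protein_count: int


@dataclass(frozen=True)
class Partition:
    """Connected-component clustering of an SSN at one threshold.

    Labels are canonical: the lexicographically smallest rep_id in each
    cluster, so they are stable under node reordering.
    """

    threshold: float
    assignment: Mapping[str, str]
    clusters: Mapping[str, ClusterInfo]

    @property
    def labels(self) -> list[str]:
        return sorted(self.clusters)

    def protein_assignment(self) -> dict[str, str]:
        """Map every underlying protein (member) id to its cluster label."""
        out: dict[str, str] = {}
        for label, info in self.clusters.items():
            for nid in info.node_ids:
                for mid in self._members[nid]:
                    out[mid] = label
        return out

    # populated by connected_components; not part of the public surface
    _members: Mapping[str, tuple[str, ...]] = field(default_factory=dict, repr=False)


def build_network(
    repnodes: Sequence[RepNode],
    edge_alignments: Iterable[PairAlignment],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    stringency: float = -5.0,
) -> SSN:
    """Assemble the SSN at the initial cutoff stringency.

    ``edge_alignments`` are representative-vs-representative alignments, at
    most one per unordered pair; duplicates, self-pairs and references to
    non-representative ids are errors.  Node attributes carry the member
    annotation roll-up and the representative's record (used for
    query-time classification).
    """
    by_id = (
        records if isinstance(records, Mapping) else {r.id: r for r in records}
    )
    g = nx.Graph()
    for node in repnodes:
        g.add_node(
            node.rep_id,
            repnode=node,
            summary=node_effective_annotation(node, by_id),
            record=by_id[node.rep_id],
        )
    seen: set[tuple[str, str]] = set()
    for aln in edge_alignments:
        u, v = aln.query_id, aln.subject_id
        if u not in g.nodes or v not in g.nodes:
            missing = u if u not in g.nodes else v
            raise ValueError(
                f"edge references non-representative id {missing!r}"
            )
        if u == v:
            raise ValueError(f"self-edge on {u!r}")
        key = (min(u, v), max(u, v))
        if key in seen:
            raise ValueError(f"duplicate edge for pair {key}")
        seen.add(key)
        if aln.logE <= stringency:
            g.add_edge(u, v, logE=aln.logE, alignment=aln)
    return SSN(graph=g, stringency=stringency)


def apply_threshold(ssn: SSN, logE_threshold: float) -> SSN:
    """Tighten the stringency: keep exactly the edges with
    ``logE <= logE_threshold``.  Nodes are never removed; loosening is an
    error because dropped edges cannot be recovered."""
    if logE_threshold > ssn.stringency:
        raise ValueError(
            f"cannot loosen threshold from {ssn.stringency} to {logE_threshold}"
        )
    g = nx.Graph()
    g.add_nodes_from(ssn.graph.nodes(data=True))
    g.add_edges_from(
        (u, v, d)
        for u, v, d in ssn.graph.edges(data=True)
        if d["logE"] <= logE_threshold
    )
    return SSN(graph=g, stringency=logE_threshold)


def connected_components(ssn: SSN) -> Partition:
    """Undirected connected components; isolated nodes are singletons."""
    assignment: dict[str, str] = {}
    clusters: dict[str, ClusterInfo] = {}
    members: dict[str, tuple[str, ...]] = {
        nid: ssn.node(nid).member_ids for nid in ssn.graph.nodes
    }
    for comp in nx.connected_components(ssn.graph):
        label = min(comp)
        node_ids = tuple(sorted(comp))
        clusters[label] = ClusterInfo(
            label=label,
            node_ids=node_ids,
            node_count=len(node_ids),
            protein_count=sum(len(members[n]) for n in node_ids),
        )
        for nid in node_ids:
            assignment[nid] = label
    return Partition(
        threshold=ssn.stringency,
        assignment=assignment,
        clusters=clusters,
        _members=members,
    )


def threshold_sweep(
    ssn: SSN, thresholds: Sequence[float]
) -> list[tuple[float, Partition]]:
    """Partitions at a strictly decreasing chain of stringencies.

    Because edge sets are nested along the chain, each partition refines
    the previous one: clusters split as the filter tightens but never
    merge.
    """
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if thresholds and thresholds[0] > ssn.stringency:
        raise ValueError("thresholds must not exceed the SSN stringency")
    out = []
    current = ssn
    for t in thresholds:
        current = apply_threshold(current, t)
        out.append((t, connected_components(current)))
    return out


def major_clusters(partition: Partition, min_proteins: int = 50) -> list[str]:
    """Clusters with *more than* ``min_proteins`` member sequences (strict),
    largest first."""
    if min_proteins < 0:
        raise ValueError("min_proteins must be >= 0")
    majors = [
        info for info in partition.clusters.values()
        if info.protein_count > min_proteins
    ]
    majors.sort(key=lambda c: (-c.protein_count, c.label))
    return [c.label for c in majors]


def _node_attribute_rows(ssn: SSN) -> list[dict]:
    rows = []
    for nid in ssn.node_ids:
        node, summ = ssn.node(nid), ssn.summary(nid)
        kc = summ.kingdom_counts()
        majority_kingdom = (
            max(sorted(kc), key=lambda k: kc[k]) if kc else "unknown"
        )
        rows.append(
            {
                "rep_id": nid,
                "size": node.size,
                "has_characterized": str(summ.has_characterized).lower(),
                "kingdom_majority": majority_kingdom,
                "substrates": ";".join(
                    f"{s}:{c}" for s, c in sorted(summ.substrate_counts().items())
                ),
                "all_fused_b5": str(summ.all_fused_b5).lower(),
            }
        )
    return rows


def export_graph(ssn: SSN, path: str | Path, format: str = "edge-tsv") -> None:
    """Write the SSN for external viewers.

    ``edge-tsv`` writes ``<path>.edges.tsv`` (bit-exact round trip via
    :func:`import_edge_tsv`) and ``<path>.nodes.tsv`` with one attribute
    row per representative node; ``graphml`` and ``xgmml`` are
    Cytoscape-readable single files.
    """
    import pandas as pd

    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {EXPORT_FORMATS}")
    path = Path(path)
    if format == "edge-tsv":
        write_edge_table(
            sorted(
                (d["alignment"] for _, _, d in ssn.graph.edges(data=True)),
                key=lambda a: (a.query_id, a.subject_id),
            ),
            path.with_suffix(".edges.tsv"),
        )
        pd.DataFrame(_node_attribute_rows(ssn)).to_csv(
            path.with_suffix(".nodes.tsv"), sep="\t", index=False
        )
    elif format == "graphml":
        g = nx.Graph()
        for row in _node_attribute_rows(ssn):
            g.add_node(row["rep_id"], **{k: v for k, v in row.items() if k != "rep_id"})
        for u, v, d in ssn.graph.edges(data=True):
            g.add_edge(u, v, logE=d["logE"])
        nx.write_graphml(g, path)
    else:  # xgmml
        _write_xgmml(ssn, path)


def _write_xgmml(ssn: SSN, path: Path) -> None:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graph label="ssn" directed="0" xmlns="http://www.cs.rpi.edu/XGMML">',
    ]
    for row in _node_attribute_rows(ssn):
        nid = quoteattr(row["rep_id"])
        lines.append(f"  <node id={nid} label={nid}>")
        for key in ("size", "has_characterized", "kingdom_majority",
                    "substrates", "all_fused_b5"):
            typ = "integer" if key == "size" else "string"
            lines.append(
                f'    <att name="{key}" type="{typ}" value={quoteattr(str(row[key]))}/>'
            )
        lines.append("  </node>")
    for u, v, le in ssn.edges:
        lines.append(
            f"  <edge source={quoteattr(u)} target={quoteattr(v)} "
            f"label={quoteattr(u + ' - ' + v)}>"
        )
        lines.append(f'    <att name="logE" type="real" value="{le!r}"/>')
        lines.append("  </edge>")
    lines.append("</graph>")
    Path(path).write_text("\n".join(lines) + "\n")


def import_edge_tsv(path: str | Path) -> list[PairAlignment]:
    """Re-read an exported edge TSV; reproduces the edge set bit-exactly."""
    return read_edge_table(path)


def save_build(
    directory: str | Path,
    records: Sequence[ProteinRecord],
    repnodes: Sequence[RepNode],
    ssn: SSN,
) -> None:
    """Persist a built network as plain text (FASTA + TSVs) for later
    query classification."""
    import json

    from . import seqio as _seqio
    from .repnode import write_repnode_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _seqio.write_fasta(records, directory / "corpus.fasta")
    _seqio.write_annotation_table(records, directory / "annotations.tsv")
    write_repnode_table(repnodes, directory / "repnodes.tsv")
    write_edge_table(
        sorted(
            (d["alignment"] for _, _, d in ssn.graph.edges(data=True)),
            key=lambda a: (a.query_id, a.subject_id),
        ),
        directory / "edges.tsv",
    )
    (directory / "meta.json").write_text(
        json.dumps({"stringency": ssn.stringency}) + "\n"
    )


def load_build(directory: str | Path):
    """Reload a network saved by :func:`save_build`.

    Returns ``(records, repnodes, ssn)``.
    """
    import json

    from . import seqio as _seqio
    from .repnode import read_repnode_table

    directory = Path(directory)
    records = _seqio.join_annotations(
        _seqio.read_fasta(directory / "corpus.fasta"),
        directory / "annotations.tsv",
    )
    repnodes = read_repnode_table(directory / "repnodes.tsv")
    meta = json.loads((directory / "meta.json").read_text())
    ssn = build_network(
        repnodes,
        read_edge_table(directory / "edges.tsv"),
        records,
        stringency=float(meta["stringency"]),
    )
    return records, repnodes, ssn
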