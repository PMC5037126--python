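"""Greedy collapse of near-identical sequences into representative nodes.

The network is drawn over representative nodes: clusters of sequences with
at least 60% pairwise identity to a representative, so that redundant
near-duplicates do not dominate the graph.  The collapse is the classic
greedy incremental scan (CD-HIT semantics): sequences are processed longest
first and join the first existing representative they match, else found a
new node.  Identity is measured on full sequences; the cytochrome-b5 edge
rule applies only later, at the all-vs-all stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import DEFAULT_SCHEME, PairAlignment, ScoringScheme, smith_waterman
from .seqio import ProteinRecord


def clustering_identity(aln: PairAlignment) -> float:
    """Percent identity with the shorter sequence as denominator.

    This is the CD-HIT convention and is the measure used for the
    representative-node collapse: identical columns over local-alignment
    columns would let two unrelated sequences "match" over a short
    high-identity stretch, whereas near-duplicate sequences are identical
    over (almost) their whole length.
    """
    identities = round(aln.pct_identity * aln.aln_len / 100.0)
    return 100.0 * identities / min(aln.m, aln.n)


@dataclass(frozen=True)
class RepNode:
    """A representative sequence plus its >=threshold-identity members."""

    rep_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rep_id not in self.member_ids:
            raise ValueError("rep_id must be among member_ids")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 60.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[RepNode]:
    """Collapse records into representative nodes at the identity threshold.

    Records are processed in order of decreasing length (ties broken by
    lexicographic id, so the result is deterministic for any input order).
    Each record is compared against existing representatives only, in
    founding order, and joins the first with :func:`clustering_identity`
    >= the threshold; otherwise it founds a new node with itself as
    representative.  The representative is therefore always the longest
    member, which best preserves domain content for downstream edges.
    Identity is measured on full sequences (the cytb5 rule applies only
    to edges, later).
    """
    if not 0 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (0, 100]")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for k, rep in enumerate(reps):
            aln = smith_waterman(
                rep.sequence, rec.sequence, scheme,
                query_id=rep.id, subject_id=rec.id,
            )
            if clustering_identity(aln) >= identity_threshold:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    return [
        RepNode(rep.id, tuple(mem)) for rep, mem in zip(reps, members)
    ]


@dataclass(frozen=True)
class NodeSummary:
    """Annotation roll-up of one representative node."""

    has_characterized: bool
    kingdoms: tuple[tuple[str, int], ...]
    substrates: tuple[tuple[str, int], ...]  # characterized members only
    all_fused_b5: bool

    def kingdom_counts(self) -> Counter:
        return Counter(dict(self.kingdoms))

    def substrate_counts(self) -> Counter:
        return Counter(dict(self.substrates))


def node_effective_annotation(
    node: RepNode, records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord]
) -> NodeSummary:
    """Summarise the members of a node: characterized flag, kingdom
    multiset, substrate multiset over characterized members, and whether
    every member carries a fused cytb5 domain."""
    by_id = (
        records if isinstance(records, Mapping) else {r.id: r for r in records}
    )
    try:
        mems = [by_id[i] for i in node.member_ids]
    except KeyError as exc:
        raise KeyError(f"unknown member id {exc.args[0]!r}") from exc
    kingdoms = Counter(m.kingdom for m in mems)
    substrates = Counter(m.substrate for m in mems if m.characterized)
    return NodeSummary(
        has_characterized=any(m.characterized for m in mems),
        kingdoms=tuple(sorted(kingdoms.items())),
        substrates=tuple(sorted(substrates.items())),
        all_fused_b5=all(m.has_cytb5 for m in mems),
    )


def write_repnode_table(nodes: Iterable[RepNode], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"rep_id": n.rep_id, "size": n.size,
             "member_ids": ";".join(n.member_ids)}
            for n in nodes
        ],
        columns=["rep_id", "size", "member_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_repnode_table(path) -> list[RepNode]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        RepNode(row["rep_id"], tuple(row["member_ids"].split(";")))
        for _, row in df.iterrows()
    ]
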