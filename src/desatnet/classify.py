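"""Query classification against a built SSN.

A new sequence is assigned by nearest representative: it is aligned
against every representative node (under the cytochrome-b5 rule), takes
the minimum logE, and — if that passes the assignment cutoff — inherits
the representative's cluster, family name and consensus substrate.  The
confidence reported is the assigned cluster's consensus support (the
fraction of its characterized members agreeing on the substrate), because
the biological claim inherited is the cluster's, not the pair's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import DEFAULT_SCHEME, PairAlignment, ScoringScheme, align_pair
from .annotate import ClusterSummary
from .network import SSN, Partition, connected_components
from .repnode import RepNode
from .seqio import ProteinRecord


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    best_rep_id: str
    best_logE: float
    cluster_label: str
    family_name: str
    predicted_substrate: str
    confidence: float
    status: str  # "assigned" | "unclassified"


def classify_query(
    query: ProteinRecord,
    ssn: SSN,
    repnodes: Sequence[RepNode],
    summaries: Sequence[ClusterSummary],
    cutoff_logE: float | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    b5_rule: bool = True,
    partition: Partition | None = None,
) -> ClassificationResult:
    """Assign a query to a cluster of the SSN, or report it unclassified.

    The cutoff defaults to the SSN's stringency.  Ties on logE are broken
    by higher percent identity, then lexicographic rep_id, so the result
    is deterministic.
    """
    if ssn.graph.number_of_nodes() == 0:
        raise ValueError("cannot classify against an empty SSN")
    if cutoff_logE is None:
        cutoff_logE = ssn.stringency
    if partition is None:
        partition = connected_components(ssn)
    best: PairAlignment | None = None
    for rep_id in ssn.node_ids:
        aln = align_pair(query, ssn.record(rep_id), scheme, b5_rule)
        if (
            best is None
            or (aln.logE, -aln.pct_identity, aln.subject_id)
            < (best.logE, -best.pct_identity, best.subject_id)
        ):
            best = aln
    assert best is not None
    if best.logE > cutoff_logE:
        return ClassificationResult(
            query_id=query.id,
            best_rep_id=best.subject_id,
            best_logE=best.logE,
            cluster_label="",
            family_name="",
            predicted_substrate="unknown",
            confidence=0.0,
            status="unclassified",
        )
    label = partition.assignment[best.subject_id]
    summary = next(s for s in summaries if s.label == label)
    return ClassificationResult(
        query_id=query.id,
        best_rep_id=best.subject_id,
        best_logE=best.logE,
        cluster_label=label,
        family_name=summary.family_name or "",
        predicted_substrate=summary.consensus_substrate,
        confidence=summary.consensus_support,
        status="assigned",
    )


def classify_queries(
    queries: Sequence[ProteinRecord],
    ssn: SSN,
    repnodes: Sequence[RepNode],
    summaries: Sequence[ClusterSummary],
    cutoff_logE: float | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    b5_rule: bool = True,
) -> list[ClassificationResult]:
    partition = connected_components(ssn)
    return [
        classify_query(
            q, ssn, repnodes, summaries, cutoff_logE, scheme, b5_rule,
            partition=partition,
        )
        for q in queries
    ]


def write_classification_table(
    results: Iterable[ClassificationResult], path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "status": r.status,
                "best_rep_id": r.best_rep_id,
                "best_logE": repr(r.best_logE),
                "cluster_label": r.cluster_label,
                "family_name": r.family_name,
                "predicted_substrate": r.predicted_substrate,
                "confidence": repr(r.confidence),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
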