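"""Pairwise local alignment, bit scores and E-values: the SSN edge weights.

Edges of the sequence similarity network carry the base-10 logarithm of the
Karlin-Altschul E-value of the optimal local alignment between two
sequences.  Scores come from exact affine-gap Smith-Waterman dynamic
programming (no heuristic seeding), normalised with the standard gapped
BLOSUM62 parameters:

    bits = (lambda * S - ln K) / ln 2
    E    = m * n * 2**(-bits),      logE = log10(E)

where m and n are the lengths of the sequences actually aligned.  A gap of
length k costs ``gap_open + k * gap_extend`` (BLAST convention).

The all-vs-all stage applies the initial logE cutoff (default -5) and the
cytochrome-b5 rule: the fused accessory domain contributes to a pair's
E-value only when both partners carry it; otherwise both sequences are
trimmed to their desaturase portion before alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord, effective_sequence

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and Karlin-Altschul
    parameters (lambda in nats per score unit, K dimensionless).

    Defaults are the published gapped BLOSUM62 values (gap open 11,
    extend 1, lambda 0.267, K 0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


@lru_cache(maxsize=8)
def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.matrix
    # Biopython charges open_gap_score for the first gapped residue and
    # extend_gap_score for each further one; open + extend reproduces the
    # BLAST cost open + k*extend for a length-k gap.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_aligner(scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    return _make_aligner(scheme, "local")


def global_aligner(scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    return _make_aligner(scheme, "global")


@dataclass(frozen=True)
class PairAlignment:
    """Optimal local alignment of one unordered sequence pair.

    ``m`` and ``n`` are the residue counts of the sequences actually
    aligned (after any cytb5 trimming) and define the E-value search
    space ``m * n``.  ``pct_identity`` uses aligned columns including gap
    columns as its denominator.  An empty alignment has score 0, zero
    aligned columns and identity 0 by convention.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    logE: float
    pct_identity: float
    aln_len: int
    m: int
    n: int


def bit_score(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalised score in bits: ``(lambda * S - ln K) / ln 2``."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (scheme.lam * raw_score - math.log(scheme.K)) / _LN2


def log_evalue(bits: float, m: int, n: int) -> float:
    """Base-10 log of the expected hit count ``E = m * n * 2**(-bits)``."""
    if m < 1 or n < 1:
        raise ValueError("search-space lengths must be >= 1")
    return math.log10(m) + math.log10(n) - bits * math.log10(2.0)


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairAlignment:
    """Exact affine-gap local alignment of two sequences.

    Returns the maximum local score floored at 0; identity is 100 *
    identical columns / aligned columns.  When no positive-scoring local
    alignment exists the result is the empty alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = local_aligner(scheme)
    score = int(round(aligner.score(a, b)))
    m, n = len(a), len(b)
    if score <= 0:
        return PairAlignment(
            query_id, subject_id, 0, bit_score(0, scheme),
            log_evalue(bit_score(0, scheme), m, n), 0.0, 0, m, n,
        )
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aln_len = aln.length
    identities = counts.identities
    bits = bit_score(score, scheme)
    return PairAlignment(
        query_id, subject_id, score, bits, log_evalue(bits, m, n),
        100.0 * identities / aln_len if aln_len else 0.0, aln_len, m, n,
    )


def _pair_sequences(
    rec_a: ProteinRecord, rec_b: ProteinRecord, b5_rule: bool
) -> tuple[str, str]:
    if b5_rule and not (rec_a.has_cytb5 and rec_b.has_cytb5):
        return (
            effective_sequence(rec_a, "desaturase-only"),
            effective_sequence(rec_b, "desaturase-only"),
        )
    return rec_a.sequence, rec_b.sequence


def align_pair(
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    b5_rule: bool = True,
) -> PairAlignment:
    """Align two annotated records under the cytochrome-b5 rule.

    Full sequences are used iff both records carry a cytb5 domain;
    otherwise both are trimmed to their desaturase portion.
    """
    sa, sb = _pair_sequences(rec_a, rec_b, b5_rule)
    return smith_waterman(
        sa, sb, scheme, query_id=rec_a.id, subject_id=rec_b.id
    )


def all_vs_all(
    records: Sequence[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    initial_cutoff_logE: float = -5.0,
    b5_rule: bool = True,
) -> list[PairAlignment]:
    """All unordered pairwise alignments with ``logE <= cutoff``.

    One alignment per unordered pair, query/subject in lexicographic id
    order so the output is direction-unambiguous.  The logE filter is
    evaluated from the score alone; the (more expensive) traceback for
    identity and alignment length is only performed for retained pairs.
    """
    if len(records) < 2:
        raise ValueError("all_vs_all needs at least 2 records")
    ordered = sorted(records, key=lambda r: r.id)
    aligner = local_aligner(scheme)
    log10_2 = math.log10(2.0)
    out: list[PairAlignment] = []
    for i, rec_a in enumerate(ordered):
        for rec_b in ordered[i + 1 :]:
            sa, sb = _pair_sequences(rec_a, rec_b, b5_rule)
            score = int(round(aligner.score(sa, sb)))
            bits = bit_score(max(score, 0), scheme)
            le = (
                math.log10(len(sa)) + math.log10(len(sb)) - bits * log10_2
            )
            if le <= initial_cutoff_logE:
                out.append(
                    smith_waterman(
                        sa, sb, scheme,
                        query_id=rec_a.id, subject_id=rec_b.id,
                    )
                )
    return out


def write_edge_table(alignments: Iterable[PairAlignment], path) -> None:
    """Edge TSV: one row per retained pair, full float precision."""
    import pandas as pd

    rows = [
        {
            "query_id": a.query_id,
            "subject_id": a.subject_id,
            "raw_score": a.raw_score,
            "bit_score": repr(a.bit_score),
            "logE": repr(a.logE),
            "pct_identity": repr(a.pct_identity),
            "aln_len": a.aln_len,
            "m": a.m,
            "n": a.n,
        }
        for a in alignments
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query_id", "subject_id", "raw_score", "bit_score", "logE",
            "pct_identity", "aln_len", "m", "n",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> list[PairAlignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        PairAlignment(
            row["query_id"], row["subject_id"], int(row["raw_score"]),
            float(row["bit_score"]), float(row["logE"]),
            float(row["pct_identity"]), int(row["aln_len"]),
            int(row["m"]), int(row["n"]),
        )
        for _, row in df.iterrows()
    ]
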