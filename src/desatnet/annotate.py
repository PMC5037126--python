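"""Cluster annotation overlays, family naming, and binding-site reports.

Connected components acquire biological meaning from their sparse
characterized members: the consensus substrate head-group of a cluster is
the strict-majority label among characterized members (ties, or a
plurality short of a majority, report "ambiguous"; no characterized
members, "unknown").  Family names (FD, ME, FE, SD, ...) are transferred
from curated seed accessions.  The binding-site report compares a query
against a reference at user-supplied head-group-binding positions via
global alignment and flags charge-class changes — the sequence-level
analogue of comparing an acyl-CoA-binding pocket with an acyl-lipid one.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .align import DEFAULT_SCHEME, ScoringScheme, global_aligner
from .network import Partition
from .seqio import ProteinRecord

#: Residue charge classes partitioning the 20-letter alphabet.  Histidine
#: is classed as positive by convention (configurable in
#: :func:`residue_class` callers via a custom table); desaturase His-boxes
#: are catalytic, so callers studying them may prefer "special".
CHARGE_CLASSES: dict[str, str] = {
    **{r: "positive" for r in "KRH"},
    **{r: "negative" for r in "DE"},
    **{r: "polar-uncharged" for r in "STNQYC"},
    **{r: "hydrophobic" for r in "AVLIMFWGP"},
}
_CHARGED = {"positive", "negative"}


def residue_class(residue: str, table: Mapping[str, str] | None = None) -> str:
    """Charge class of a residue; X and gaps are "special"."""
    table = CHARGE_CLASSES if table is None else table
    return table.get(residue, "special")


@dataclass(frozen=True)
class ClusterSummary:
    label: str
    node_count: int
    protein_count: int
    kingdom_counts: tuple[tuple[str, int], ...]
    characterized_count: int
    substrate_counts: tuple[tuple[str, int], ...]
    consensus_substrate: str
    consensus_support: float
    member_ids: tuple[str, ...]
    family_name: str | None = None


def summarize_clusters(
    partition: Partition,
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
) -> list[ClusterSummary]:
    """Per-cluster annotation roll-up with consensus substrate.

    The consensus is decided by characterized members only — an
    uncharacterized member carries no vote.  Clusters are returned largest
    first (ties by label).
    """
    by_id = (
        records if isinstance(records, Mapping) else {r.id: r for r in records}
    )
    out = []
    for label in partition.labels:
        info = partition.clusters[label]
        member_ids = tuple(
            mid
            for nid in info.node_ids
            for mid in partition._members[nid]
        )
        mems = [by_id[m] for m in member_ids]
        characterized = [m for m in mems if m.characterized]
        substrate_counts = Counter(m.substrate for m in characterized)
        if not characterized:
            consensus, support = "unknown", 0.0
        else:
            top = max(substrate_counts.values())
            leaders = [s for s, c in substrate_counts.items() if c == top]
            support = top / len(characterized)
            if len(leaders) > 1 or top * 2 <= len(characterized):
                consensus = "ambiguous"
            else:
                consensus = leaders[0]
        out.append(
            ClusterSummary(
                label=label,
                node_count=info.node_count,
                protein_count=info.protein_count,
                kingdom_counts=tuple(
                    sorted(Counter(m.kingdom for m in mems).items())
                ),
                characterized_count=len(characterized),
                substrate_counts=tuple(sorted(substrate_counts.items())),
                consensus_substrate=consensus,
                consensus_support=support,
                member_ids=member_ids,
            )
        )
    out.sort(key=lambda s: (-s.protein_count, s.label))
    return out


def name_families(
    summaries: Sequence[ClusterSummary],
    seed_map: Mapping[str, str],
) -> list[ClusterSummary]:
    """Transfer family names from curated seed accessions onto clusters.

    A cluster is named by the unique family of the seeds it contains;
    seeds from two or more families flag it "conflict"; seedless clusters
    get systematic names ("cluster-01", ...) by descending size rank.
    Seeds not found in any cluster raise a warning only.
    """
    located: set[str] = set()
    named = []
    ranked = sorted(summaries, key=lambda s: (-s.protein_count, s.label))
    rank_of = {s.label: i + 1 for i, s in enumerate(ranked)}
    for summ in summaries:
        families = sorted(
            {
                seed_map[m]
                for m in summ.member_ids
                if m in seed_map and (located.add(m) or True)
            }
        )
        if not families:
            name = f"cluster-{rank_of[summ.label]:02d}"
        elif len(families) == 1:
            name = families[0]
        else:
            name = "conflict"
        named.append(replace(summ, family_name=name))
    missing = sorted(set(seed_map) - located)
    if missing:
        warnings.warn(
            f"seed accession(s) not found in any cluster: {missing}",
            UserWarning,
            stacklevel=2,
        )
    return named


@dataclass(frozen=True)
class SiteSubstitution:
    """One reference binding-site position compared across the alignment."""

    ref_position: int
    ref_residue: str
    query_residue: str  # "-" when the position is deleted in the query
    ref_class: str
    query_class: str
    charge_change: bool


@dataclass(frozen=True)
class SiteReport:
    sites: tuple[SiteSubstitution, ...]
    charged_to_uncharged: int

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


def _charge_change(class_a: str, class_b: str) -> bool:
    # exactly one side charged, or opposite charges
    a, b = class_a in _CHARGED, class_b in _CHARGED
    if a != b:
        return True
    return a and b and class_a != class_b


def binding_site_substitutions(
    ref_seq: str,
    query_seq: str,
    ref_positions: Sequence[int],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SiteReport:
    """Report query residues aligned to reference binding-site positions.

    Positions are 1-based indices into the reference (they must be
    supplied from a structure; they are not inferred).  Mapping uses a
    global alignment so that terminal binding-site residues are not
    truncated by local alignment.  ``charged_to_uncharged`` counts
    positions where a charged reference residue faces an uncharged (or
    gapped) query residue.
    """
    for p in ref_positions:
        if not 1 <= p <= len(ref_seq):
            raise IndexError(
                f"position {p} out of range for reference of length {len(ref_seq)}"
            )
    aln = global_aligner(scheme).align(ref_seq, query_seq)[0]
    # map reference residue index -> query residue index (or None at a gap)
    ref_to_query: dict[int, int | None] = {}
    indices = aln.indices  # 2 x columns; -1 marks a gap
    for col in range(indices.shape[1]):
        ri, qi = int(indices[0, col]), int(indices[1, col])
        if ri >= 0:
            ref_to_query[ri] = qi if qi >= 0 else None
    sites = []
    n_charged_to_uncharged = 0
    for p in ref_positions:
        ref_res = ref_seq[p - 1]
        qi = ref_to_query.get(p - 1)
        query_res = "-" if qi is None else query_seq[qi]
        ref_cls = residue_class(ref_res)
        query_cls = residue_class(query_res)
        change = _charge_change(ref_cls, query_cls)
        if ref_cls in _CHARGED and query_cls not in _CHARGED:
            n_charged_to_uncharged += 1
        sites.append(
            SiteSubstitution(p, ref_res, query_res, ref_cls, query_cls, change)
        )
    return SiteReport(tuple(sites), n_charged_to_uncharged)


def write_cluster_summary_table(
    summaries: Iterable[ClusterSummary], path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "label": s.label,
                "family_name": s.family_name or "",
                "node_count": s.node_count,
                "protein_count": s.protein_count,
                "characterized_count": s.characterized_count,
                "consensus_substrate": s.consensus_substrate,
                "consensus_support": repr(s.consensus_support),
                "kingdoms": ";".join(f"{k}:{c}" for k, c in s.kingdom_counts),
                "substrates": ";".join(f"{k}:{c}" for k, c in s.substrate_counts),
                "member_ids": ";".join(s.member_ids),
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def write_site_report(report: SiteReport, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "ref_position": s.ref_position,
                "ref_residue": s.ref_residue,
                "query_residue": s.query_residue,
                "ref_class": s.ref_class,
                "query_class": s.query_class,
                "charge_change": str(s.charge_change).lower(),
            }
            for s in report
        ]
    ).to_csv(path, sep="\t", index=False)
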