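"""Sequence and annotation I/O for the desaturase SSN pipeline.

Proteins enter the pipeline as FASTA; functional metadata (kingdom,
characterized substrate head-group, regioselectivity, domain ranges such as
a fused cytochrome b5) arrives in a separate TSV keyed by accession and is
joined onto the records.  The module also applies the superfamily length
filter and produces the desaturase-domain-trimmed sequence used for E-value
computation when only one partner of a pair carries a cytochrome b5 fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

KINGDOMS = frozenset(
    {"animal", "plant", "fungus", "protist", "cyanobacteria",
     "other-prokaryote", "unknown"}
)
SUBSTRATES = frozenset(
    {"acyl-CoA", "acyl-PC", "MGDG", "sphingolipid", "phospholipid",
     "other", "unknown"}
)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

#: Named length-filter presets. "methods" is the procedural record
#: (exclude <250 aa or >550 aa); "overview" is the 350-550 aa range used
#: when assembling the single-domain + b5-fusion overview corpus.
LENGTH_PRESETS: dict[str, tuple[int, int]] = {
    "methods": (250, 550),
    "overview": (350, 550),
}


class AnnotationWarning(UserWarning):
    """Non-fatal problems while joining annotation tables."""


@dataclass(frozen=True)
class DomainRange:
    """A labelled residue range, 1-based inclusive."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid domain range {self.label}:{self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with taxonomy, function and domain metadata.

    ``substrate != "unknown"`` implies ``characterized`` — an uncharacterized
    protein cannot carry a substrate claim.
    """

    id: str
    sequence: str
    kingdom: str = "unknown"
    organism: str = ""
    characterized: bool = False
    substrate: str = "unknown"
    regio: str = ""
    domains: tuple[DomainRange, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"record {self.id!r}: unknown kingdom {self.kingdom!r}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(
                f"record {self.id!r}: unknown substrate {self.substrate!r}"
            )
        if self.substrate != "unknown" and not self.characterized:
            raise ValueError(
                f"record {self.id!r}: substrate {self.substrate!r} given but "
                "characterized is false"
            )
        for d in self.domains:
            if d.end > self.length:
                raise ValueError(
                    f"record {self.id!r}: domain {d.label}:{d.start}-{d.end} "
                    f"exceeds sequence length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def domain_ranges(self, label: str) -> tuple[DomainRange, ...]:
        return tuple(d for d in self.domains if d.label == label)

    @property
    def has_cytb5(self) -> bool:
        return any(d.label == "cytb5" for d in self.domains)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into bare :class:`ProteinRecord` objects.

    Annotations default to unknown/empty until :func:`join_annotations`.
    Duplicate ids and non-amino-acid characters (other than X) are hard
    errors naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def parse_domain_spec(spec: str, *, context: str = "") -> tuple[DomainRange, ...]:
    """Parse ``"label:start-end;label:start-end"`` into domain ranges."""
    spec = spec.strip()
    if not spec:
        return ()
    out = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            label, rng = part.split(":")
            start_s, end_s = rng.split("-")
            out.append(DomainRange(label.strip(), int(start_s), int(end_s)))
        except ValueError as exc:
            raise ValueError(
                f"malformed domain range {part!r}{' in ' + context if context else ''}"
            ) from exc
    return tuple(out)


def format_domain_spec(domains: Sequence[DomainRange]) -> str:
    return ";".join(f"{d.label}:{d.start}-{d.end}" for d in domains)


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", "", "nan"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def join_annotations(
    records: Sequence[ProteinRecord],
    table: pd.DataFrame | str | Path,
) -> list[ProteinRecord]:
    """Join a per-protein annotation table onto FASTA records.

    The table is keyed by ``id`` with columns kingdom, organism, substrate,
    regio, characterized and domains (``label:start-end`` joined by ``;``).
    Rows whose id is absent from the records are reported with an
    :class:`AnnotationWarning`, not fatal.  An unrecognized substrate value
    is mapped to ``"other"`` with a warning so real-world tables do not
    hard-fail; a substrate on an uncharacterized protein is an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_annotation_table(table)
    by_id = {r.id: r for r in records}
    annotated: dict[str, ProteinRecord] = {}
    missing = []
    for _, row in table.iterrows():
        rid = str(row["id"])
        if rid not in by_id:
            missing.append(rid)
            continue
        substrate = str(row.get("substrate", "unknown")).strip() or "unknown"
        if substrate not in SUBSTRATES:
            warnings.warn(
                f"row {rid!r}: unrecognized substrate {substrate!r} mapped to 'other'",
                AnnotationWarning,
                stacklevel=2,
            )
            substrate = "other"
        domains = parse_domain_spec(
            str(row.get("domains", "")), context=f"row {rid!r}"
        )
        annotated[rid] = replace(
            by_id[rid],
            kingdom=str(row.get("kingdom", "unknown")).strip() or "unknown",
            organism=str(row.get("organism", "")).strip(),
            characterized=_coerce_bool(row.get("characterized", False)),
            substrate=substrate,
            regio=str(row.get("regio", "")).strip(),
            domains=domains,
        )
    if missing:
        warnings.warn(
            f"{len(missing)} annotation row(s) with no matching record: "
            f"{missing[:10]}",
            AnnotationWarning,
            stacklevel=2,
        )
    return [annotated.get(r.id, r) for r in records]


def filter_by_length(
    records: Sequence[ProteinRecord],
    min_len: int = LENGTH_PRESETS["methods"][0],
    max_len: int = LENGTH_PRESETS["methods"][1],
) -> list[ProteinRecord]:
    """Retain records with ``min_len <= length <= max_len``, order-preserving.

    The default bounds exclude partial proteins (<250 aa) and multi-domain
    fusions beyond desaturase+cytb5 (>550 aa).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= r.length <= max_len]


def effective_sequence(record: ProteinRecord, mode: str = "full") -> str:
    """Sequence used for E-value computation under the cytochrome-b5 rule.

    ``mode="full"`` returns the whole sequence; ``mode="desaturase-only"``
    removes all residues inside cytb5-labelled ranges, so that a fused
    protein is compared to an unfused partner on its desaturase portion
    only.  Records without a cytb5 domain are returned unchanged in both
    modes.
    """
    if mode not in {"full", "desaturase-only"}:
        raise ValueError(f"unknown mode {mode!r}")
    ranges = sorted(record.domain_ranges("cytb5"), key=lambda d: d.start)
    if mode == "full" or not ranges:
        return record.sequence
    for prev, cur in zip(ranges, ranges[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"record {record.id!r}: overlapping cytb5 ranges "
                f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
            )
    keep = []
    pos = 0
    for d in ranges:
        keep.append(record.sequence[pos : d.start - 1])
        pos = d.end
    keep.append(record.sequence[pos:])
    return "".join(keep)


def write_annotation_table(
    records: Iterable[ProteinRecord], path: str | Path
) -> None:
    rows = [
        {
            "id": r.id,
            "kingdom": r.kingdom,
            "organism": r.organism,
            "substrate": r.substrate,
            "regio": r.regio,
            "characterized": str(r.characterized).lower(),
            "domains": format_domain_spec(r.domains),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
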