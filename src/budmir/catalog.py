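"""Annotation of unique small-RNA sequences against a mature-miRNA reference.

A sequenced read is "annotated" when it aligns to a mature miRNA with at most
``max_mismatch`` substitutions (default 2).  The alignment contract is
deliberately simple and fully deterministic: full-length, ungapped,
substitution-only, with the shorter sequence allowed to sit anywhere inside
the longer one as long as the length difference is at most 2 nt; terminal
overhangs of the longer sequence are not counted as mismatches.  T and U are
equivalent throughout.

Reads matching a focal-species reference entry (default species code "vvi")
are classified ``known_in_focal``; reads matching only other species are
``conserved``; everything else is ``unannotated``.  Sequences with >= 20
combined counts across the two libraries are "highly abundant" and feed the
downstream differential-abundance statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from budmir.io import read_fasta

logger = logging.getLogger(__name__)

_ID_RE = re.compile(r"^([A-Za-z]{3})-mi[rR](\d+)")
_VALID_NT = set("ACGTU")

#: maximum length difference tolerated by the full-length alignment contract
MAX_LENGTH_SLACK = 2


def _normalize(seq: str) -> str:
    """Uppercase and collapse the T/U distinction (DNA alphabet internally)."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)!r}")
    return seq


def parse_mirna_id(mirna_id: str) -> tuple[str, str]:
    """Split a miRBase-style mature id into (species code, numeric family).

    >>> parse_mirna_id("vvi-miR156a")
    ('vvi', '156')
    """
    m = _ID_RE.match(mirna_id)
    if m is None:
        raise ValueError(f"cannot parse miRNA id {mirna_id!r} "
                         "(expected e.g. 'vvi-miR156a')")
    return m.group(1).lower(), m.group(2)


@dataclass(frozen=True)
class MiRNARef:
    """One mature miRNA reference record."""

    mirna_id: str
    species: str
    family: str
    sequence: str
    is_focal_species: bool

    @classmethod
    def from_fasta_entry(cls, mirna_id: str, sequence: str,
                         focal_species: str = "vvi") -> "MiRNARef":
        species, family = parse_mirna_id(mirna_id)
        seq = _normalize(sequence)
        if not seq:
            raise ValueError(f"empty sequence for {mirna_id}")
        return cls(
            mirna_id=mirna_id,
            species=species,
            family=family,
            sequence=seq,
            is_focal_species=(species == focal_species.lower()),
        )


def load_mirna_reference(path: str | Path,
                         focal_species: str = "vvi") -> list[MiRNARef]:
    """Load a mature-miRNA FASTA; ids must parse, duplicates are rejected."""
    records = read_fasta(path)
    return [
        MiRNARef.from_fasta_entry(name, seq, focal_species=focal_species)
        for name, seq in records.items()
    ]


def _min_mismatches(read: str, ref: str) -> int | None:
    """Mismatch count under the full-length ungapped contract, or None.

    The shorter sequence slides fully inside the longer one; the minimum
    Hamming distance over all such placements is returned.  Placements only
    exist when the length difference is <= MAX_LENGTH_SLACK.
    """
    if abs(len(read) - len(ref)) > MAX_LENGTH_SLACK:
        return None
    short, long_ = (read, ref) if len(read) <= len(ref) else (ref, read)
    best: int | None = None
    for off in range(len(long_) - len(short) + 1):
        mm = sum(a != b for a, b in zip(short, long_[off:off + len(short)]))
        if best is None or mm < best:
            best = mm
    return best


def match_read(sequence: str, ref: Iterable[MiRNARef],
               max_mismatch: int = 2) -> list[tuple[str, int]]:
    """Match one read against the reference; [(mirna_id, mismatches), ...].

    Results are sorted by ascending mismatch count, ties broken by id.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    read = _normalize(sequence)
    hits: list[tuple[str, int]] = []
    for rec in ref:
        mm = _min_mismatches(read, rec.sequence)
        if mm is not None and mm <= max_mismatch:
            hits.append((rec.mirna_id, mm))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


@dataclass
class SeqAnnotation:
    """Annotation of one unique read: its matches, status, and families."""

    sequence: str
    matches: list[tuple[str, int]]
    best_mismatch: int | None
    status: str  # known_in_focal | conserved | unannotated
    families: set[str] = field(default_factory=set)


def classify_annotation(matches: Sequence[tuple[str, int]],
                        ref: Iterable[MiRNARef]) -> str:
    """known_in_focal if any focal-species match, else conserved, else unannotated."""
    if not matches:
        return "unannotated"
    by_id = {r.mirna_id: r for r in ref}
    for mirna_id, _ in matches:
        if by_id[mirna_id].is_focal_species:
            return "known_in_focal"
    return "conserved"


def annotate_read(sequence: str, ref: Sequence[MiRNARef],
                  max_mismatch: int = 2) -> SeqAnnotation:
    """Match + classify one read; families come from the best-mismatch tier."""
    matches = match_read(sequence, ref, max_mismatch=max_mismatch)
    status = classify_annotation(matches, ref)
    if matches:
        best = matches[0][1]
        by_id = {r.mirna_id: r for r in ref}
        families = {by_id[mid].family for mid, mm in matches if mm == best}
    else:
        best = None
        families = set()
    return SeqAnnotation(
        sequence=_normalize(sequence),
        matches=list(matches),
        best_mismatch=best,
        status=status,
        families=families,
    )


@dataclass
class SeqAbundance:
    """One unique small-RNA sequence with per-library counts and annotation."""

    sequence: str
    count_ld: int
    count_sd: int
    annotation: SeqAnnotation
    rpm_ld: float = 0.0
    rpm_sd: float = 0.0

    @property
    def total_count(self) -> int:
        return self.count_ld + self.count_sd

    def is_highly_abundant(self, min_total: int = 20) -> bool:
        return self.total_count >= min_total


def filter_highly_abundant(records: Iterable[SeqAbundance],
                           min_total: int = 20) -> list[SeqAbundance]:
    """Keep annotated sequences with >= min_total combined counts."""
    records = list(records)
    kept = [
        r for r in records
        if r.is_highly_abundant(min_total) and r.annotation.status != "unannotated"
    ]
    logger.info("highly-abundant filter: retained %d / %d sequences "
                "(min_total=%d)", len(kept), len(records), min_total)
    return kept


def build_catalog(counts: pd.DataFrame, ref: Sequence[MiRNARef],
                  max_mismatch: int = 2) -> list[SeqAbundance]:
    """Annotate a counts table (columns: sequence, count_ld, count_sd).

    RPM values are filled in against each library's total counts.
    """
    for col in ("sequence", "count_ld", "count_sd"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    total_ld = int(counts["count_ld"].sum())
    total_sd = int(counts["count_sd"].sum())
    out: list[SeqAbundance] = []
    for row in counts.itertuples(index=False):
        ann = annotate_read(str(row.sequence), ref, max_mismatch=max_mismatch)
        rec = SeqAbundance(
            sequence=ann.sequence,
            count_ld=int(row.count_ld),
            count_sd=int(row.count_sd),
            annotation=ann,
        )
        rec.rpm_ld = rec.count_ld / total_ld * 1e6 if total_ld > 0 else 0.0
        rec.rpm_sd = rec.count_sd / total_sd * 1e6 if total_sd > 0 else 0.0
        out.append(rec)
    return out


def catalog_to_frame(records: Iterable[SeqAbundance]) -> pd.DataFrame:
    """Flatten SeqAbundance records to the annotated-catalog TSV layout."""
    rows = []
    for r in records:
        rows.append({
            "sequence": r.sequence,
            "count_ld": r.count_ld,
            "count_sd": r.count_sd,
            "rpm_ld": r.rpm_ld,
            "rpm_sd": r.rpm_sd,
            "status": r.annotation.status,
            "best_mismatch": (r.annotation.best_mismatch
                              if r.annotation.best_mismatch is not None else ""),
            "families": ",".join(sorted(r.annotation.families)),
            "matches": ";".join(f"{m}:{mm}" for m, mm in r.annotation.matches),
        })
    return pd.DataFrame(rows)
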