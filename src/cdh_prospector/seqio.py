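"""Sequence records, FASTA I/O, dataset merging and length filtering.

Protein datasets mined from public databases arrive as FASTA exports whose
header token is a bare accession (e.g. ``KAH7237211.1``).  This module turns
those files into validated in-memory records and provides the two set
operations every downstream stage shares: union-with-deduplication of
several search results, and inclusive length windows (150–1100 residues for
network construction, 700–1000 for the full-length CDH selection).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
#: residues rejected by default; coercible to X (ambiguity / non-proteinogenic)
NONCANONICAL = set("BZJUO*")
DNA_ALPHABET = set("ACGT")


class SequenceError(ValueError):
    """Invalid sequence content or duplicated accessions."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional curation metadata.

    ``taxonomy`` is a division label (e.g. Ascomycota/Basidiomycota),
    ``lifestyle`` a free-form ecological flag ("plant-associated" drives
    candidate prioritisation) and ``class_label`` the CDH class when known.
    """

    accession: str
    sequence: str
    description: str = ""
    taxonomy: str | None = None
    lifestyle: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise SequenceError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise SequenceError(f"{self.accession}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA sequence (A/C/G/T only); ``frame_offset`` marks codon 1."""

    accession: str
    sequence: str
    description: str = ""
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.accession:
            raise SequenceError("accession must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"{self.accession}: illegal DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergeReport:
    """Bookkeeping for :func:`merge_dedup`."""

    per_source: list[int] = field(default_factory=list)
    merged_total: int = 0
    duplicates_removed: int = 0
    conflicts: list[str] = field(default_factory=list)


def _validate_protein(accession: str, seq: str, coerce: bool) -> str:
    bad = set(seq) - PROTEIN_ALPHABET
    if not bad:
        return seq
    if coerce and bad <= NONCANONICAL:
        for ch in bad:
            seq = seq.replace(ch, "X")
        return seq
    raise SequenceError(
        f"{accession}: illegal protein characters {sorted(bad)}"
    )


def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "dna"] = "protein",
    coerce_noncanonical: bool = False,
) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a FASTA file into validated records.

    The header token before the first whitespace becomes the accession, the
    remainder the description.  Accessions must be unique within the file.
    Non-canonical residues (B, Z, U, O, J, ``*``) raise by default;
    ``coerce_noncanonical=True`` maps them to X instead.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        warnings.warn(f"{path}: empty FASTA, returning empty dataset")
        return []
    records: list = []
    seen: set[str] = set()
    for entry in raw:
        accession = entry.id
        if accession in seen:
            raise SequenceError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        desc = entry.description[len(entry.id):].strip()
        seq = str(entry.seq).upper()
        if alphabet == "protein":
            seq = _validate_protein(accession, seq, coerce_noncanonical)
            records.append(ProteinRecord(accession, seq, desc))
        else:
            records.append(NucleotideRecord(accession, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord | NucleotideRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records as FASTA; inverse of :func:`read_fasta`."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.accession,
                  description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


def merge_dedup(
    *datasets: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], MergeReport]:
    """Union several record sets, keeping the first occurrence per accession.

    Mirrors the merge step after combining independent database searches,
    where duplicate sequence IDs are deleted.  Records whose accession
    re-appears with a *different* sequence are kept in their first-seen form
    and reported as conflicts.
    """
    report = MergeReport(per_source=[len(d) for d in datasets])
    merged: dict[str, ProteinRecord] = {}
    for dataset in datasets:
        for rec in dataset:
            prev = merged.get(rec.accession)
            if prev is None:
                merged[rec.accession] = rec
            else:
                report.duplicates_removed += 1
                if prev.sequence != rec.sequence:
                    report.conflicts.append(rec.accession)
                    logger.warning(
                        "accession %s re-seen with a different sequence; "
                        "keeping the first occurrence", rec.accession)
    out = list(merged.values())
    report.merged_total = len(out)
    return out, report


def filter_by_length(
    records: Sequence[ProteinRecord],
    min_len: int,
    max_len: int,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (kept, removed) by an inclusive length window.

    Both bounds are inclusive: the standard windows are [150, 1100] residues
    for network construction and [700, 1000] for full-length two-domain CDH.
    """
    if min_len < 0 or max_len < 0:
        raise ValueError("length bounds must be non-negative")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept, removed = [], []
    for rec in records:
        (kept if min_len <= len(rec) <= max_len else removed).append(rec)
    return kept, removed


def with_metadata(rec: ProteinRecord, **kwargs) -> ProteinRecord:
    """Return a copy of ``rec`` with metadata fields replaced."""
    return replace(rec, **kwargs)
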