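"""Reading, validating, and filtering protein sequences.

Records are read from FASTA, uppercased, and optionally labelled per file
(one FASTA of cancerlectins, one of noncancerlectins). Validation excludes
whole records rather than dropping residues: every downstream descriptor
indexes the strict 20-letter alphabet, and the lag-parameterised families
additionally need a minimum sequence length, so a record that fails either
rule is reported and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import AMINO_ACIDS

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

_CANONICAL = frozenset(AMINO_ACIDS)


class FastaFormatError(ValueError):
    """Raised for FASTA entries the pipeline cannot represent."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an identifier and optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r}/{NEGATIVE!r}, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_canonical(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= _CANONICAL

    def noncanonical_residues(self) -> set[str]:
        return set(self.sequence) - _CANONICAL


@dataclass
class FilterReport:
    """Bookkeeping of a validation pass: kept count plus per-record reasons."""

    kept: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    REASON_NONCANONICAL = "non-canonical residue"
    REASON_TOO_SHORT = "too short for descriptor parameters"

    @property
    def total(self) -> int:
        return self.kept + len(self.excluded)


def read_fasta(path: str | Path, label: Optional[str] = None) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, uppercasing sequences.

    ``label`` (``"positive"``/``"negative"``) is applied to every record.
    An empty file yields an empty list with a logged warning; an entry with
    an empty sequence raises :class:`FastaFormatError` naming its header.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace(" ", "")
        if not seq:
            raise FastaFormatError(f"empty sequence for FASTA entry {entry.id!r} in {path}")
        records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA with 60-column line wrapping."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def validate_records(
    records: Sequence[ProteinRecord], min_length: int = 1
) -> tuple[list[ProteinRecord], FilterReport]:
    """Keep fully canonical records with length >= ``min_length``.

    Exclusions are reported, never raised: the report lists every dropped
    record with its reason, and ``kept + len(excluded)`` equals the input
    count. Descriptor families re-check their own stricter length
    preconditions; ``min_length`` here guards the lag-parameterised families
    (a lag-30 descriptor needs L > 30, hence ``min_length=31``).
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    kept: list[ProteinRecord] = []
    report = FilterReport()
    for rec in records:
        if not rec.is_canonical():
            report.excluded.append((rec.id, FilterReport.REASON_NONCANONICAL))
        elif rec.length < min_length:
            report.excluded.append((rec.id, FilterReport.REASON_TOO_SHORT))
        else:
            kept.append(rec)
    report.kept = len(kept)
    if report.excluded:
        logger.info(
            "validate_records: kept %d of %d (%d excluded)",
            report.kept, report.total, len(report.excluded),
        )
    return kept, report


def read_labelled(
    pos_path: str | Path, neg_path: str | Path, min_length: int = 1
) -> tuple[list[ProteinRecord], FilterReport]:
    """Read a positive and a negative FASTA and validate the union."""
    records = read_fasta(pos_path, label=POSITIVE) + read_fasta(neg_path, label=NEGATIVE)
    return validate_records(records, min_length=min_length)
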