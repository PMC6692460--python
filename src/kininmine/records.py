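"""Sequence record types and FASTA/GenBank input.

Two light containers are used throughout the package: :class:`NucleotideRecord`
for DNA (cDNA, genomic fragments) and :class:`PrecursorRecord` for a candidate
neuropeptide precursor protein.  File parsing is delegated to Bio.SeqIO; the
containers only enforce the alphabets the downstream stages assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .errors import InputError

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _check_alphabet(sequence: str, allowed: frozenset, what: str) -> None:
    for pos, ch in enumerate(sequence, start=1):
        if ch not in allowed:
            raise InputError(f"{what}: invalid residue {ch!r} at position {pos}")


@dataclass(frozen=True)
class NucleotideRecord:
    """A named DNA sequence restricted to the A/C/G/T/N alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        _check_alphabet(self.sequence, DNA_ALPHABET, f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor protein; ``signal_end`` is the 1-based index of the last
    signal-peptide residue when an external prediction is supplied."""

    id: str
    sequence: str
    signal_end: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        _check_alphabet(self.sequence, PROTEIN_ALPHABET, f"record {self.id!r}")
        if self.signal_end is not None and not 0 < self.signal_end < len(self.sequence):
            raise InputError(
                f"record {self.id!r}: signal_end {self.signal_end} outside (0, {len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _iter_seqio(path: str | Path, fmt: str) -> Iterator:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        yield from SeqIO.parse(str(path), fmt)
    except ValueError as exc:  # malformed file
        raise InputError(f"{path}: {exc}") from exc


def read_nucleotide_records(path: str | Path, fmt: str = "fasta") -> list[NucleotideRecord]:
    """Read DNA records from a FASTA or GenBank flat file."""
    records = [
        NucleotideRecord(rec.id, str(rec.seq), rec.description)
        for rec in _iter_seqio(path, fmt)
    ]
    if not records:
        raise InputError(f"{path}: no records found")
    return records


def read_precursor_records(path: str | Path, fmt: str = "fasta") -> list[PrecursorRecord]:
    """Read protein records from a FASTA or GenBank flat file."""
    records = [
        PrecursorRecord(rec.id, str(rec.seq), description=rec.description)
        for rec in _iter_seqio(path, fmt)
    ]
    if not records:
        raise InputError(f"{path}: no records found")
    return records
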