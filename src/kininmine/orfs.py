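"""Six-frame translation and open-reading-frame discovery.

Candidate precursor proteins are found by translating a nucleotide record in
all six frames and scanning each conceptual translation for Met-initiated
reading frames.  Translation itself is delegated to Bio.Seq; this module owns
the frame bookkeeping and the ORF ranking conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import ContractError
from .records import NucleotideRecord

#: Stop codons are rendered with this sentinel in frame translations.
STOP = "*"

#: Codons containing N translate to this unknown-residue sentinel.
UNKNOWN = "X"

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCall:
    """One Met-initiated open reading frame.

    ``start`` is the 1-based forward-strand coordinate of the first base of
    the start codon (for reverse-frame calls this is the forward-strand
    position complementary to the A of the ATG, i.e. the highest-numbered
    base of the codon).  ``coding_length_nt`` excludes the stop codon;
    ``partial`` marks ORFs running into the end of the frame without a stop.
    """

    frame: int
    start: int
    coding_length_nt: int
    protein: str
    partial: bool = False

    @property
    def length_with_stop_nt(self) -> int:
        """Coding length including the stop codon (0 added when partial)."""
        return self.coding_length_nt + (0 if self.partial else 3)

    @property
    def has_ambiguous(self) -> bool:
        return UNKNOWN in self.protein


def translate_six_frames(record: NucleotideRecord) -> dict[int, str]:
    """Translate ``record`` in frames +1..+3 and -1..-3.

    Forward frames translate the forward strand at offsets 0..2; reverse
    frames translate the reverse complement at the same offsets.  Stop codons
    become ``*`` and trailing partial codons are dropped.
    """
    if len(record) < 3:
        raise ContractError(f"record {record.id!r}: need >= 3 nt to translate")
    fwd = Seq(record.sequence)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for offset in range(3):
        for frame, strand in ((offset + 1, fwd), (-(offset + 1), rev)):
            sub = strand[offset : offset + 3 * ((len(strand) - offset) // 3)]
            out[frame] = str(sub.translate(table=1, stop_symbol=STOP))
    return out


def find_orfs(record: NucleotideRecord, min_protein_len: int = 1) -> list[OrfCall]:
    """All Met-initiated ORFs in six frames, longest protein first.

    Ties are broken by earlier forward-strand start, then by frame order
    +1, +2, +3, -1, -2, -3.
    """
    if min_protein_len < 1:
        raise ContractError("min_protein_len must be >= 1")
    translations = translate_six_frames(record)
    n = len(record)
    calls: list[OrfCall] = []
    for frame in FRAMES:
        protein = translations[frame]
        offset = abs(frame) - 1
        for match in re.finditer(r"M[^*]*", protein):
            aa_start, aa_end = match.start(), match.end()
            partial = aa_end == len(protein)
            prot = match.group(0)
            if len(prot) < min_protein_len:
                continue
            nt_in_frame = offset + 3 * aa_start  # 0-based on the translated strand
            if frame > 0:
                start = nt_in_frame + 1
            else:
                start = n - nt_in_frame  # forward-strand coordinate of the first codon base
            calls.append(OrfCall(frame, start, 3 * len(prot), prot, partial))
    frame_rank = {f: i for i, f in enumerate(FRAMES)}
    calls.sort(key=lambda c: (-len(c.protein), c.start, frame_rank[c.frame]))
    return calls
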