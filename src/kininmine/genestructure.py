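"""Gene-structure inference by splice-aware cDNA-to-genomic comparison.

For a cloned mRNA and a near-identical genomic sequence the exon/intron
architecture can be recovered without full dynamic programming: exact k-mer
anchors between the two sequences are collapsed into maximal co-diagonal
segments, a colinear chain of segments is selected, and diagonal jumps of at
least the minimum intron length become introns.  The exact cut point within
the junction ambiguity window is chosen so the intron carries canonical
GT..AG donor/acceptor dinucleotides (fallback GC..AG, then leftmost donor).

Coordinates are 1-based inclusive throughout; GFF3 export follows the GFF3
convention (which is also 1-based inclusive).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .errors import AlignmentError, ContractError
from .records import NucleotideRecord

MIN_INTRON_DEFAULT = 30


@dataclass(frozen=True)
class Intron:
    start: int  # 1-based inclusive, genomic
    end: int
    donor: str  # first two intron bases
    acceptor: str  # last two intron bases

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron architecture of one gene on one genomic record."""

    cdna_id: str
    genomic_id: str
    exons: tuple[tuple[int, int], ...]  # genomic, 1-based inclusive, ascending
    introns: tuple[Intron, ...]
    cdna_span: tuple[int, int]  # aligned cDNA interval, 1-based inclusive
    cdna_coverage: float  # fraction of the cDNA covered by exons
    identity: float  # percent matching bases over exonic columns

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(i.length for i in self.introns)


def _codiagonal_segments(cdna: str, genomic: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal runs of exact k-mer anchors on a common diagonal.

    Returns ``(c_start, length, diag)`` triples, 0-based, where the segment
    matches ``cdna[c_start : c_start+length]`` to
    ``genomic[c_start+diag : c_start+diag+length]``.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(genomic) - k + 1):
        index[genomic[j : j + k]].append(j)
    # anchor cdna positions per diagonal
    diag_hits: dict[int, list[int]] = defaultdict(list)
    for i in range(len(cdna) - k + 1):
        hits = index.get(cdna[i : i + k])
        if hits is None or len(hits) > 64:  # skip hyper-repetitive seeds
            continue
        for j in hits:
            diag_hits[j - i].append(i)
    segments = []
    for diag, starts in diag_hits.items():
        starts.sort()
        run_start = starts[0]
        prev = starts[0]
        for i in starts[1:]:
            if i <= prev + 1:
                prev = i
                continue
            segments.append((run_start, prev - run_start + k, diag))
            run_start = prev = i
        segments.append((run_start, prev - run_start + k, diag))
    return segments


def _chain(segments: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear chain (increasing cDNA and genomic coordinates),
    maximising matched length with a mild penalty on diagonal jumps."""
    segs = sorted(segments, key=lambda s: (s[0], s[2]))
    n = len(segs)
    score = [0.0] * n
    back = [-1] * n
    for b in range(n):
        cb, lb, db = segs[b]
        score[b] = float(lb)
        for a in range(b):
            ca, la, da = segs[a]
            if ca + la <= cb + lb and ca <= cb and da <= db and ca + da < cb + db:
                gap_pen = 0.01 * (db - da) + (5.0 if db != da else 0.0)
                cand = score[a] + lb - gap_pen
                if cand > score[b]:
                    score[b] = cand
                    back[b] = a
    if not segs:
        return []
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(segs[best])
        best = back[best]
    return chain[::-1]


def _pick_boundary(
    genomic: str, lo: int, hi: int, d_left: int, d_right: int
) -> tuple[int, str, str]:
    """Choose the cut point s in [lo, hi] (0-based cDNA index of the last
    exon base before the intron), preferring GT..AG, then GC..AG, then
    the leftmost candidate."""
    best = None
    for s in range(lo, hi + 1):
        g_donor = s + d_left + 1
        g_acc = s + d_right - 1
        if g_donor < 0 or g_acc + 1 >= len(genomic):
            continue
        donor = genomic[g_donor : g_donor + 2]
        acceptor = genomic[g_acc : g_acc + 2]
        if donor == "GT" and acceptor == "AG":
            return s, donor, acceptor
        rank = 1 if (donor == "GC" and acceptor == "AG") else 2
        if best is None or rank < best[0]:
            best = (rank, s, donor, acceptor)
    if best is None:
        raise AlignmentError("no admissible intron boundary in the ambiguity window")
    return best[1], best[2], best[3]


def spliced_align(
    cdna: NucleotideRecord,
    genomic: NucleotideRecord,
    anchor_k: int = 15,
    min_intron: int = MIN_INTRON_DEFAULT,
) -> GeneModel:
    """Infer a gene model by anchoring ``cdna`` on ``genomic``.

    Raises :class:`AlignmentError` when no colinear anchor chain covers at
    least half of the cDNA.
    """
    if anchor_k < 11:
        raise ContractError("anchor_k must be >= 11")
    C, G = cdna.sequence, genomic.sequence
    chain = _chain(_codiagonal_segments(C, G, anchor_k))
    if not chain:
        raise AlignmentError("no exact anchors between cDNA and genomic sequence")

    # merge chained segments into exon blocks: diagonal jumps below the
    # minimum intron length are treated as mismatch patches within one exon
    blocks: list[list[int]] = []  # [c_start, c_end, diag] 0-based inclusive
    for c, ln, d in chain:
        if blocks and d - blocks[-1][2] < min_intron:
            blocks[-1][1] = c + ln - 1
        else:
            blocks.append([c, c + ln - 1, d])

    # extend the terminal blocks to the cDNA ends along their diagonals
    blocks[0][0] = max(0, -blocks[0][2])
    blocks[-1][1] = min(len(C) - 1, len(G) - 1 - blocks[-1][2])

    # fix the exact cut points between adjacent blocks
    exon_bounds: list[list[int]] = [[blocks[0][0], None, blocks[0][2]]]
    introns: list[Intron] = []
    for left, right in zip(blocks, blocks[1:]):
        window = anchor_k
        lo = max(left[0], right[0] - 1 - window)
        hi = min(left[1] + window, right[1] - 1)
        if lo > hi:
            raise AlignmentError("inconsistent junction between anchor blocks")
        s, donor, acceptor = _pick_boundary(G, lo, hi, left[2], right[2])
        exon_bounds[-1][1] = s
        exon_bounds.append([s + 1, None, right[2]])
        introns.append(
            Intron(
                start=s + left[2] + 2, end=s + right[2] + 1, donor=donor, acceptor=acceptor
            )
        )
    exon_bounds[-1][1] = blocks[-1][1]

    exons = []
    matches = 0
    aligned = 0
    for c0, c1, d in exon_bounds:
        exons.append((c0 + d + 1, c1 + d + 1))
        aligned += c1 - c0 + 1
        matches += sum(1 for i in range(c0, c1 + 1) if C[i] == G[i + d])
    coverage = aligned / len(C)
    if coverage < 0.5:
        raise AlignmentError(
            f"anchor chain covers only {coverage:.0%} of the cDNA (need >= 50%)"
        )
    return GeneModel(
        cdna_id=cdna.id,
        genomic_id=genomic.id,
        exons=tuple(exons),
        introns=tuple(introns),
        cdna_span=(exon_bounds[0][0] + 1, exon_bounds[-1][1] + 1),
        cdna_coverage=coverage,
        identity=100.0 * matches / aligned,
    )


def validate_splice(model: GeneModel) -> list[str]:
    """Per-intron splice classification: canonical GT..AG, semi-canonical
    GC..AG, otherwise non-canonical."""
    flags = []
    for intron in model.introns:
        if intron.donor == "GT" and intron.acceptor == "AG":
            flags.append("canonical")
        elif intron.donor == "GC" and intron.acceptor == "AG":
            flags.append("semi-canonical")
        else:
            flags.append("non-canonical")
    return flags


def write_gff3(model: GeneModel, path: str | Path, source: str = "kininmine") -> None:
    """Write the gene model as GFF3 gene/mRNA/exon features."""
    gene_id = f"{model.cdna_id}.gene"
    mrna_id = f"{model.cdna_id}.mRNA"
    start = model.exons[0][0]
    end = model.exons[-1][1]
    lines = ["##gff-version 3"]

    def feat(ftype: str, s: int, e: int, attrs: str) -> str:
        return "\t".join(
            [model.genomic_id, source, ftype, str(s), str(e), ".", "+", ".", attrs]
        )

    lines.append(feat("gene", start, end, f"ID={gene_id}"))
    lines.append(feat("mRNA", start, end, f"ID={mrna_id};Parent={gene_id}"))
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(feat("exon", s, e, f"ID={mrna_id}.exon{i};Parent={mrna_id}"))
    Path(path).write_text("\n".join(lines) + "\n")


def summarize(model: GeneModel) -> str:
    """Human-readable one-paragraph summary of the model."""
    parts = [
        f"{model.cdna_id} vs {model.genomic_id}:",
        f"{len(model.exons)} exon(s) {list(model.exon_lengths)} bp",
    ]
    if model.introns:
        flags = validate_splice(model)
        parts.append(
            "intron(s) "
            + ", ".join(
                f"{i.length} bp {i.donor}..{i.acceptor} ({f})"
                for i, f in zip(model.introns, flags)
            )
        )
    parts.append(f"coverage {model.cdna_coverage:.1%}, identity {model.identity:.1f}%")
    return "; ".join(parts)
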