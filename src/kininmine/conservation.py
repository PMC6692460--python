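"""Anchored kinin alignment and per-position information content.

Kinin paracopies share an invariant amidated C-terminal Gly, so the family
alignment is built gap-free by right-justifying every sequence on that
residue.  Column conservation is then the classical sequence-logo measure:

    R = log2(20) - (H + e_n),   H = -sum(p log2 p)

with the small-sample correction e_n = 19 / (2 n ln 2) for a column of n
observed residues (Schneider-Stephens).  Letter heights within a stack are
R times the residue frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractError

PAD = "-"
N_RESIDUES = 20
MAX_BITS = math.log2(N_RESIDUES)

#: Residue colour classes used in exported plot metadata.
COLOR_CLASSES = {
    "polar-amide": set("QN"),
    "polar": set("GSTYC"),
    "basic": set("KRH"),
    "acidic": set("DE"),
    "hydrophobic": set("AVLIPWFM"),
}


@dataclass(frozen=True)
class AnchoredMatrix:
    """Right-justified, gap-free alignment; ``PAD`` marks absent positions."""

    rows: tuple[str, ...]
    width: int

    def column(self, index: int) -> list[str]:
        """Residues of column ``index`` (1-based), padding excluded."""
        return [r[index - 1] for r in self.rows if r[index - 1] != PAD]


@dataclass(frozen=True)
class LogoColumn:
    """Per-column conservation summary (all quantities in bits)."""

    column: int
    n: int
    frequencies: dict[str, float]
    entropy_bits: float
    correction_bits: float
    info_bits: float

    def letter_heights(self) -> dict[str, float]:
        return {res: self.info_bits * p for res, p in self.frequencies.items()}


def anchor_align(kinins: Sequence[str]) -> AnchoredMatrix:
    """Right-align peptides on their final residue (the amide-donor Gly)."""
    if not kinins:
        raise ContractError("no sequences to align")
    if any(not s for s in kinins):
        raise ContractError("empty sequence in alignment input")
    width = max(len(s) for s in kinins)
    rows = tuple(PAD * (width - len(s)) + s.upper() for s in kinins)
    return AnchoredMatrix(rows=rows, width=width)


def information_content(
    matrix: AnchoredMatrix, apply_correction: bool = True
) -> list[LogoColumn]:
    """Information content per column, left edge to anchor.

    All-padding columns report R = 0 with n = 0.  With the correction on,
    R approaches log2(20) - H as n grows.
    """
    columns: list[LogoColumn] = []
    for idx in range(1, matrix.width + 1):
        residues = matrix.column(idx)
        n = len(residues)
        if n == 0:
            columns.append(LogoColumn(idx, 0, {}, 0.0, 0.0, 0.0))
            continue
        freqs: dict[str, float] = {}
        for res in residues:
            freqs[res] = freqs.get(res, 0.0) + 1.0
        freqs = {res: c / n for res, c in sorted(freqs.items())}
        entropy = -sum(p * math.log2(p) for p in freqs.values() if p > 0)
        correction = (N_RESIDUES - 1) / (2 * n * math.log(2)) if apply_correction else 0.0
        info = max(0.0, MAX_BITS - entropy - correction)
        columns.append(LogoColumn(idx, n, freqs, entropy, correction, info))
    return columns


def color_class(residue: str) -> str:
    for name, members in COLOR_CLASSES.items():
        if residue in members:
            return name
    return "other"


def logo_table(columns: Sequence[LogoColumn], top: int = 3) -> pd.DataFrame:
    """Per-column TSV-ready summary (column, n, H, e_n, R, top residues)."""
    rows = []
    for col in columns:
        ranked = sorted(col.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        rows.append(
            {
                "column": col.column,
                "n": col.n,
                "H": round(col.entropy_bits, 4),
                "e_n": round(col.correction_bits, 4),
                "R": round(col.info_bits, 4),
                "top_residues": ",".join(f"{r}:{p:.3f}" for r, p in ranked[:top]),
            }
        )
    return pd.DataFrame(rows, columns=["column", "n", "H", "e_n", "R", "top_residues"])


def write_logo_table(columns: Sequence[LogoColumn], path: str | Path) -> None:
    logo_table(columns).to_csv(path, sep="\t", index=False)


def plot_logo(columns: Sequence[LogoColumn], path: str | Path) -> None:
    """Render a simple stacked-letter conservation logo to ``path``.

    Letters are stacked per column in increasing frequency order, each with
    height R * frequency; colours follow the residue class groups.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {
        "polar-amide": "#8e44ad",
        "polar": "#1e8449",
        "basic": "#1f618d",
        "acidic": "#c0392b",
        "hydrophobic": "#17202a",
        "other": "#7f8c8d",
    }
    fig, ax = plt.subplots(figsize=(max(4.0, 0.45 * len(columns)), 3.0))
    for col in columns:
        base = 0.0
        for res, height in sorted(col.letter_heights().items(), key=lambda kv: kv[1]):
            if height <= 0:
                continue
            ax.text(
                col.column, base + height / 2, res,
                ha="center", va="center",
                fontsize=14, fontweight="bold",
                color=palette[color_class(res)],
            )
            base += height
    ax.set_xlim(0.5, len(columns) + 0.5)
    ax.set_ylim(0, MAX_BITS)
    ax.set_xlabel("alignment position (anchored at the C-terminal Gly)")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
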