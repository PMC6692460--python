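"""Prohormone processing: cleavage prediction, peptide excision, amidation,
kinin-core detection and average-mass calculation.

The model follows the classical picture of neuropeptide maturation.  A
precursor is cut by prohormone convertases at basic-residue sites: always
after the dibasic pairs KR and RR, optionally after KK/RK, and after a lone
Arg when another basic residue sits a few positions upstream (offsets -4, -6
or -8 by default).  A site followed immediately by Pro is suppressed, and a
maximal run of basic residues is treated as a single site cleaved after its
last residue.  Carboxypeptidase activity then removes trailing K/R from each
fragment, and peptidylglycine alpha-amidating monooxygenase converts a
C-terminal Gly into an amide on the preceding residue.  Kinins are recognised
among the products by the amidated C-terminal core Phe-X1-X2-Trp-Gly-NH2.

Masses are average (not monoisotopic): the sum of standard average residue
masses plus one water (18.0153 Da), with -0.9848 Da for the C-terminal amide
(OH -> NH2).  Rounding is to the nearest integer, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, InputError
from .records import PROTEIN_ALPHABET, PrecursorRecord

# Standard average residue (monomer minus water) masses, Daltons.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
AMIDE_SHIFT = -0.9848

BASIC = frozenset("KR")


def average_mass(sequence: str, amidated: bool = False) -> tuple[float, int]:
    """Average peptide mass in Daltons and its nearest-integer form.

    ``amidated`` applies the C-terminal amide correction of -0.9848 Da.
    Rounding is half away from zero.
    """
    if not sequence:
        raise InputError("empty peptide sequence")
    total = WATER_MASS
    for pos, ch in enumerate(sequence.upper(), start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[ch]
        except KeyError:
            raise InputError(f"unknown residue {ch!r} at position {pos}") from None
    if amidated:
        total += AMIDE_SHIFT
    return total, int(math.floor(total + 0.5))


@dataclass(frozen=True)
class CleavageRuleSet:
    """Configurable basic-residue cleavage rules.

    ``monobasic_upstream_offsets`` are positions relative to a lone Arg at
    which a K/R licenses cleavage (offset -4 means four residues upstream).
    """

    dibasic_pairs: frozenset[str] = frozenset({"KR", "RR"})
    optional_pairs: frozenset[str] = frozenset({"KK", "RK"})
    optional_pairs_enabled: bool = False
    monobasic_r_enabled: bool = True
    monobasic_upstream_offsets: frozenset[int] = frozenset({-4, -6, -8})
    block_if_next_is_proline: bool = True
    amidation_enabled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "dibasic_pairs", frozenset(self.dibasic_pairs))
        object.__setattr__(self, "optional_pairs", frozenset(self.optional_pairs))
        object.__setattr__(
            self, "monobasic_upstream_offsets", frozenset(self.monobasic_upstream_offsets)
        )
        for pair in self.dibasic_pairs | self.optional_pairs:
            if len(pair) != 2 or not set(pair) <= BASIC:
                raise ContractError(f"invalid basic pair {pair!r}")
        if any(off >= 0 for off in self.monobasic_upstream_offsets):
            raise ContractError("monobasic offsets must be negative")

    @property
    def active_pairs(self) -> frozenset[str]:
        if self.optional_pairs_enabled:
            return self.dibasic_pairs | self.optional_pairs
        return self.dibasic_pairs


@dataclass(frozen=True)
class CleavageSite:
    """Cleavage occurs after ``position`` (1-based, the last residue of the
    basic run); ``motif`` is the full run matched."""

    position: int
    kind: str  # "dibasic" | "monobasic"
    motif: str


@dataclass(frozen=True)
class KininCore:
    """The two variable positions of the F-X1-X2-W-G amide core."""

    x1: str
    x2: str


@dataclass(frozen=True)
class MaturePeptide:
    """An excised, trimmed, possibly amidated product peptide.

    ``source_span`` is the 1-based inclusive interval of the *untrimmed*
    fragment on the precursor.
    """

    sequence: str
    amidated: bool
    source_span: tuple[int, int]
    core: KininCore | None
    mass_da: float
    mass_rounded: int
    name: str = ""


def predict_cleavage_sites(
    precursor: PrecursorRecord, rules: CleavageRuleSet | None = None
) -> list[CleavageSite]:
    """Predict convertase cleavage sites on a precursor.

    Maximal runs of K/R are single candidates, cleaved after the last
    residue of the run.  Sites inside the signal peptide (positions <=
    ``signal_end``) and sites followed immediately by Pro are suppressed.
    """
    rules = rules or CleavageRuleSet()
    seq = precursor.sequence
    if not set(seq) <= PROTEIN_ALPHABET:
        bad = next(ch for ch in seq if ch not in PROTEIN_ALPHABET)
        raise InputError(f"non-standard residue {bad!r} in precursor {precursor.id!r}")
    signal_end = precursor.signal_end or 0
    sites: list[CleavageSite] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] not in BASIC:
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] in BASIC:
            j += 1
        # candidate: cleave after position j (0-based)
        run = seq[i : j + 1]
        pos1 = j + 1  # 1-based position of the last run residue
        blocked = (
            rules.block_if_next_is_proline and j + 1 < n and seq[j + 1] == "P"
        ) or pos1 <= signal_end
        if not blocked:
            if len(run) >= 2 and run[-2:] in rules.active_pairs:
                sites.append(CleavageSite(pos1, "dibasic", run))
            elif len(run) == 1 and run == "R" and rules.monobasic_r_enabled:
                for off in rules.monobasic_upstream_offsets:
                    k = j + off  # 0-based index of the upstream residue
                    if k >= 0 and seq[k] in BASIC:
                        sites.append(CleavageSite(pos1, "monobasic", run))
                        break
        i = j + 1
    sites.sort(key=lambda s: s.position)
    return sites


def _trim_and_amidate(fragment: str, rules: CleavageRuleSet) -> tuple[str, bool]:
    trimmed = fragment.rstrip("KR")
    if rules.amidation_enabled and trimmed.endswith("G"):
        return trimmed[:-1], True
    return trimmed, False


def find_kinin_core(sequence: str, amidated: bool) -> KininCore | None:
    """Return the F-X1-X2-W-G core when the amidated peptide carries it."""
    if not amidated or len(sequence) < 5:
        return None
    penta = sequence[-5:]
    if penta[0] == "F" and penta[3] == "W" and penta[4] == "G":
        return KininCore(x1=penta[1], x2=penta[2])
    return None


def excise_peptides(
    precursor: PrecursorRecord,
    sites: Sequence[CleavageSite],
    rules: CleavageRuleSet | None = None,
) -> list[MaturePeptide]:
    """Excise the fragments between cleavage points and mature them.

    Each fragment is trimmed of trailing K/R; a remaining C-terminal Gly is
    removed as the amide donor when amidation is enabled.  Fragments that
    trim to nothing are discarded.  The untrimmed fragments partition the
    precursor exactly.
    """
    rules = rules or CleavageRuleSet()
    n = len(precursor)
    positions = [s.position for s in sites]
    if positions != sorted(set(positions)) or any(not 1 <= p <= n for p in positions):
        raise ContractError("cleavage sites must be sorted, unique and within the sequence")
    bounds = [0] + positions + ([n] if (not positions or positions[-1] != n) else [])
    peptides: list[MaturePeptide] = []
    for idx in range(len(bounds) - 1):
        lo, hi = bounds[idx], bounds[idx + 1]
        fragment = precursor.sequence[lo:hi]
        trimmed, amidated = _trim_and_amidate(fragment, rules)
        if not trimmed:
            continue
        core = find_kinin_core(trimmed, amidated)
        mass_da, mass_rounded = average_mass(trimmed, amidated)
        peptides.append(
            MaturePeptide(
                sequence=trimmed,
                amidated=amidated,
                source_span=(lo + 1, hi),
                core=core,
                mass_da=mass_da,
                mass_rounded=mass_rounded,
                name=f"{precursor.id}_p{len(peptides) + 1}",
            )
        )
    return peptides


def mine_precursor(
    precursor: PrecursorRecord, rules: CleavageRuleSet | None = None
) -> list[MaturePeptide]:
    """Full mining pass: predict sites, excise and mature all peptides."""
    rules = rules or CleavageRuleSet()
    return excise_peptides(precursor, predict_cleavage_sites(precursor, rules), rules)


def core_position_summary(
    peptides: Iterable[MaturePeptide],
) -> tuple[pd.DataFrame, list[MaturePeptide]]:
    """Residue frequency tables at the core's X1 and X2 positions.

    Returns a tidy frame (position, residue, count) over core-bearing
    peptides, plus the list of peptides without a core (excluded).
    """
    rows = []
    excluded = []
    for pep in peptides:
        if pep.core is None:
            excluded.append(pep)
        else:
            rows.append(("X1", pep.core.x1))
            rows.append(("X2", pep.core.x2))
    if not rows:
        table = pd.DataFrame(columns=["position", "residue", "count"])
    else:
        table = (
            pd.DataFrame(rows, columns=["position", "residue"])
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["position", "count", "residue"], ascending=[True, False, True])
            .reset_index(drop=True)
        )
    return table, excluded


def peptide_table(peptides: Iterable[MaturePeptide]) -> pd.DataFrame:
    """Peptide report table, one row per mature peptide."""
    rows = []
    for pep in peptides:
        rows.append(
            {
                "name": pep.name,
                "sequence": pep.sequence,
                "amidated": int(pep.amidated),
                "core": int(pep.core is not None),
                "X1": pep.core.x1 if pep.core else "",
                "X2": pep.core.x2 if pep.core else "",
                "span_start": pep.source_span[0],
                "span_end": pep.source_span[1],
                "mass_da": round(pep.mass_da, 2),
                "mass_rounded": pep.mass_rounded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "sequence", "amidated", "core", "X1", "X2",
            "span_start", "span_end", "mass_da", "mass_rounded",
        ],
    )


def write_peptide_table(peptides: Iterable[MaturePeptide], path: str | Path) -> None:
    peptide_table(peptides).to_csv(path, sep="\t", index=False)
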