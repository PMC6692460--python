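"""Seeded generators with ground truth for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes — a multi-paracopy kinin precursor with basic cleavage sites, a
two-exon gene with a planted GT..AG intron, endpoint fluorescence plates
whose dose dependence follows a four-parameter logistic, and 65-s kinetic
bioluminescence traces — and returns the exact truth the pipeline should
recover.  All randomness flows through ``numpy.random.default_rng(seed)``,
so regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import RANGE1, RANGE2, TRACE_LEN, DilutionSeries, four_pl
from .errors import ContractError
from .prohormone import CleavageRuleSet, KininCore, MaturePeptide, average_mass
from .records import NucleotideRecord, PrecursorRecord

# Residue pools used when composing synthetic precursors.  None can form a
# basic cleavage site or start with Pro after a site, so the planted sites
# are the only ones the mining stage should find.
SPACER_POOL = "DEQNSTA"
PREFIX_POOL = "DEQNSTAG"
X1_POOL = "NGSAT"
X2_POOL = "PSA"
#: X2 is Pro-dominated in tick kinins; 15/17 mirrors the cloned precursor.
X2_PROLINE_WEIGHT = 15 / 17


def generate_precursor(
    n_kinins: int,
    seed: int,
    rules: CleavageRuleSet | None = None,
    include_signal: bool = False,
    include_tail: bool = True,
) -> tuple[PrecursorRecord, list[MaturePeptide]]:
    """A precursor of ``n_kinins`` paracopies plus its expected products.

    Each paracopy block is spacer + body ending F-X1-X2-W-G, followed by the
    amide-donor Gly and a dibasic pair drawn from the rule set.  The returned
    truth lists the mature peptides (sequence, span, amidation, core) the
    prohormone pipeline must reproduce exactly.
    """
    if n_kinins < 1:
        raise ContractError("n_kinins must be >= 1")
    rules = rules or CleavageRuleSet()
    rng = np.random.default_rng([1, seed])
    pairs = sorted(rules.dibasic_pairs)
    parts: list[str] = []
    truth: list[MaturePeptide] = []
    cursor = 0
    signal_end = None

    if include_signal:
        stub = "M" + "".join(rng.choice(list("LAVITS"), size=17)) + "A"
        signal_end = len(stub)
    else:
        stub = ""

    for i in range(n_kinins):
        spacer = "".join(rng.choice(list(SPACER_POOL), size=rng.integers(2, 9)))
        prefix = "".join(rng.choice(list(PREFIX_POOL), size=rng.integers(0, 6)))
        x1 = str(rng.choice(list(X1_POOL)))
        x2 = "P" if rng.random() < X2_PROLINE_WEIGHT else str(rng.choice(list("SA")))
        mature = (stub if i == 0 else "") + spacer + prefix + "F" + x1 + x2 + "WG"
        pair = pairs[int(rng.integers(0, len(pairs)))]
        fragment = mature + "G" + pair
        span = (cursor + 1, cursor + len(fragment))
        mass_da, mass_rounded = average_mass(mature, amidated=True)
        truth.append(
            MaturePeptide(
                sequence=mature, amidated=True, source_span=span,
                core=KininCore(x1=x1, x2=x2), mass_da=mass_da,
                mass_rounded=mass_rounded, name=f"synthetic_precursor_p{i + 1}",
            )
        )
        parts.append(fragment)
        cursor += len(fragment)

    if include_tail:
        tail = "".join(rng.choice(list("DEA"), size=rng.integers(2, 7)))
        span = (cursor + 1, cursor + len(tail))
        mass_da, mass_rounded = average_mass(tail, amidated=False)
        truth.append(
            MaturePeptide(
                sequence=tail, amidated=False, source_span=span, core=None,
                mass_da=mass_da, mass_rounded=mass_rounded,
                name=f"synthetic_precursor_p{n_kinins + 1}",
            )
        )
        parts.append(tail)

    record = PrecursorRecord(
        id="synthetic_precursor", sequence="".join(parts), signal_end=signal_end,
        description=f"synthetic kinin precursor, {n_kinins} paracopies, seed {seed}",
    )
    return record, truth


def generate_random_cdna(length: int, seed: int) -> NucleotideRecord:
    """Uniform-random cDNA of ``length`` nt."""
    rng = np.random.default_rng([2, seed])
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return NucleotideRecord("synthetic_cdna", seq, f"random cDNA, seed {seed}")


@dataclass(frozen=True)
class GeneTruth:
    """Planted coordinates (genomic, 1-based inclusive) of the two-exon gene."""

    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    donor: str
    acceptor: str
    n_mutations: int


def _forbid_dinucleotide(chars: list[str], dinuc: str, lo: int, hi: int) -> None:
    """Rewrite ``chars[lo:hi]`` in place so ``dinuc`` never occurs there."""
    for i in range(max(0, lo), min(len(chars) - 1, hi)):
        if chars[i] == dinuc[0] and chars[i + 1] == dinuc[1]:
            chars[i + 1] = "C"


def generate_gene(
    cdna: NucleotideRecord,
    intron_length: int,
    insert_after: int,
    seed: int,
    mutation_rate: float = 0.0,
    guard: int = 20,
) -> tuple[NucleotideRecord, GeneTruth]:
    """Plant one GT..AG intron into ``cdna`` after position ``insert_after``.

    The intron interior is scrubbed of GT near its start and AG near its end
    (``guard`` bases) so the planted junction is the unique canonical
    interpretation within the boundary-refinement window.  Point mutations
    are applied at ``mutation_rate`` everywhere except the two splice
    dinucleotides.
    """
    if not 0 < insert_after < len(cdna):
        raise ContractError("insert_after must fall strictly inside the cDNA")
    if intron_length < 6:
        raise ContractError("intron_length must be >= 6")
    rng = np.random.default_rng([3, seed])
    interior = list(rng.choice(list("ACGT"), size=intron_length - 4))
    _forbid_dinucleotide(interior, "GT", 0, guard)
    _forbid_dinucleotide(interior, "AG", len(interior) - guard - 1, len(interior))
    genomic = list(
        cdna.sequence[:insert_after] + "GT" + "".join(interior) + "AG"
        + cdna.sequence[insert_after:]
    )

    donor_pos = {insert_after, insert_after + 1}  # 0-based GT
    acceptor_pos = {insert_after + intron_length - 2, insert_after + intron_length - 1}
    n_mut = 0
    if mutation_rate > 0:
        protected = donor_pos | acceptor_pos
        hits = np.nonzero(rng.random(len(genomic)) < mutation_rate)[0]
        for pos in hits:
            if int(pos) in protected:
                continue
            alternatives = [b for b in "ACGT" if b != genomic[pos]]
            genomic[pos] = str(rng.choice(alternatives))
            n_mut += 1

    record = NucleotideRecord(
        "synthetic_gene",
        "".join(genomic),
        f"cdna {cdna.id} with {intron_length} nt intron after {insert_after}, seed {seed}",
    )
    truth = GeneTruth(
        exon1=(1, insert_after),
        intron=(insert_after + 1, insert_after + intron_length),
        exon2=(insert_after + intron_length + 1, len(record)),
        donor="GT",
        acceptor="AG",
        n_mutations=n_mut,
    )
    return record, truth


@dataclass(frozen=True)
class EndpointPlateTruth:
    """Generating parameters and noiseless per-well values of one plate."""

    params: dict[str, tuple[float, float, float, float]]  # bottom, top, log_ic50, hill
    percents: dict[str, tuple[float, ...]]  # noiseless percent per dose, descending conc
    noiseless: np.ndarray
    pc_level: float


@dataclass(frozen=True)
class EndpointPlate:
    forward: np.ndarray
    reverse: np.ndarray  # as physically read after 180-degree rotation
    plate_map: pd.DataFrame  # well, row, col, role, compound, concentration_molar
    truth: EndpointPlateTruth


def generate_endpoint_plate(
    compound_params: Mapping[str, tuple[float, float, float, float]],
    dilution: DilutionSeries,
    noise_cv: float,
    seed: int,
    nrow: int = 16,
    ncol: int = 24,
    pc_level: float = 1000.0,
) -> EndpointPlate:
    """A dual-read endpoint plate: one compound per row, doses across
    columns, positive-control wells in the two edge column pairs.

    Noiseless compound wells are ``pc_level * 4PL(c)/100``; multiplicative
    Gaussian noise of coefficient ``noise_cv`` is drawn independently for
    the forward and reverse reads.
    """
    if noise_cv < 0:
        raise ContractError("noise_cv must be >= 0")
    n_doses = dilution.n
    if n_doses > ncol - 4:
        raise ContractError(f"{n_doses} doses do not fit in {ncol - 4} assay columns")
    if not compound_params:
        raise ContractError("need at least one compound")
    if len(compound_params) > nrow:
        raise ContractError("more compounds than plate rows")
    rng = np.random.default_rng([4, seed])
    noiseless = np.zeros((nrow, ncol))
    rows = []
    percents: dict[str, tuple[float, ...]] = {}
    import string as _string

    for r in range(nrow):
        for c in (0, 1, ncol - 2, ncol - 1):
            noiseless[r, c] = pc_level
    compounds = list(compound_params)
    for r in range(nrow):
        compound = compounds[r % len(compounds)] if compounds else ""
        params = compound_params[compound]
        pct = four_pl(np.asarray(dilution.concentrations), *params)
        if r < len(compounds):
            percents[compound] = tuple(float(p) for p in pct)
        for j, conc in enumerate(dilution.concentrations):
            noiseless[r, 2 + j] = pc_level * pct[j] / 100.0
        for c in range(ncol):
            if c in (0, 1, ncol - 2, ncol - 1):
                role, cid, conc = "positive-control", "", np.nan
            elif c - 2 < n_doses:
                role, cid, conc = "compound", compound, dilution.concentrations[c - 2]
            else:
                role, cid, conc = "blank", "", np.nan
                noiseless[r, c] = 0.0
            rows.append(
                {
                    "well": f"{_string.ascii_uppercase[r]}{c + 1}",
                    "row": r + 1, "col": c + 1, "role": role,
                    "compound": cid, "concentration_molar": conc,
                }
            )

    def noisy() -> np.ndarray:
        if noise_cv == 0:
            return noiseless.copy()
        return noiseless * (1.0 + noise_cv * rng.standard_normal(noiseless.shape))

    forward = noisy()
    reverse = np.rot90(noisy(), 2).copy()
    truth = EndpointPlateTruth(
        params=dict(compound_params), percents=percents,
        noiseless=noiseless, pc_level=pc_level,
    )
    return EndpointPlate(
        forward=forward, reverse=reverse, plate_map=pd.DataFrame(rows), truth=truth
    )


@dataclass(frozen=True)
class KineticTruth:
    """Noiseless window means per well and the PC second-window mean."""

    range_means: dict[str, tuple[float, float]]
    pc_range2_mean: float
    params: dict[str, tuple[float, float, float, float]]


def _transient(amplitude: float, baseline: float, t0: float = 32.0, tau: float = 5.0) -> np.ndarray:
    t = np.arange(TRACE_LEN, dtype=float)
    sig = np.full(TRACE_LEN, baseline)
    after = t >= t0
    dt = t[after] - t0
    sig[after] += amplitude * dt * np.exp(-dt / tau)
    return sig


def generate_kinetic_traces(
    compound_params: Mapping[str, tuple[float, float, float, float]],
    concentrations: Sequence[float],
    seed: int,
    noise_sd: float = 1.0,
    baseline: float = 5.0,
    pc_amplitude: float = 60.0,
    tau: float = 5.0,
) -> tuple[pd.DataFrame, KineticTruth]:
    """Kinetic traces for each compound x concentration, plus one PC well.

    The agonist response is the transient A (t - t0) exp(-(t - t0)/tau)
    starting at the second addition (t0 = 32 s); A is scaled by the 4PL
    inhibition truth.  Additive Gaussian noise per 1-s sample.
    """
    rng = np.random.default_rng([5, seed])
    rows = []
    range_means: dict[str, tuple[float, float]] = {}

    def emit(well: str, role: str, compound: str, conc: float, amplitude: float) -> None:
        clean = _transient(amplitude, baseline, tau=tau)
        trace = clean + (noise_sd * rng.standard_normal(TRACE_LEN) if noise_sd > 0 else 0.0)
        range_means[well] = (
            float(np.mean(clean[RANGE1[0] : RANGE1[1]])),
            float(np.mean(clean[RANGE2[0] : RANGE2[1]])),
        )
        for t, bu in enumerate(trace):
            rows.append(
                {
                    "well": well, "role": role, "compound": compound,
                    "concentration_molar": conc, "time_s": t, "bu": float(bu),
                }
            )

    emit("PC1", "positive-control", "", np.nan, pc_amplitude)
    w = 0
    for compound, params in compound_params.items():
        for conc in concentrations:
            w += 1
            pct = float(four_pl(conc, *params))
            emit(f"W{w}", "compound", compound, float(conc), pc_amplitude * pct / 100.0)

    truth = KineticTruth(
        range_means=range_means,
        pc_range2_mean=range_means["PC1"][1],
        params=dict(compound_params),
    )
    return pd.DataFrame(rows), truth


def endpoint_long_table(plate: EndpointPlate) -> pd.DataFrame:
    """Flatten a generated plate into the endpoint CSV schema
    (well, role, compound, concentration_molar, orientation, rfu), with the
    reverse read already mapped back to its forward well."""
    derotated = plate.reverse[::-1, ::-1]
    rows = []
    for rec in plate.plate_map.itertuples():
        r, c = rec.row - 1, rec.col - 1
        for orientation, arr in (("fwd", plate.forward), ("rev", derotated)):
            rows.append(
                {
                    "well": rec.well, "role": rec.role, "compound": rec.compound,
                    "concentration_molar": rec.concentration_molar,
                    "orientation": orientation, "rfu": float(arr[r, c]),
                }
            )
    return pd.DataFrame(rows)
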