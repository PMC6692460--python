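"""Seeded self-validation studies used by the acceptance machinery.

Each study regenerates synthetic inputs, runs the corresponding pipeline
stage, and summarises how well the generating truth is recovered.  They are
ordinary library functions — the same code a user would run to requalify
the pipeline after a change.
"""

from __future__ import annotations

import numpy as np

from . import assay
from .genestructure import spliced_align
from .synthetic import (
    generate_endpoint_plate,
    generate_gene,
    generate_random_cdna,
)

#: Monte-Carlo study conditions: the confirmatory dose-response design
#: (10 doses, 1:1.4 from 100 uM) with a full antagonist whose IC50 sits
#: mid-series (~22 uM), read at 5% multiplicative noise per orientation.
MC_TRUTH = (5.0, 100.0, -4.65, -1.0)
MC_DILUTION = dict(start=1e-4, ratio=1.4, n=10)
MC_NOISE_CV = 0.05


def _plate_dose_curve(plate) -> tuple[np.ndarray, np.ndarray]:
    """Percent-of-control dose curve from a generated plate, via the full
    dual-read / PC-normalisation path."""
    df = assay.merge_dual_reads(plate.forward, plate.reverse).merge(
        plate.plate_map, on=["well", "row", "col"]
    )
    pc = df[df.role == "positive-control"].rfu_mean.mean()
    curve = (
        df[df.role == "compound"]
        .groupby("concentration_molar")
        .rfu_mean.mean()
        .sort_index(ascending=False)
        / pc
        * 100.0
    )
    return curve.index.to_numpy(), curve.to_numpy()


def fourpl_noiseless_recovery(seed: int = 0) -> float:
    """Max relative parameter error of a 4PL fit on one noiseless plate."""
    d = assay.dilution_series(**MC_DILUTION)
    plate = generate_endpoint_plate({"cmp": MC_TRUTH}, d, noise_cv=0.0, seed=seed)
    c, y = _plate_dose_curve(plate)
    fit = assay.fit_4pl(c, y)
    est = np.array([fit.bottom, fit.top, fit.log_ic50, fit.hill])
    return float(np.max(np.abs(est - np.array(MC_TRUTH)) / np.abs(np.array(MC_TRUTH))))


def fourpl_monte_carlo(n_plates: int = 500, seed: int = 0) -> dict:
    """Recovery and CI calibration of the 4PL fit over seeded noisy plates.

    Returns the median absolute log10-IC50 error, the fraction of fits whose
    95% CI covers the generating IC50, and the convergence count.
    """
    d = assay.dilution_series(**MC_DILUTION)
    errors, covered, converged = [], 0, 0
    base = (seed % 2**20) * 1000
    for i in range(n_plates):
        plate = generate_endpoint_plate(
            {"cmp": MC_TRUTH}, d, noise_cv=MC_NOISE_CV, seed=base + i
        )
        c, y = _plate_dose_curve(plate)
        fit = assay.fit_4pl(c, y)
        if not fit.converged:
            continue
        converged += 1
        errors.append(abs(fit.log_ic50 - MC_TRUTH[2]))
        covered += fit.ci95_low <= 10 ** MC_TRUTH[2] <= fit.ci95_high
    return {
        "n_plates": n_plates,
        "n_converged": converged,
        "median_abs_log10_ic50_error": float(np.median(errors)),
        "ci95_coverage_pct": 100.0 * covered / converged,
    }


def classification_study(n_cases: int = 200, seed: int = 0) -> dict:
    """Noiseless antagonist calls against generator truth.

    Truth parameters span inactive, partial and full antagonists; the truth
    call is derived from the generator's own noiseless percent curve, and
    the pipeline call from the analysed plate.
    """
    rng = np.random.default_rng([7, seed])
    d = assay.dilution_series(**MC_DILUTION)
    agree = 0
    base = (seed % 2**20) * 1000
    for i in range(n_cases):
        kind = i % 3
        if kind == 0:  # inactive
            params = (100.0, 100.0, float(rng.uniform(-5, -3)), -1.0)
        elif kind == 1:  # partial
            params = (float(rng.uniform(25, 45)), 100.0, float(rng.uniform(-5.2, -4.6)), -1.0)
        else:  # full
            params = (float(rng.uniform(0, 10)), 100.0, float(rng.uniform(-5.6, -5.0)), -1.0)
        plate = generate_endpoint_plate({"cmp": params}, d, noise_cv=0.0, seed=base + i)
        truth_call = assay.classify_antagonist(plate.truth.percents["cmp"])
        _, y = _plate_dose_curve(plate)
        agree += assay.classify_antagonist(y) == truth_call
    return {"n_cases": n_cases, "agreement_pct": 100.0 * agree / n_cases}


def splice_recovery_study(
    n_genes: int = 100, seed: int = 0, mutation_rate: float = 0.0
) -> dict:
    """Exon-coordinate recovery on seeded two-exon genes.

    Exon lengths 50-2,000 bp, intron 100-3,000 bp; reports the fraction of
    genes with exact boundary recovery and the minimum cDNA coverage.
    """
    exact = 0
    coverages = []
    base = (seed % 2**20) * 1000
    for i in range(n_genes):
        rng = np.random.default_rng([8, base + i])
        e1 = int(rng.integers(50, 2001))
        e2 = int(rng.integers(50, 2001))
        il = int(rng.integers(100, 3001))
        cdna = generate_random_cdna(e1 + e2, base + i)
        genomic, truth = generate_gene(
            cdna, il, e1, seed=base + i, mutation_rate=mutation_rate
        )
        model = spliced_align(cdna, genomic)
        exact += model.exons == (truth.exon1, truth.exon2)
        coverages.append(model.cdna_coverage)
    return {
        "n_genes": n_genes,
        "exact_pct": 100.0 * exact / n_genes,
        "min_coverage_pct": 100.0 * float(np.min(coverages)),
    }
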