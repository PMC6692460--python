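"""Dual-addition calcium-assay analytics.

Covers the two read-outs of a GPCR antagonist screen on a recombinant
receptor cell line:

* endpoint fluorescence in 384-well plates, read in forward and reverse
  orientations and averaged, expressed as percent of the positive control
  (blank solvent + agonist), with antagonists called from the dose-percent
  curve and quantified by a four-parameter logistic (4PL) fit;
* kinetic bioluminescence traces (65 samples at 1 s), summarised as the mean
  signal over the two 30 s windows that follow the compound and agonist
  additions, normalised to the positive control's second-window mean.

The 4PL model is the GraphPad "log(inhibitor) vs. response - variable slope"
parameterisation::

    y = bottom + (top - bottom) / (1 + 10**((log_ic50 - log10(c)) * hill))

and the reported IC50 is the fitted curve midpoint, not the dose producing
50% of control.  Replicate statistics operate on independent-assay means
(pseudo-replicate wells are averaged first): one-way ANOVA followed by Tukey
HSD with a compact letter display.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError, ContractError, InputError

# Kinetic windows (seconds, half-open): compound addition at 2 s, agonist at
# 32 s, each response quantified over 30 samples.
RANGE1 = (2, 32)
RANGE2 = (35, 65)
TRACE_LEN = 65


@dataclass(frozen=True)
class DilutionSeries:
    """A geometric dilution series, concentrations descending (molar)."""

    start: float
    ratio: float
    n: int
    concentrations: tuple[float, ...]


def dilution_series(start: float, ratio: float, n: int) -> DilutionSeries:
    """Serial dilution: concentrations[i] = start / ratio**i."""
    if start <= 0 or ratio <= 1 or n < 1:
        raise ContractError("need start > 0, ratio > 1, n >= 1")
    concs = tuple(start / ratio**i for i in range(n))
    return DilutionSeries(start=start, ratio=ratio, n=n, concentrations=concs)


def merge_dual_reads(forward: np.ndarray, reverse: np.ndarray) -> pd.DataFrame:
    """Merge forward and 180-degree-rotated reverse plate reads.

    The reverse read at well (r, c) reports forward well (R+1-r, C+1-c).
    Returns one row per well with both reads and their mean.
    """
    forward = np.asarray(forward, dtype=float)
    reverse = np.asarray(reverse, dtype=float)
    if forward.shape != reverse.shape or forward.ndim != 2:
        raise InputError(
            f"plate shapes differ or are not 2-D: {forward.shape} vs {reverse.shape}"
        )
    nrow, ncol = forward.shape
    derotated = reverse[::-1, ::-1]
    rows = []
    for r in range(nrow):
        for c in range(ncol):
            rows.append(
                {
                    "well": f"{_row_letter(r)}{c + 1}",
                    "row": r + 1,
                    "col": c + 1,
                    "rfu_forward": forward[r, c],
                    "rfu_reverse": derotated[r, c],
                    "rfu_mean": (forward[r, c] + derotated[r, c]) / 2,
                }
            )
    return pd.DataFrame(rows)


def _row_letter(index0: int) -> str:
    letters = string.ascii_uppercase
    if index0 < 26:
        return letters[index0]
    return letters[index0 // 26 - 1] + letters[index0 % 26]


def endpoint_percent_response(rfu_mean, pc_mean: float):
    """Well response as percent of the positive-control mean."""
    if pc_mean <= 0:
        raise ContractError("positive-control mean must be > 0")
    return 100.0 * np.asarray(rfu_mean, dtype=float) / pc_mean


def classify_antagonist(
    percents: Sequence[float], threshold: float = 50.0, full_cutoff: float = 20.0
) -> str:
    """Call a compound from its dose -> percent-of-control curve.

    Antagonist iff any dose drops to ``threshold`` percent or below; "full"
    when the minimum additionally reaches ``full_cutoff`` or below.
    """
    values = np.asarray(list(percents), dtype=float)
    if values.size < 3:
        raise ContractError("need at least 3 dosages to classify")
    low = float(np.min(values))
    if low > threshold:
        return "none"
    return "full" if low <= full_cutoff else "partial"


@dataclass(frozen=True)
class FourPLFit:
    """Fitted four-parameter logistic with asymptotic IC50 confidence band."""

    bottom: float
    top: float
    log_ic50: float
    hill: float
    ic50: float
    ci95_low: float
    ci95_high: float
    converged: bool
    message: str = ""

    def predict(self, concentrations) -> np.ndarray:
        return four_pl(np.asarray(concentrations, dtype=float),
                       self.bottom, self.top, self.log_ic50, self.hill)


def four_pl(c, bottom: float, top: float, log_ic50: float, hill: float):
    """The variable-slope logistic in concentration space."""
    logc = np.log10(np.asarray(c, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))


def fit_4pl(concentrations, responses) -> FourPLFit:
    """Least-squares 4PL fit with a t-based 95% CI on log10 IC50.

    Degenerate (flat) data return ``converged=False`` with a diagnostic
    message instead of raising.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ContractError("concentrations and responses differ in length")
    if np.unique(c).size < 4:
        raise ContractError("need at least 4 distinct concentrations")
    if np.any(c <= 0):
        raise InputError("concentrations must be positive")

    spread = float(np.max(y) - np.min(y))
    if spread < 1e-9 * max(1.0, abs(float(np.mean(y)))):
        return FourPLFit(
            bottom=float(np.mean(y)), top=float(np.mean(y)), log_ic50=math.nan,
            hill=math.nan, ic50=math.nan, ci95_low=math.nan, ci95_high=math.nan,
            converged=False, message="flat response: midpoint is unidentifiable",
        )

    logc = np.log10(c)
    half = (np.max(y) + np.min(y)) / 2.0
    log_mid = float(logc[np.argmin(np.abs(y - half))])
    # slope sign from the observed trend: inhibition curves decrease with dose
    trend = np.polyfit(logc, y, 1)[0]
    hill0 = 1.0 if trend >= 0 else -1.0
    p0 = [float(np.min(y)), float(np.max(y)), log_mid, hill0]
    try:
        popt, pcov = optimize.curve_fit(four_pl, c, y, p0=p0, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return FourPLFit(
            bottom=math.nan, top=math.nan, log_ic50=math.nan, hill=math.nan,
            ic50=math.nan, ci95_low=math.nan, ci95_high=math.nan,
            converged=False, message=f"fit failed: {exc}",
        )
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    var = pcov[2, 2]
    dof = max(1, y.size - 4)
    converged = bool(np.isfinite(pcov).all() and var >= 0)
    if converged and var > 0:
        t_crit = float(stats.t.ppf(0.975, dof))
        se = math.sqrt(var)
        with np.errstate(over="ignore"):
            ci_low = float(np.power(10.0, log_ic50 - t_crit * se))
            ci_high = float(np.power(10.0, log_ic50 + t_crit * se))
    else:
        ci_low = ci_high = math.nan
    return FourPLFit(
        bottom=bottom, top=top, log_ic50=log_ic50, hill=hill, ic50=10**log_ic50,
        ci95_low=ci_low, ci95_high=ci_high, converged=converged,
        message="" if converged else "covariance not estimable",
    )


@dataclass(frozen=True)
class KineticWell:
    """One 65-s bioluminescence trace sampled at 1-s intervals."""

    well: str
    trace: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.trace) != TRACE_LEN:
            raise ContractError(f"trace must have {TRACE_LEN} samples, got {len(self.trace)}")


def kinetic_range_totals(
    trace: Sequence[float],
    range1: tuple[int, int] = RANGE1,
    range2: tuple[int, int] = RANGE2,
) -> tuple[float, float]:
    """Mean signal per second over the two half-open response windows."""
    arr = np.asarray(trace, dtype=float)
    if arr.size < max(range1[1], range2[1]):
        raise ContractError(
            f"trace of {arr.size} samples does not cover the windows {range1}, {range2}"
        )
    r1 = float(np.mean(arr[range1[0] : range1[1]]))
    r2 = float(np.mean(arr[range2[0] : range2[1]]))
    return r1, r2


def normalize_to_pc(
    range_totals: tuple[float, float], pc_range2_mean: float
) -> tuple[float, float]:
    """Both window means as percent of the positive control's second-window
    mean; the PC's own second window normalises to 100%."""
    if pc_range2_mean <= 0:
        raise ContractError("positive-control range-2 mean must be > 0")
    return (
        100.0 * range_totals[0] / pc_range2_mean,
        100.0 * range_totals[1] / pc_range2_mean,
    )


@dataclass(frozen=True)
class ReplicateStats:
    """One-way ANOVA over assay means plus Tukey HSD letters."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # compact letter display, groups sharing a letter do not differ


def replicate_stats(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ReplicateStats:
    """ANOVA + Tukey on independent-assay means grouped by condition.

    Each value must already be the mean over that assay's pseudo-replicate
    wells; every group needs at least two assays.
    """
    if len(groups) < 2:
        raise AnalysisError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise AnalysisError(f"group {name!r} has fewer than 2 assays")
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    f_stat, p_val = stats.f_oneway(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(samples)
    tags = np.concatenate([[g] * len(s) for g, s in zip(labels, samples)])
    if np.ptp(values) == 0:  # all observations identical: nothing differs
        tukey_df = pd.DataFrame(
            [
                {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0, "reject": False}
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        )
    else:
        res = pairwise_tukeyhsd(values, tags, alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:],
            columns=[c.strip() for c in res.summary().data[0]],
        )[["group1", "group2", "meandiff", "p-adj", "reject"]].rename(
            columns={"p-adj": "p_adj"}
        )
    letters = compact_letters(
        labels,
        {(r.group1, r.group2) for r in tukey_df.itertuples() if bool(r.reject)},
        means={g: float(np.mean(s)) for g, s in zip(labels, samples)},
    )
    return ReplicateStats(
        anova_f=float(f_stat), anova_p=float(p_val), tukey=tukey_df, letters=letters
    )


def compact_letters(
    groups: Sequence[str],
    significant_pairs: set[tuple[str, str]],
    means: Mapping[str, float] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing any letter are not significantly different.  Letters are
    assigned to letter-sets ordered by descending group mean when means are
    given (the usual presentation), else by input order.
    """
    sig = {frozenset(p) for p in significant_pairs}
    sets: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for current in list(sets):
            if a in current and b in current:
                sets.remove(current)
                sets.extend([current - {a}, current - {b}])
    # absorb subsets
    sets = [s for s in sets if s]
    sets = [s for s in sets if not any(s < t for t in sets)]
    # deduplicate, stable order by best (highest-mean) member
    uniq: list[set[str]] = []
    for s in sets:
        if s not in uniq:
            uniq.append(s)
    if means is not None:
        uniq.sort(key=lambda s: -max(means[g] for g in s))
    out = {g: "" for g in groups}
    for letter, s in zip(string.ascii_lowercase, uniq):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}
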