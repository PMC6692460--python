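"""High-level screen analysis: from plate tables to per-compound reports.

These drivers consume the long-format CSV schemas the generators write
(endpoint: well, role, compound, concentration_molar, orientation, rfu;
kinetic: well, role, compound, concentration_molar, time_s, bu) and tie
together the elementary assay operations: dual-read averaging, percent-of-
control normalisation, antagonist calling, 4PL fitting, kinetic window
totals and replicate statistics.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np
import pandas as pd

from . import assay
from .errors import AnalysisError, InputError

ENDPOINT_COLUMNS = ["well", "role", "compound", "concentration_molar", "orientation", "rfu"]
KINETIC_COLUMNS = ["well", "role", "compound", "concentration_molar", "time_s", "bu"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{what}: missing column(s) {', '.join(missing)}")


def endpoint_report(table: pd.DataFrame) -> dict[str, Any]:
    """Analyse an endpoint screen table into per-compound calls and fits.

    Well responses are the mean of the forward and reverse reads, expressed
    as percent of the positive-control mean; each compound gets an
    antagonist call and, when it has >= 4 dosages, a 4PL fit.
    """
    _require_columns(table, ENDPOINT_COLUMNS, "endpoint table")
    per_well = (
        table.groupby(["well", "role", "compound"], dropna=False)
        .agg(rfu_mean=("rfu", "mean"), concentration_molar=("concentration_molar", "first"))
        .reset_index()
    )
    pc = per_well.loc[per_well["role"] == "positive-control", "rfu_mean"]
    if pc.empty:
        raise AnalysisError("no positive-control wells in the endpoint table")
    pc_mean = float(pc.mean())
    per_well["percent_of_pc"] = assay.endpoint_percent_response(per_well["rfu_mean"], pc_mean)

    report: dict[str, Any] = {"pc_mean_rfu": pc_mean, "compounds": {}}
    wells = per_well[(per_well["role"] == "compound") & (per_well["compound"] != "")]
    for compound, sub in wells.groupby("compound"):
        curve = (
            sub.groupby("concentration_molar")["percent_of_pc"]
            .mean()
            .sort_index(ascending=False)
        )
        entry: dict[str, Any] = {
            "call": assay.classify_antagonist(curve.to_numpy()),
            "doses_molar": [float(c) for c in curve.index],
            "percent_of_pc": [float(p) for p in curve.to_numpy()],
        }
        if curve.size >= 4:
            fit = assay.fit_4pl(curve.index.to_numpy(), curve.to_numpy())
            entry["fit"] = {
                "bottom": fit.bottom, "top": fit.top, "hill": fit.hill,
                "ic50_molar": fit.ic50, "ci95_molar": [fit.ci95_low, fit.ci95_high],
                "converged": fit.converged,
            }
            if not fit.converged:
                entry["fit"]["warning"] = fit.message
        report["compounds"][compound] = entry
    return report


def kinetic_report(table: pd.DataFrame, assay_column: str | None = "assay") -> dict[str, Any]:
    """Analyse kinetic traces into two-window percent-of-control responses.

    Traces are averaged per well into the two 30-s window means, normalised
    to the positive control's second window.  When an assay (replicate)
    column with >= 2 independent assays per dose is present, dose groups are
    compared by one-way ANOVA + Tukey HSD on assay-level means.
    """
    _require_columns(table, KINETIC_COLUMNS, "kinetic table")
    has_assay = assay_column is not None and assay_column in table.columns
    keys = ["well", "role", "compound", "concentration_molar"] + (
        [assay_column] if has_assay else []
    )
    totals = []
    for key, sub in table.groupby(keys, dropna=False):
        trace = sub.sort_values("time_s")["bu"].to_numpy()
        r1, r2 = assay.kinetic_range_totals(trace)
        totals.append(dict(zip(keys, key if isinstance(key, tuple) else (key,)),
                           range1_mean=r1, range2_mean=r2))
    per_well = pd.DataFrame(totals)
    pc = per_well[per_well["role"] == "positive-control"]
    if pc.empty:
        raise AnalysisError("no positive-control wells in the kinetic table")
    pc2 = float(pc["range2_mean"].mean())
    pcts = per_well.apply(
        lambda row: assay.normalize_to_pc((row.range1_mean, row.range2_mean), pc2),
        axis=1, result_type="expand",
    )
    per_well[["pct_range1", "pct_range2"]] = pcts

    report: dict[str, Any] = {"pc_range2_mean": pc2, "compounds": {}}
    wells = per_well[(per_well["role"] == "compound") & (per_well["compound"] != "")]
    for compound, sub in wells.groupby("compound"):
        curve = (
            sub.groupby("concentration_molar")[["pct_range1", "pct_range2"]]
            .mean()
            .sort_index(ascending=False)
        )
        entry: dict[str, Any] = {
            "doses_molar": [float(c) for c in curve.index],
            "pct_range1": [float(v) for v in curve["pct_range1"]],
            "pct_range2": [float(v) for v in curve["pct_range2"]],
        }
        if curve.shape[0] >= 3:
            entry["call"] = assay.classify_antagonist(curve["pct_range2"].to_numpy())
        if has_assay:
            groups = {
                f"{conc:.3g}": g.groupby(assay_column)["pct_range2"].mean().to_numpy()
                for conc, g in sub.groupby("concentration_molar")
            }
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                st = assay.replicate_stats(groups)
                entry["anova_p"] = None if math.isnan(st.anova_p) else st.anova_p
                entry["tukey_letters"] = st.letters
        report["compounds"][compound] = entry
    return report
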