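"""Dual-addition assay analytics: dilutions, reads, calls, 4PL, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kininmine import (
    AnalysisError,
    ContractError,
    classify_antagonist,
    compact_letters,
    dilution_series,
    endpoint_percent_response,
    fit_4pl,
    four_pl,
    kinetic_range_totals,
    merge_dual_reads,
    normalize_to_pc,
    replicate_stats,
)


class TestDilutionSeries:
    def test_single_dose(self):
        d = dilution_series(1e-3, 1.4, 1)
        assert d.concentrations == (1e-3,)

    def test_tenth_dose_value(self):
        d = dilution_series(1e-4, 1.4, 10)
        assert d.concentrations[-1] == pytest.approx(1e-4 / 1.4**9)
        assert d.concentrations[-1] == pytest.approx(4.84e-6, rel=1e-3)

    def test_screen_design_strictly_decreasing(self):
        d = dilution_series(1e-3, 1.4, 22)
        assert len(d.concentrations) == 22
        assert all(a > b for a, b in zip(d.concentrations, d.concentrations[1:]))

    @pytest.mark.parametrize("args", [(0, 1.4, 5), (1e-3, 1.0, 5), (1e-3, 1.4, 0)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ContractError):
            dilution_series(*args)


class TestDualReads:
    def test_rotation_mapping(self):
        fwd = np.arange(16 * 24, dtype=float).reshape(16, 24)
        rev = np.zeros((16, 24))
        rev[0, 0] = 99.0  # reverse A1 is forward P24
        df = merge_dual_reads(fwd, rev)
        p24 = df[(df.row == 16) & (df.col == 24)].iloc[0]
        assert p24.rfu_reverse == 99.0
        assert p24.well == "P24"

    def test_identical_reads_mean_is_either(self):
        plate = np.random.default_rng(0).random((4, 6))
        df = merge_dual_reads(plate, np.rot90(plate, 2).copy())
        assert np.allclose(df.rfu_mean, df.rfu_forward)

    def test_dimension_mismatch(self):
        with pytest.raises(Exception):
            merge_dual_reads(np.zeros((4, 6)), np.zeros((6, 4)))


class TestPercentAndCalls:
    def test_percent_of_control(self):
        assert endpoint_percent_response(400.0, 1000.0) == pytest.approx(40.0)
        assert endpoint_percent_response(1000.0, 1000.0) == pytest.approx(100.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ContractError):
            endpoint_percent_response(100.0, 0.0)

    @pytest.mark.parametrize(
        "curve, call",
        [
            ([100, 100, 100], "none"),
            ([100, 70, 40], "partial"),
            ([100, 50, 10], "full"),
            ([100, 50.0, 60], "partial"),  # threshold is inclusive
        ],
    )
    def test_classification(self, curve, call):
        assert classify_antagonist(curve) == call

    def test_needs_three_doses(self):
        with pytest.raises(ContractError):
            classify_antagonist([100, 50])

    @given(
        curve=st.lists(st.floats(0, 150), min_size=3, max_size=10),
        idx=st.integers(0, 9),
        drop=st.floats(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_dose_response(self, curve, idx, drop):
        """Lowering any dose's percent never downgrades the call."""
        order = {"none": 0, "partial": 1, "full": 2}
        before = classify_antagonist(curve)
        lowered = list(curve)
        lowered[idx % len(curve)] = max(0.0, lowered[idx % len(curve)] - drop)
        assert order[classify_antagonist(lowered)] >= order[before]

    def test_scale_invariance_of_percent(self):
        rfu = np.array([100.0, 250.0, 900.0])
        base = endpoint_percent_response(rfu, 1000.0)
        scaled = endpoint_percent_response(rfu * 7.3, 7300.0)
        assert np.allclose(base, scaled)


class TestFourPL:
    TRUTH = (5.0, 100.0, -4.65, -1.0)

    def test_noiseless_recovery(self):
        c = np.array(dilution_series(1e-4, 1.4, 10).concentrations)
        y = four_pl(c, *self.TRUTH)
        fit = fit_4pl(c, y)
        assert fit.converged
        assert fit.bottom == pytest.approx(self.TRUTH[0], rel=1e-6)
        assert fit.top == pytest.approx(self.TRUTH[1], rel=1e-6)
        assert fit.log_ic50 == pytest.approx(self.TRUTH[2], rel=1e-6)
        assert fit.hill == pytest.approx(self.TRUTH[3], rel=1e-6)
        assert fit.ic50 == pytest.approx(10 ** fit.log_ic50)

    def test_midpoint_property(self):
        """The response at c = IC50 is (top + bottom) / 2 — the fitted
        midpoint, not the 50%-of-control dose."""
        fit_val = four_pl(10 ** self.TRUTH[2], *self.TRUTH)
        assert fit_val == pytest.approx((self.TRUTH[0] + self.TRUTH[1]) / 2)

    def test_unit_change_shifts_log_ic50(self):
        c = np.array(dilution_series(1e-4, 1.4, 12).concentrations)
        y = four_pl(c, *self.TRUTH)
        fit_m = fit_4pl(c, y)
        fit_u = fit_4pl(c * 1e6, y)  # molar -> micromolar
        assert fit_u.log_ic50 - fit_m.log_ic50 == pytest.approx(6.0, abs=1e-6)
        assert fit_u.hill == pytest.approx(fit_m.hill, rel=1e-6)

    def test_flat_response_flagged_not_raised(self):
        c = np.array(dilution_series(1e-4, 1.4, 6).concentrations)
        fit = fit_4pl(c, np.full_like(c, 100.0))
        assert not fit.converged and "flat" in fit.message

    def test_too_few_doses(self):
        with pytest.raises(ContractError):
            fit_4pl([1e-4, 1e-5, 1e-6], [100, 50, 10])


class TestKinetics:
    def test_constant_trace(self):
        assert kinetic_range_totals([10.0] * 65) == (10.0, 10.0)

    def test_zero_trace(self):
        assert kinetic_range_totals([0.0] * 65) == (0.0, 0.0)

    def test_windows_have_thirty_samples(self):
        trace = np.zeros(65)
        trace[2:32] = 1.0
        trace[35:65] = 2.0
        assert kinetic_range_totals(trace) == (1.0, 2.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ContractError):
            kinetic_range_totals([1.0] * 40)

    def test_pc_normalizes_to_100(self):
        assert normalize_to_pc((0.0, 50.0), 100.0) == (0.0, 50.0)
        assert normalize_to_pc((0.0, 80.0), 80.0)[1] == pytest.approx(100.0)

    def test_nonpositive_pc_rejected(self):
        with pytest.raises(ContractError):
            normalize_to_pc((1.0, 1.0), 0.0)

    def test_scale_invariance(self):
        totals = (12.0, 48.0)
        k = 3.7
        assert normalize_to_pc(totals, 96.0) == pytest.approx(
            normalize_to_pc((totals[0] * k, totals[1] * k), 96.0 * k)
        )


class TestReplicateStats:
    def test_identical_groups_share_a_letter(self):
        groups = {"a": [10.0, 10.0, 10.0], "b": [10.0, 10.0, 10.0], "c": [10.0, 10.0, 10.0]}
        res = replicate_stats(groups)
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        lo = 10 + 0.1 * rng.standard_normal(3)
        hi = 1000 + 0.1 * rng.standard_normal(3)
        res = replicate_stats({"low": lo, "high": hi})
        assert res.anova_p < 0.01
        assert set(res.letters["low"]) != set(res.letters["high"])

    def test_group_with_single_assay_rejected(self):
        with pytest.raises(AnalysisError):
            replicate_stats({"a": [1.0], "b": [1.0, 2.0]})

    def test_power_exceeds_alpha_under_true_effect(self):
        """With a real dose effect at n = 3 assays the ANOVA rejects more
        often than the nominal 5% level."""
        rng = np.random.default_rng(123)
        rejections = 0
        runs = 200
        for _ in range(runs):
            groups = {
                "blank": 100 + 5 * rng.standard_normal(3),
                "mid": 80 + 5 * rng.standard_normal(3),
                "top": 30 + 5 * rng.standard_normal(3),
            }
            rejections += replicate_stats(groups).anova_p < 0.05
        assert rejections / runs > 0.5

    def test_compact_letters_chain(self):
        # a differs from c; b bridges both -> b shares a letter with each
        letters = compact_letters(
            ["a", "b", "c"], {("a", "c")}, means={"a": 3.0, "b": 2.0, "c": 1.0}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
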