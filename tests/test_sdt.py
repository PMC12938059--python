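"""Differencing-model arithmetic: corrections, inversions, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nearmerge import design, observer, sdt


class TestCorrectRates:
    def test_perfect_hits_corrected(self):
        counts = sdt.SdtCellCounts("L", "i", 2, hits=10, misses=0)
        h, _ = sdt.correct_rates(counts)
        assert h == pytest.approx(10.5 / 11)

    def test_zero_false_alarms_stay_positive(self):
        counts = sdt.SdtCellCounts("L", "i", 0, false_alarms=0,
                                   correct_rejections=60)
        _, f = sdt.correct_rates(counts)
        assert f == pytest.approx(0.5 / 61)
        assert f > 0

    def test_balanced_counts_give_half(self):
        counts = sdt.SdtCellCounts("L", "i", 2, hits=30, misses=30)
        h, _ = sdt.correct_rates(counts)
        assert h == 0.5

    def test_never_zero_or_one(self):
        for hits, misses in ((0, 50), (50, 0), (1, 0), (0, 1)):
            h, _ = sdt.correct_rates(
                sdt.SdtCellCounts("L", "i", 2, hits=hits, misses=misses))
            assert 0.0 < h < 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sdt.SdtCellCounts("L", "i", 2, hits=-1)


class TestCriterion:
    def test_f_of_one_gives_zero(self):
        assert sdt.estimate_criterion(1.0 - 1e-15) == pytest.approx(0.0,
                                                                    abs=1e-6)

    def test_half_false_alarms(self):
        # sqrt(2) * Phi^-1(0.75), from the normal-quantile oracle
        expected = np.sqrt(2) * norm.ppf(0.75)
        assert sdt.estimate_criterion(0.5) == pytest.approx(expected,
                                                            abs=1e-12)
        assert expected == pytest.approx(0.9539, abs=1e-4)

    def test_pooled_a_context_rate(self):
        # F = 0.196 maps to k = 1.829 under the model's F equation (the
        # listener-mean aggregation prints a different number; the
        # transform is nonlinear, so the two aggregations need not agree)
        assert sdt.estimate_criterion(0.196) == pytest.approx(1.8286,
                                                              abs=1e-3)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                sdt.estimate_criterion(bad)


class TestSolveDprime:
    def test_chance_hit_rate_gives_zero(self):
        for k in (0.5, 1.87, 3.0):
            h0 = float(sdt.hit_rate(k, 0.0))
            assert sdt.solve_dprime(h0, k) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("mode", sdt.MODES)
    def test_forward_inverse_round_trip(self, mode):
        for k in (0.5, 1.0, 1.829, 2.0, 3.0):
            for d in (0.0, 0.5, 1.0, 1.54, 2.0):
                h = float(sdt.hit_rate(k, d, mode))
                assert sdt.solve_dprime(h, k, mode) == pytest.approx(
                    d, abs=1e-8)

    def test_below_chance_gives_small_negative(self):
        k = 1.87
        h0 = float(sdt.hit_rate(k, 0.0))
        d = sdt.solve_dprime(h0 - 0.01, k)
        assert -0.5 < d < 0.0

    def test_f_decreasing_in_k_and_h_increasing_in_d(self):
        ks = np.linspace(0.1, 4, 50)
        assert np.all(np.diff(sdt.false_alarm_rate(ks)) < 0)
        ds = np.linspace(0, 6, 50)
        for k in (0.5, 2.0):
            assert np.all(np.diff(sdt.hit_rate(k, ds)) > 0)


class TestLnBeta:
    def test_zero_criterion_closed_form(self):
        for d in (0.5, 1.0, 2.0):
            assert sdt.ln_beta(d, 0.0) == pytest.approx(-d * d / 4.0)

    def test_zero_sensitivity_is_zero(self):
        assert sdt.ln_beta(0.0, 2.0) == 0.0

    def test_pooled_i_context_value(self):
        # direct high-precision evaluation of -d'^2/4 + ln cosh(k d'/sqrt 2)
        d, k = 1.03, 1.87
        expected = -d * d / 4 + np.log(np.cosh(k * d / np.sqrt(2)))
        assert sdt.ln_beta(d, k) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4671, abs=1e-4)

    def test_increases_with_criterion(self):
        vals = [sdt.ln_beta(1.0, k) for k in (0.0, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(vals) > 0)


class TestEstimateCells:
    def test_recovery_on_homogeneous_cohort(self):
        """32 listeners at study-scale trial counts: listener-mean estimates
        land near the generative values (finite-sample bias is the dominant
        residual at 60 trials/cell)."""
        params = observer.ObserverParams(dprime_by_vowel={"i": 1.03, "a": 0.45},
                                         k_by_vowel={"i": 1.87, "a": 2.13})
        trials = design.build_ax_blocks(seed=0)
        responses = observer.simulate_ax_cohort(params, trials, 32, seed=42)
        est = sdt.estimate_cells(responses)
        means = est["listener_mean"].set_index("vowel")
        assert means.loc["i", "k"] == pytest.approx(1.87, abs=0.15)
        assert means.loc["a", "k"] == pytest.approx(2.13, abs=0.15)
        assert means.loc["i", "dprime"] == pytest.approx(1.03, abs=0.3)
        assert means.loc["a", "dprime"] == pytest.approx(0.45, abs=0.3)

    def test_row_count_is_listeners_by_vowels(self):
        params = observer.POOLED_DEFAULTS
        trials = design.build_ax_blocks(seed=1)
        responses = observer.simulate_ax_cohort(params, trials, 5, seed=7)
        est = sdt.estimate_cells(responses)
        assert len(est["per_listener"]) == 5 * 2

    def test_always_same_responder_degenerate_path(self):
        """A listener who always answers "same" has equal corrected hit and
        false-alarm rates, so the implied criterion is large but finite and
        the implied sensitivity exactly zero."""
        trials = design.build_ax_blocks(seed=2)
        responses = trials.copy()
        responses["listener"] = "L01"
        responses["response"] = "same"
        est = sdt.estimate_cells(responses)
        row = est["per_listener"].iloc[0]
        assert row["f_rate"] > 0          # Hautus keeps F off zero
        assert row["k"] > 2.5             # large, finite criterion
        assert row["dprime"] == pytest.approx(0.0, abs=1e-6)


class TestBootstrap:
    def _frame(self, k_values):
        return pd.DataFrame({
            "listener": [f"L{i}" for i in range(len(k_values))],
            "vowel": "i", "k": k_values,
            "dprime": 1.0, "ln_beta_d": 0.4,
            "h_rate": 0.4, "f_rate": 0.2})

    def test_zero_variance_collapses_to_point(self):
        ci = sdt.bootstrap_ci(self._frame([2.0] * 8), b=500, seed=0)
        k_row = ci[ci["index"] == "k"].iloc[0]
        assert k_row["ci_low"] == k_row["ci_high"] == 2.0

    def test_seed_determinism(self):
        frame = self._frame([1.0, 1.5, 2.0, 2.5, 3.0])
        a = sdt.bootstrap_ci(frame, b=1000, seed=9)
        b = sdt.bootstrap_ci(frame, b=1000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_listener_rejected(self):
        with pytest.raises(ValueError, match="2 listeners"):
            sdt.bootstrap_ci(self._frame([2.0]), b=100, seed=0)

    def test_coverage_on_simulated_cohorts(self):
        """Nominal 95% percentile interval covers the generative mean in at
        least 90% of replicates (large per-listener trial counts keep
        finite-sample bias negligible)."""
        gen_k = 2.0
        rng = np.random.default_rng(123)
        n_cover = 0
        n_rep = 120
        for _ in range(n_rep):
            f_true = float(sdt.false_alarm_rate(gen_k))
            fa = rng.binomial(600, f_true, size=24)
            ks = [sdt.estimate_criterion((x + 0.5) / 601.0) for x in fa]
            frame = self._frame(ks)
            ci = sdt.bootstrap_ci(frame, b=400,
                                  seed=int(rng.integers(2**31)))
            row = ci[ci["index"] == "k"].iloc[0]
            if row["ci_low"] <= gen_k <= row["ci_high"]:
                n_cover += 1
        assert n_cover / n_rep >= 0.90
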