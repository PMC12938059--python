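"""Curves, Wilson intervals, and the RT preprocessing pipeline."""

import numpy as np
import pandas as pd
import pytest

from nearmerge import descriptives, design, observer, sdt
from nearmerge.descriptives import (accuracy_curve, identification_curve,
                                    preprocess_rt, retention_summary)


def _id_responses(n_listeners=6, seed=0):
    trials = design.build_id_blocks(seed=seed)
    frames = [observer.simulate_identification(observer.ID_DEFAULTS, trials,
                                               seed=seed + i,
                                               listener=f"L{i:02d}")
              for i in range(n_listeners)]
    return pd.concat(frames, ignore_index=True)


class TestIdentificationCurve:
    def test_wilson_interval_matches_oracle(self):
        # 50/100 with z = 1.959964: the closed-form Wilson bounds
        df = pd.DataFrame({"vowel": "i", "step": 3,
                           "response": ["l"] * 50 + ["n"] * 50})
        row = identification_curve(df).iloc[0]
        z = 1.959964
        n, p = 100, 0.5
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(p * (1 - p) / n
                                              + z**2 / (4 * n**2))
        assert row["prop_l"] == 0.5
        assert row["ci_low"] == pytest.approx(center - half, abs=1e-9)
        assert row["ci_high"] == pytest.approx(center + half, abs=1e-9)
        assert row["ci_low"] == pytest.approx(0.404, abs=5e-4)
        assert row["ci_high"] == pytest.approx(0.596, abs=5e-4)

    def test_zero_successes_boundary(self):
        df = pd.DataFrame({"vowel": "i", "step": 0, "response": ["n"] * 40})
        row = identification_curve(df).iloc[0]
        assert row["prop_l"] == 0.0
        assert row["ci_low"] == 0.0
        assert row["ci_high"] > 0.0

    def test_intervals_contain_estimate_and_stay_in_unit_range(self):
        curve = identification_curve(_id_responses())
        assert ((curve["ci_low"] <= curve["prop_l"]) &
                (curve["prop_l"] <= curve["ci_high"])).all()
        assert (curve["ci_low"] >= 0).all() and (curve["ci_high"] <= 1).all()

    def test_steep_i_curve_monotone(self):
        curve = identification_curve(_id_responses(n_listeners=12))
        props = curve[curve["vowel"] == "i"].sort_values("step")["prop_l"]
        assert np.all(np.diff(props.to_numpy()) > -0.05)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no identification"):
            identification_curve(pd.DataFrame({"vowel": [], "step": [],
                                               "response": []}))


@pytest.fixture(scope="module")
def ax_responses():
    trials = design.build_ax_blocks(seed=1)
    return observer.simulate_ax_cohort(observer.POOLED_DEFAULTS, trials,
                                       16, seed=5)


class TestAccuracyCurve:

    def test_midpoints_are_one_through_five(self, ax_responses):
        curve = accuracy_curve(ax_responses)
        for vowel in ("i", "a"):
            mids = sorted(curve[curve["vowel"] == vowel]["midpoint"])
            assert mids == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_null_observer_accuracy_is_false_alarm_rate(self):
        k = 1.5
        params = observer.ObserverParams(dprime_by_vowel={"i": 0.0, "a": 0.0},
                                         k_by_vowel={"i": k, "a": k})
        trials = design.build_ax_blocks(seed=2)
        resp = observer.simulate_ax_cohort(params, trials, 40, seed=6)
        curve = accuracy_curve(resp)
        expected = float(sdt.false_alarm_rate(k))
        assert np.allclose(curve["prop_correct"], expected, atol=0.04)

    def test_higher_i_sensitivity_yields_higher_i_accuracy(self, ax_responses):
        curve = accuracy_curve(ax_responses)
        by_vowel = curve.groupby("vowel")["prop_correct"].mean()
        assert by_vowel["i"] > by_vowel["a"]


class TestPreprocessRt:
    def _table(self):
        """3748 AX trials with 425 planted violations: 140 missing RTs,
        140 outside the 0.1-3.0 s bounds, 145 extreme on log-RT."""
        n, n_listeners = 3748, 32
        rng = np.random.default_rng(99)
        listeners = [f"L{i % n_listeners:02d}" for i in range(n)]
        rt = np.exp(rng.uniform(-0.75, -0.65, size=n))
        rt[:140] = np.nan          # timeouts
        rt[140:280] = 5.0          # beyond the upper bound
        rt[280:425] = 2.8          # inside bounds, far out on log-RT
        order = rng.permutation(n)
        return pd.DataFrame({"listener": np.array(listeners)[order],
                             "rt_s": rt[order],
                             "correct": True})

    def test_printed_trim_percentage_reproduced(self):
        filtered, report = preprocess_rt(self._table())
        assert report.n_input == 3748
        assert report.n_removed == 425
        assert report.n_retained == 3323
        assert round(report.pct_removed, 2) == 11.34
        assert "11.34%" in report.summary()

    def test_stage_accounting(self):
        _, report = preprocess_rt(self._table())
        assert report.n_missing == 140
        assert report.n_out_of_bounds == 140
        assert report.n_mad_trimmed == 145

    def test_constant_rts_nothing_mad_trimmed(self):
        df = pd.DataFrame({"listener": ["L01"] * 50, "rt_s": 0.5,
                           "correct": True})
        _, report = preprocess_rt(df)
        assert report.n_mad_trimmed == 0
        assert report.n_retained == 50

    def test_bounds_rule_removes_5s_trial(self):
        df = pd.DataFrame({"listener": ["L01"] * 20,
                           "rt_s": [0.5] * 19 + [5.0], "correct": True})
        _, report = preprocess_rt(df)
        assert report.n_out_of_bounds == 1

    def test_idempotent_with_frozen_stats(self):
        filtered, _ = preprocess_rt(self._table())
        again, report2 = preprocess_rt(filtered,
                                       frozen_stats=filtered.attrs["trim_stats"])
        assert report2.n_removed == 0
        pd.testing.assert_frame_equal(again.reset_index(drop=True),
                                      filtered.reset_index(drop=True))

    def test_order_stable(self):
        table = self._table()
        filtered, _ = preprocess_rt(table)
        assert list(filtered.index) == sorted(filtered.index,
                                              key=list(table.index).index)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_rt(pd.DataFrame())


class TestRetention:
    def test_printed_timeout_percentage_reproduced(self):
        """32 listeners x 168 identification trials with 50 timeouts."""
        n = 32 * 168
        resp = pd.DataFrame({"response": ["l"] * (n - 50) + [None] * 50})
        summary = retention_summary(resp)
        assert summary["n_total"] == 5376
        assert summary["n_valid"] == 5326
        assert round(summary["pct_timeout"], 2) == 0.93
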