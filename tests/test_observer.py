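"""Generative observers: null cases, limits, estimator consistency."""

import numpy as np
import pandas as pd
import pytest

from nearmerge import observer, sdt
from nearmerge.observer import (ObserverParams, PsychFuncParams, RtParams,
                                prob_l, simulate_ax, simulate_identification,
                                simulate_rt)


def _bulk_trials(n_same, n_diff, vowel="i"):
    return pd.DataFrame({"vowel": vowel,
                         "delta": [0] * n_same + [2] * n_diff})


class TestAxObserver:
    def test_null_sensitivity_equalizes_rates(self):
        params = ObserverParams(dprime_by_vowel={"i": 0.0},
                                k_by_vowel={"i": 1.5})
        resp = simulate_ax(params, _bulk_trials(40_000, 40_000), seed=0)
        said_diff = resp["response"] == "different"
        h = said_diff[resp["delta"] == 2].mean()
        f = said_diff[resp["delta"] == 0].mean()
        assert h == pytest.approx(f, abs=0.01)

    def test_conservative_criterion_limit(self):
        params = ObserverParams(dprime_by_vowel={"i": 1.0},
                                k_by_vowel={"i": 8.0})
        resp = simulate_ax(params, _bulk_trials(5_000, 5_000), seed=1)
        assert (resp["response"] == "same").mean() > 0.999

    def test_seed_determinism(self):
        params = observer.POOLED_DEFAULTS
        trials = _bulk_trials(500, 500)
        a = simulate_ax(params, trials, seed=7)
        b = simulate_ax(params, trials, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_hit_rate_nondecreasing_in_dprime(self):
        trials = _bulk_trials(0, 20_000)
        rates = []
        for d in (0.0, 0.5, 1.0, 2.0):
            params = ObserverParams(dprime_by_vowel={"i": d},
                                    k_by_vowel={"i": 1.5})
            resp = simulate_ax(params, trials, seed=3)
            rates.append((resp["response"] == "different").mean())
        assert np.all(np.diff(rates) > -0.01)

    def test_latent_sampler_matches_closed_form(self):
        params = ObserverParams(dprime_by_vowel={"i": 1.2},
                                k_by_vowel={"i": 1.8})
        trials = _bulk_trials(40_000, 40_000)
        latent = simulate_ax(params, trials, seed=5, latent=True)
        said_diff = latent["response"] == "different"
        h = said_diff[latent["delta"] == 2].mean()
        f = said_diff[latent["delta"] == 0].mean()
        assert h == pytest.approx(float(sdt.hit_rate(1.8, 1.2)), abs=0.01)
        assert f == pytest.approx(float(sdt.false_alarm_rate(1.8)), abs=0.01)

    def test_estimator_consistency_on_grid(self):
        """Estimates from 1e5 simulated trials per cell fall within 3 MC
        standard errors of the generative values on a (k, d') grid."""
        n = 100_000
        trials = _bulk_trials(n, n)
        for k_gen in (0.5, 1.0, 2.0, 3.0):
            for d_gen in (0.0, 0.5, 1.0, 2.0):
                params = ObserverParams(dprime_by_vowel={"i": d_gen},
                                        k_by_vowel={"i": k_gen})
                resp = simulate_ax(params, trials,
                                   seed=1000 + int(10 * k_gen + d_gen))
                cells = {c.delta: c for c in sdt.counts_from_responses(resp)}
                _, f = sdt.correct_rates(cells[0])
                h, _ = sdt.correct_rates(cells[2])
                k_hat = sdt.estimate_criterion(f)
                d_hat = sdt.solve_dprime(h, k_hat)
                # delta-method MC standard errors
                f_true = float(sdt.false_alarm_rate(k_gen))
                se_f = np.sqrt(f_true * (1 - f_true) / n)
                dfdk = np.sqrt(2) * 0.3989 * np.exp(-k_gen**2 / 4)
                se_k = se_f / dfdk
                assert abs(k_hat - k_gen) < max(3 * se_k, 0.02)
                h_true = float(sdt.hit_rate(k_gen, d_gen))
                se_h = np.sqrt(h_true * (1 - h_true) / n)
                eps = 1e-4
                dhdd = (float(sdt.hit_rate(k_gen, d_gen + eps)) -
                        h_true) / eps
                se_d = se_h / dhdd + se_k * abs(
                    (float(sdt.hit_rate(k_gen + eps, d_gen)) - h_true)
                    / eps) / dhdd
                assert abs(d_hat - d_gen) < max(3 * se_d, 0.03)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(dprime_by_vowel={"i": 1.0},
                           k_by_vowel={"i": -0.5})
        with pytest.raises(ValueError):
            ObserverParams(dprime_by_vowel={"i": 1.0},
                           k_by_vowel={"i": 1.0}, lapse=0.5)


class TestIdentificationObserver:
    def test_probability_half_at_boundary(self):
        params = PsychFuncParams(boundary_by_vowel={"i": 3.0},
                                 slope_by_vowel={"i": 1.0},
                                 guess=0.03, lapse=0.03)
        assert prob_l(params, ["i"], [3.0])[0] == pytest.approx(0.5)

    def test_steep_slope_approaches_step_function(self):
        params = PsychFuncParams(boundary_by_vowel={"i": 3.0},
                                 slope_by_vowel={"i": 1e-4})
        p = prob_l(params, ["i"] * 7, np.arange(7.0))
        assert np.all(p[:3] < 1e-6) and np.all(p[4:] > 1 - 1e-6)

    def test_flat_configuration_has_small_adjacent_differences(self, id_trials):
        frames = [simulate_identification(observer.ID_DEFAULTS, id_trials,
                                          seed=s, listener=f"L{s}")
                  for s in range(40)]
        resp = pd.concat(frames)
        props = (resp.assign(is_l=resp["response"] == "l")
                 .groupby(["vowel", "step"])["is_l"].mean())
        diffs_a = np.abs(np.diff(props["a"].to_numpy()))
        diffs_i = np.abs(np.diff(props["i"].to_numpy()))
        assert np.all(diffs_a < 0.15)       # flat /a/ identification
        assert diffs_a.max() < diffs_i.max()  # steep /i/, flat /a/

    def test_guess_plus_lapse_bounded(self):
        with pytest.raises(ValueError):
            PsychFuncParams(boundary_by_vowel={"i": 3.0},
                            slope_by_vowel={"i": 1.0}, guess=0.6, lapse=0.5)


class TestRtModel:
    def test_degenerate_noise_gives_constant(self):
        trials = pd.DataFrame({"listener": ["L01"] * 10})
        params = RtParams(mu_log=np.log(0.5), sigma_log=0.0)
        out = simulate_rt(params, trials, seed=0)
        np.testing.assert_allclose(out["rt_s"], 0.5)

    def test_age_multiplier_shifts_median(self):
        n = 60_000
        params = RtParams(mu_log=np.log(0.7), sigma_log=0.3,
                          covariate_multipliers={"age_z": 1.09})
        cov = pd.DataFrame({"age_z": [0.0, 1.0]}, index=["L00", "L01"])
        trials = pd.DataFrame({"listener": ["L00"] * n + ["L01"] * n})
        out = simulate_rt(params, trials, seed=2, covariates=cov)
        med = out.groupby("listener")["rt_s"].median()
        assert med["L01"] / med["L00"] == pytest.approx(1.09, abs=0.02)

    def test_seed_determinism(self):
        trials = pd.DataFrame({"listener": ["L01"] * 100})
        a = simulate_rt(RtParams(), trials, seed=4)
        b = simulate_rt(RtParams(), trials, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_time_ratio_rejected(self):
        with pytest.raises(ValueError):
            RtParams(covariate_multipliers={"age_z": -1.0})
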