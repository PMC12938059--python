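"""Generative listener models: an SDT differencing observer for AX trials,
a logistic psychometric responder for identification, and lognormal RTs.

The AX observer draws Bernoulli responses from the same model equations the
estimator inverts (``sdt.false_alarm_rate`` / ``sdt.hit_rate``), so
parameter-recovery tests are sharp: any systematic discrepancy between
generative and recovered (k, d') is an estimator defect, not model
mismatch.  A latent-variable sampler that actually differences two noisy
observations is available as a cross-check; it is distributionally
equivalent to the ``standard`` equation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import sdt


@dataclass
class ObserverParams:
    """Differencing-observer parameters per vowel context.

    dprime_by_vowel : generative sensitivity for a 2-step separation.
    k_by_vowel : criterion on the difference axis (SD units), > 0.
    lapse : probability of replacing the model response with a coin flip.
    """

    dprime_by_vowel: dict[str, float]
    k_by_vowel: dict[str, float]
    lapse: float = 0.0
    mode: str = "standard"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        for v, k in self.k_by_vowel.items():
            if k <= 0:
                raise ValueError(f"criterion for vowel {v!r} must be > 0")
            f = float(sdt.false_alarm_rate(k, self.mode))
            if not 0.0 < f < 1.0:
                raise ValueError(f"criterion for vowel {v!r} implies a "
                                 "degenerate false-alarm rate")
        for v, d in self.dprime_by_vowel.items():
            if d < 0:
                raise ValueError(f"d' for vowel {v!r} must be >= 0")


# the study's pooled group-level values are natural simulation defaults
POOLED_DEFAULTS = ObserverParams(
    dprime_by_vowel={"i": 1.03, "a": 0.45},
    k_by_vowel={"i": 1.87, "a": 2.13},
)


def simulate_ax(params: ObserverParams, trials: pd.DataFrame,
                seed: int, listener: str = "L01",
                latent: bool = False) -> pd.DataFrame:
    """Simulate same/different responses for an AX trial list.

    `trials` needs columns vowel and delta (as built by design.build_ax_blocks).
    With ``latent=True``, responses come from explicitly differencing two
    unit-variance observations instead of the closed-form cell probabilities.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    vowels = out["vowel"].to_numpy()
    deltas = out["delta"].to_numpy()

    k = np.array([params.k_by_vowel[v] for v in vowels])
    d = np.array([params.dprime_by_vowel[v] for v in vowels])
    signal = deltas != 0

    if latent:
        mean_sep = np.where(signal, d, 0.0)
        diff = rng.normal(mean_sep, np.sqrt(2.0), size=n)
        said_diff = np.abs(diff) > k
    else:
        p_diff = np.where(signal,
                          sdt.hit_rate(k, d, params.mode),
                          sdt.false_alarm_rate(k, params.mode))
        said_diff = rng.random(n) < p_diff

    if params.lapse > 0:
        lapse_mask = rng.random(n) < params.lapse
        coin = rng.random(n) < 0.5
        said_diff = np.where(lapse_mask, coin, said_diff)

    out["listener"] = listener
    out["response"] = np.where(said_diff, "different", "same")
    out["correct"] = said_diff == signal
    return out


def simulate_ax_cohort(params: ObserverParams, trials: pd.DataFrame,
                       n_listeners: int, seed: int,
                       k_sd: float = 0.0, dprime_sd: float = 0.0,
                       latent: bool = False) -> pd.DataFrame:
    """Simulate a cohort; optional normal heterogeneity in (k, d').

    Per-listener parameters are truncated below at small positive values so
    every listener satisfies the parameter invariants.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_listeners):
        if k_sd > 0 or dprime_sd > 0:
            p = ObserverParams(
                dprime_by_vowel={
                    v: max(0.0, d + rng.normal(0.0, dprime_sd))
                    for v, d in params.dprime_by_vowel.items()},
                k_by_vowel={
                    v: max(0.05, k + rng.normal(0.0, k_sd))
                    for v, k in params.k_by_vowel.items()},
                lapse=params.lapse, mode=params.mode)
        else:
            p = params
        listener_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(simulate_ax(p, trials, listener_seed,
                                  listener=f"L{i + 1:02d}", latent=latent))
    return pd.concat(frames, ignore_index=True)


@dataclass
class PsychFuncParams:
    """Logistic psychometric identification model per vowel.

    P(/l/ | step) = guess + (1 - guess - lapse) *
                    logistic((step - boundary) / slope)

    A steep function (small slope) emulates categorical /i/-context
    labelling; a large slope yields the flat, /l/-biased /a/ pattern.
    """

    boundary_by_vowel: dict[str, float]
    slope_by_vowel: dict[str, float]
    guess: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.guess + self.lapse >= 1.0:
            raise ValueError("guess + lapse must be < 1")
        for v, s in self.slope_by_vowel.items():
            if s <= 0:
                raise ValueError(f"slope for vowel {v!r} must be > 0")


ID_DEFAULTS = PsychFuncParams(
    boundary_by_vowel={"i": 3.5, "a": 1.0},
    slope_by_vowel={"i": 0.55, "a": 4.0},
    guess=0.02, lapse=0.02,
)


def prob_l(params: PsychFuncParams, vowel, step):
    b = np.array([params.boundary_by_vowel[v] for v in np.atleast_1d(vowel)])
    s = np.array([params.slope_by_vowel[v] for v in np.atleast_1d(vowel)])
    core = expit((np.asarray(step, float) - b) / s)
    return params.guess + (1.0 - params.guess - params.lapse) * core


def simulate_identification(params: PsychFuncParams, trials: pd.DataFrame,
                            seed: int, listener: str = "L01") -> pd.DataFrame:
    """Bernoulli /l/-vs-/n/ choices for an identification trial list."""
    rng = np.random.default_rng(seed)
    out = trials.copy()
    p = prob_l(params, out["vowel"].to_numpy(), out["step"].to_numpy())
    chose_l = rng.random(len(out)) < p
    out["listener"] = listener
    out["response"] = np.where(chose_l, "l", "n")
    return out


@dataclass
class RtParams:
    """Lognormal RT model: log-scale intercept, SD, and covariate
    time-ratios (a ratio of 1.09 means +9% RT per +1 SD of that covariate)."""

    mu_log: float = np.log(0.7)
    sigma_log: float = 0.35
    covariate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        for name, tr in self.covariate_multipliers.items():
            if tr <= 0:
                raise ValueError(f"time ratio for {name!r} must be > 0")


def simulate_rt(params: RtParams, trials: pd.DataFrame, seed: int,
                covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach rt_s = exp(mu + sum z_c log TR_c + noise) to a trial table.

    `covariates` is one row per listener (index = listener id) of z-scored
    covariate values matching the keys of covariate_multipliers.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    shift = np.zeros(len(out))
    if covariates is not None and params.covariate_multipliers:
        for name, tr in params.covariate_multipliers.items():
            z = covariates.loc[out["listener"], name].to_numpy()
            shift += z * np.log(tr)
    noise = rng.normal(0.0, params.sigma_log, size=len(out)) \
        if params.sigma_log > 0 else 0.0
    out["rt_s"] = np.exp(params.mu_log + shift + noise)
    return out
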