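"""Signal-detection analysis for roving same-different (AX) data.

In a roving AX task the pair (A, X) is drawn from many continuum positions,
so the observer cannot hold a fixed standard in mind.  The appropriate
decision rule is *differencing*: respond "different" when the absolute
internal difference |X_A - X_X| exceeds a criterion ``k`` (expressed in SD
units on the difference axis).  With unit-variance internal observations and
a mean separation ``d'`` on signal (different) trials, the textbook
equal-variance differencing model gives

    F(k)      = 2 * Phi(-k / sqrt(2))
    H(k, d')  = Phi((d' - k) / sqrt(2)) + Phi(-(d' + k) / sqrt(2))

where ``F`` is the false-alarm rate on same pairs and ``H`` the hit rate on
different pairs.  An alternative equation set (mode ``"as_printed"``) keeps
the same ``F`` but drops the 1/sqrt(2) scaling of ``k`` inside ``H``:

    H(k, d')  = Phi(-k + d'/sqrt(2)) + Phi(-k - d'/sqrt(2))

The two sets coincide at d' = 0 only for the standard pair, which is why
``"standard"`` is the default; both are kept so published estimates computed
under either convention can be audited.  The complementary bias index is the
log likelihood ratio at the criterion,

    ln beta_d = -d'^2 / 4 + ln cosh(k * d' / sqrt(2)).

Counts are corrected with the log-linear (Hautus) rule -- 0.5 added to every
count, 1 to every denominator -- so rates never reach 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

SQRT2 = np.sqrt(2.0)

MODES = ("standard", "as_printed")

D_PRIME_BRACKET = 10.0  # root search bound on |d'|


# --------------------------------------------------------------------------
# model equations (forward)

def false_alarm_rate(k, mode: str = "standard"):
    """Model false-alarm rate F(k) on same pairs; identical in both modes."""
    _check_mode(mode)
    return 2.0 * norm.cdf(-np.asarray(k, float) / SQRT2)


def hit_rate(k, dprime, mode: str = "standard"):
    """Model hit rate H(k, d') on different pairs under `mode`."""
    _check_mode(mode)
    k = np.asarray(k, float)
    d = np.asarray(dprime, float)
    if mode == "standard":
        return norm.cdf((d - k) / SQRT2) + norm.cdf(-(d + k) / SQRT2)
    return norm.cdf(-k + d / SQRT2) + norm.cdf(-k - d / SQRT2)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


# --------------------------------------------------------------------------
# counts and corrected rates

@dataclass
class SdtCellCounts:
    """Response counts for one listener x vowel x step-distance cell.

    Delta = 0 cells carry no signal trials, so hits = misses = 0 there and
    only the false-alarm side is meaningful.
    """

    listener: str
    vowel: str
    delta: int
    hits: int = 0
    misses: int = 0
    false_alarms: int = 0
    correct_rejections: int = 0

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count in {name}")
        if self.delta == 0 and (self.hits or self.misses):
            raise ValueError("delta=0 cells cannot contain signal trials")


def correct_rates(counts: SdtCellCounts) -> tuple[float | None, float]:
    """Log-linear (Hautus) corrected (hit rate, false-alarm rate).

    Returns ``(None, f)`` for delta=0 cells.  Both rates are strictly inside
    (0, 1) for any finite counts.
    """
    f = (counts.false_alarms + 0.5) / (counts.false_alarms +
                                       counts.correct_rejections + 1.0)
    if counts.delta == 0:
        return None, f
    h = (counts.hits + 0.5) / (counts.hits + counts.misses + 1.0)
    return h, f


# --------------------------------------------------------------------------
# estimation (inverse)

def estimate_criterion(f_rate: float) -> float:
    """Criterion k from a false-alarm rate: k = sqrt(2) * Phi^-1(1 - F/2)."""
    if not 0.0 < f_rate < 1.0:
        raise ValueError(f"false-alarm rate must lie in (0,1), got {f_rate}")
    return float(SQRT2 * norm.ppf(1.0 - f_rate / 2.0))


def solve_dprime(h_rate: float, k: float, mode: str = "standard",
                 tol: float = 1e-12) -> float:
    """Solve H(k, d') = h for d' by bracketed root finding.

    H is monotone increasing in d' >= 0, so the root on [0, 10] is unique.
    When the observed hit rate falls below the chance level H(0; k) -- hits
    rarer than the false-alarm prediction -- the deficit is solved on the
    reflected scale and returned with a negative sign, so below-chance cells
    yield negative d' rather than an error.  Roots outside the bracket are
    clamped to +/-10.
    """
    _check_mode(mode)
    if not 0.0 < h_rate < 1.0:
        raise ValueError(f"hit rate must lie in (0,1), got {h_rate}")
    if k < 0:
        raise ValueError("criterion k must be non-negative")

    h0 = float(hit_rate(k, 0.0, mode))
    sign = 1.0
    target = h_rate
    if h_rate < h0:
        sign = -1.0
        target = h0 + (h0 - h_rate)  # reflect the deficit above chance

    if target >= float(hit_rate(k, D_PRIME_BRACKET, mode)):
        return sign * D_PRIME_BRACKET

    def objective(d: float) -> float:
        return float(hit_rate(k, d, mode)) - target

    root = brentq(objective, 0.0, D_PRIME_BRACKET, xtol=tol)
    return float(sign * root)


def ln_beta(dprime: float, k: float) -> float:
    """Log likelihood-ratio bias at the criterion.

    ln beta_d = -d'^2/4 + ln cosh(k d'/sqrt(2)); zero at d' = 0 and equal to
    -d'^2/4 at k = 0, increasing in k for d' > 0 (a conservative "same" bias).
    """
    d = float(dprime)
    # log cosh without overflow for large arguments
    z = abs(k * d / SQRT2)
    log_cosh = z + np.log1p(np.exp(-2.0 * z)) - np.log(2.0)
    return float(-d * d / 4.0 + log_cosh)


# --------------------------------------------------------------------------
# table-level estimation

@dataclass
class SdtEstimate:
    listener: str
    vowel: str
    k: float
    dprime: float
    ln_beta_d: float
    h_rate: float
    f_rate: float


def counts_from_responses(responses: pd.DataFrame) -> list[SdtCellCounts]:
    """Tabulate hit/miss/FA/CR counts per listener x vowel x delta cell.

    `responses` must carry columns listener, vowel, delta, response where
    response is "different" or "same" (timeouts/NaN rows are dropped).
    """
    df = responses.dropna(subset=["response"])
    out: list[SdtCellCounts] = []
    for (listener, vowel, delta), cell in df.groupby(
            ["listener", "vowel", "delta"], sort=True):
        said_diff = (cell["response"] == "different").sum()
        said_same = (cell["response"] == "same").sum()
        if delta == 0:
            out.append(SdtCellCounts(str(listener), str(vowel), int(delta),
                                     false_alarms=int(said_diff),
                                     correct_rejections=int(said_same)))
        else:
            out.append(SdtCellCounts(str(listener), str(vowel), int(delta),
                                     hits=int(said_diff),
                                     misses=int(said_same)))
    return out


def estimate_cells(responses: pd.DataFrame, mode: str = "standard"
                   ) -> dict[str, pd.DataFrame]:
    """Differencing-model estimates per listener x vowel, plus summaries.

    For each listener and vowel the criterion k is anchored on the delta=0
    false-alarm rate and d' solved from the delta=2 hit rate with that k.
    Listeners missing a delta=0 cell in a vowel are skipped with a warning
    column in the output rather than an exception.

    Returns a dict with:
      per_listener : one row per listener x vowel (k, d', ln beta_d, rates)
      listener_mean : mean of the per-listener indices by vowel
      pooled : estimates from counts pooled over listeners by vowel
    """
    _check_mode(mode)
    cells = counts_from_responses(responses)
    by_key: dict[tuple[str, str], dict[int, SdtCellCounts]] = {}
    for c in cells:
        by_key.setdefault((c.listener, c.vowel), {})[c.delta] = c

    rows = []
    for (listener, vowel), deltas in sorted(by_key.items()):
        if 0 not in deltas:
            continue  # no noise trials: k is unanchored for this cell
        _, f = correct_rates(deltas[0])
        k = estimate_criterion(f)
        signal = deltas.get(2)
        if signal is None:
            rows.append(SdtEstimate(listener, vowel, k, np.nan, np.nan,
                                    np.nan, f))
            continue
        h, _ = correct_rates(signal)
        d = solve_dprime(h, k, mode)
        rows.append(SdtEstimate(listener, vowel, k, d, ln_beta(d, k), h, f))

    per_listener = pd.DataFrame([vars(r) for r in rows])

    listener_mean = (per_listener
                     .groupby("vowel")[["k", "dprime", "ln_beta_d",
                                        "h_rate", "f_rate"]]
                     .mean().reset_index())
    listener_mean.insert(1, "aggregation", "listener_mean")

    pooled_rows = []
    for vowel in sorted({c.vowel for c in cells}):
        noise = [c for c in cells if c.vowel == vowel and c.delta == 0]
        sig = [c for c in cells if c.vowel == vowel and c.delta == 2]
        if not noise or not sig:
            continue
        pooled_noise = SdtCellCounts(
            "pooled", vowel, 0,
            false_alarms=sum(c.false_alarms for c in noise),
            correct_rejections=sum(c.correct_rejections for c in noise))
        pooled_sig = SdtCellCounts(
            "pooled", vowel, 2,
            hits=sum(c.hits for c in sig),
            misses=sum(c.misses for c in sig))
        _, f = correct_rates(pooled_noise)
        h, _ = correct_rates(pooled_sig)
        k = estimate_criterion(f)
        d = solve_dprime(h, k, mode)
        pooled_rows.append({"vowel": vowel, "aggregation": "pooled_rates",
                            "k": k, "dprime": d, "ln_beta_d": ln_beta(d, k),
                            "h_rate": h, "f_rate": f})
    pooled = pd.DataFrame(pooled_rows)

    return {"per_listener": per_listener, "listener_mean": listener_mean,
            "pooled": pooled}


def bootstrap_ci(per_listener: pd.DataFrame, b: int = 10_000,
                 seed: int = 0, level: float = 0.95) -> pd.DataFrame:
    """Percentile bootstrap CIs over listeners for k, d' and ln beta_d.

    Listeners (not trials) are resampled with replacement within each vowel;
    the statistic is the listener mean of each index.
    """
    if b < 1:
        raise ValueError("bootstrap replicate count must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    out = []
    for vowel, grp in per_listener.groupby("vowel", sort=True):
        vals = grp[["k", "dprime", "ln_beta_d"]].to_numpy()
        n = len(vals)
        if n < 2:
            raise ValueError(
                f"bootstrap needs >= 2 listeners, vowel {vowel!r} has {n}")
        idx = rng.integers(0, n, size=(b, n))
        means = np.nanmean(vals[idx], axis=1)  # (b, 3)
        lo = np.percentile(means, 100 * alpha, axis=0)
        hi = np.percentile(means, 100 * (1 - alpha), axis=0)
        for j, index_name in enumerate(["k", "dprime", "ln_beta_d"]):
            out.append({"vowel": vowel, "index": index_name,
                        "mean": float(np.nanmean(vals[:, j])),
                        "ci_low": float(lo[j]), "ci_high": float(hi[j]),
                        "n_listeners": n, "n_boot": b})
    return pd.DataFrame(out)
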