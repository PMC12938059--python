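"""Descriptive behavioral analyses: identification and discrimination-accuracy
curves with Wilson 95% CIs, and the reaction-time preprocessing pipeline
(absolute bounds, then per-listener +/-3 MAD trimming on log-RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

WILSON_Z_LEVEL = 0.95  # two-sided; z = 1.959964

RT_LOWER_S = 0.1
RT_UPPER_S = 3.0
MAD_MULT = 3.0


def _wilson_table(grouped) -> pd.DataFrame:
    rows = []
    for keys, (successes, n) in grouped.items():
        if n == 0:
            continue
        lo, hi = proportion_confint(successes, n, alpha=1 - WILSON_Z_LEVEL,
                                    method="wilson")
        rows.append((*keys, successes / n, float(lo), float(hi), n))
    return rows


def identification_curve(responses: pd.DataFrame) -> pd.DataFrame:
    """Proportion of /l/ responses with Wilson CIs per vowel x step."""
    df = responses.dropna(subset=["response"])
    if df.empty:
        raise ValueError("no identification responses to summarize")
    grouped = {}
    for (vowel, step), cell in df.groupby(["vowel", "step"], sort=True):
        grouped[(vowel, step)] = ((cell["response"] == "l").sum(), len(cell))
    rows = _wilson_table(grouped)
    return pd.DataFrame(rows, columns=["vowel", "step", "prop_l",
                                       "ci_low", "ci_high", "n"])


def accuracy_curve(responses: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct on Delta=2 "different" pairs per vowel x midpoint.

    The pair midpoint (a_step + x_step)/2 locates each two-step pair on the
    continuum; for the 0..6 step range the midpoints are 1..5.
    """
    df = responses.dropna(subset=["response"])
    df = df[df["delta"] == 2].copy()
    if df.empty:
        raise ValueError("no delta=2 trials to summarize")
    df["midpoint"] = (df["a_step"] + df["x_step"]) / 2.0
    grouped = {}
    for (vowel, mid), cell in df.groupby(["vowel", "midpoint"], sort=True):
        grouped[(vowel, mid)] = (cell["correct"].sum(), len(cell))
    rows = _wilson_table(grouped)
    return pd.DataFrame(rows, columns=["vowel", "midpoint", "prop_correct",
                                       "ci_low", "ci_high", "n"])


@dataclass
class TrimReport:
    """Stage-by-stage accounting of RT preprocessing removals."""

    n_input: int
    n_missing: int
    n_out_of_bounds: int
    n_mad_trimmed: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_input if self.n_input else 0.0

    def summary(self) -> str:
        return (f"{self.n_input} trials in; removed {self.n_missing} missing, "
                f"{self.n_out_of_bounds} outside bounds, "
                f"{self.n_mad_trimmed} MAD-trimmed; "
                f"{self.n_retained} retained ({self.pct_removed:.2f}% trimmed)")


def preprocess_rt(responses: pd.DataFrame,
                  lower_s: float = RT_LOWER_S,
                  upper_s: float = RT_UPPER_S,
                  mad_mult: float = MAD_MULT,
                  correct_only: bool = False,
                  frozen_stats: pd.DataFrame | None = None,
                  ) -> tuple[pd.DataFrame, TrimReport]:
    """RT outlier pipeline: drop missing, apply absolute bounds, then trim
    per-listener beyond median +/- mad_mult * MAD on log-RT.

    The MAD here is the raw median absolute deviation (no 1.4826 consistency
    constant).  Per-listener statistics are computed on the bounds-filtered
    data; passing `frozen_stats` (columns listener, median_log, mad_log, as
    returned in `report_stats` attribute) reuses statistics from an earlier
    pass, under which the operation is idempotent.  Output preserves input
    row order.
    """
    if responses.empty:
        raise ValueError("empty response table")
    df = responses
    if correct_only:
        df = df[df["correct"].fillna(False)]
    n_input = len(df)

    missing = df["rt_s"].isna()
    df1 = df[~missing]

    oob = (df1["rt_s"] < lower_s) | (df1["rt_s"] > upper_s)
    df2 = df1[~oob]

    log_rt = np.log(df2["rt_s"])
    if frozen_stats is None:
        med = log_rt.groupby(df2["listener"]).median()
        mad = (log_rt - df2["listener"].map(med)).abs() \
            .groupby(df2["listener"]).median()
        stats = pd.DataFrame({"median_log": med, "mad_log": mad})
    else:
        stats = frozen_stats
    dev = (log_rt - df2["listener"].map(stats["median_log"])).abs()
    cut = df2["listener"].map(stats["mad_log"]) * mad_mult
    trimmed = dev > cut
    df3 = df2[~trimmed]

    report = TrimReport(n_input=n_input,
                        n_missing=int(missing.sum()),
                        n_out_of_bounds=int(oob.sum()),
                        n_mad_trimmed=int(trimmed.sum()),
                        n_retained=len(df3))
    out = df3.copy()
    out.attrs["trim_stats"] = stats
    return out, report


def retention_summary(responses: pd.DataFrame) -> dict:
    """Timeout/retention accounting for a response table.

    A timeout is a trial with no recorded response (NaN), mirroring a task
    in which the program advances after the response window elapses.
    """
    n_total = len(responses)
    n_timeout = int(responses["response"].isna().sum())
    n_valid = n_total - n_timeout
    return {"n_total": n_total, "n_valid": n_valid, "n_timeout": n_timeout,
            "pct_timeout": 100.0 * n_timeout / n_total if n_total else 0.0}
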