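"""Acoustic cue measures for nasal-lateral contrasts.

Three measures, computed on segmented CV tokens:

* **relative RMS** -- dB difference between the consonant and vowel
  intervals over their full durations (default order: vowel minus
  consonant, configurable, recorded in the output);
* **delta-A1** -- change in the first-formant spectral-peak level from
  20 ms before to 20 ms after the consonant-vowel boundary; nasal onsets
  attenuate oral F1 energy, so the post-boundary jump is large;
* **BW1** -- first-formant bandwidth from Burg LPC analysis at 5, 10, 15
  and 20 ms after vowel onset, averaged over probes; nasal coupling adds
  losses that widen F1.

A1 uses a 25 ms Hann-windowed FFT and picks the peak level in a 250-1200 Hz
search band.  Burg analysis decimates to 11025 Hz, pre-emphasizes (0.97),
fits an order-12 AR model in a 25 ms Hann window, converts AR roots to
(frequency, bandwidth) pairs, and takes the lowest-frequency candidate in
the search band.  Bandwidth estimates from short windows of voiced signals
carry substantial variance; the probe average tempers but does not remove
it, so single-token BW1 values should be read as rough (tens of Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.regression.linear_model import burg

from .tokens import CONSONANT, VOWEL, SegmentedToken, rms

F1_BAND = (250.0, 1200.0)
A1_WINDOW_MS = 25.0
A1_OFFSET_MS = 20.0
BW1_PROBES_MS = (5.0, 10.0, 15.0, 20.0)
BURG_FS = 11_025.0
BURG_ORDER = 12
BURG_PREEMPH = 0.97
BW_CANDIDATE_MAX = 1500.0


class SilentIntervalError(ValueError):
    pass


class EstimationFailure(RuntimeError):
    pass


@dataclass
class AcousticProfile:
    """One token's cue battery (durations in ms, levels in dB, BW1 in Hz)."""

    c_duration: float
    v_duration: float
    relative_rms: float
    delta_a1: float
    bw1: float
    rms_order: str = "vowel_minus_consonant"


def measure_relative_rms(token: SegmentedToken,
                         order: str = "vowel_minus_consonant") -> float:
    """Signed dB RMS difference between the C and V intervals."""
    c = token.slice(CONSONANT)
    v = token.slice(VOWEL)
    rc, rv = rms(c), rms(v)
    if rc == 0.0 or rv == 0.0:
        raise SilentIntervalError("consonant or vowel interval is silent")
    diff = 20.0 * np.log10(rv / rc)
    if order == "vowel_minus_consonant":
        return float(diff)
    if order == "consonant_minus_vowel":
        return float(-diff)
    raise ValueError(f"unknown RMS order convention {order!r}")


def _a1_db(x: np.ndarray, fs: float, center: int,
           band: tuple[float, float] = F1_BAND,
           win_ms: float = A1_WINDOW_MS) -> float:
    half = int(round(win_ms / 2000.0 * fs))
    lo, hi = center - half, center + half
    if lo < 0 or hi > len(x):
        raise ValueError("analysis window extends beyond the signal")
    seg = x[lo:hi] * np.hanning(hi - lo)
    spec = np.abs(np.fft.rfft(seg, n=8192))
    freqs = np.fft.rfftfreq(8192, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(20.0 * np.log10(max(spec[sel].max(), 1e-12)))


def measure_delta_a1(token: SegmentedToken,
                     offset_ms: float = A1_OFFSET_MS,
                     band: tuple[float, float] = F1_BAND) -> float:
    """A1(boundary + offset) - A1(boundary - offset) in dB."""
    fs = token.fs
    boundary = int(round(token.cv_boundary * fs))
    offset = int(round(offset_ms / 1000.0 * fs))
    half = int(round(A1_WINDOW_MS / 2000.0 * fs))
    c_start, _ = token.sample_range(CONSONANT)
    _, v_end = token.sample_range(VOWEL)
    if boundary - offset - half < c_start or boundary + offset + half > v_end:
        raise ValueError("offset window extends into silence")
    before = _a1_db(token.samples, fs, boundary - offset, band)
    after = _a1_db(token.samples, fs, boundary + offset, band)
    return after - before


def _burg_f1(seg: np.ndarray, fs: float,
             band: tuple[float, float]) -> tuple[float, float] | None:
    seg = seg - seg.mean()
    if not np.any(seg):
        return None
    ar, _ = burg(seg, order=BURG_ORDER)
    roots = np.roots(np.concatenate([[1.0], -ar]))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.abs(roots)) * fs / np.pi
    sel = (freqs > band[0]) & (freqs < band[1]) & (bws > 0) & \
          (bws < BW_CANDIDATE_MAX)
    if not np.any(sel):
        return None
    i = np.argmin(freqs[sel])
    return float(freqs[sel][i]), float(bws[sel][i])


def measure_bw1(token: SegmentedToken,
                probe_times_ms: tuple[float, ...] = BW1_PROBES_MS,
                band: tuple[float, float] = F1_BAND,
                win_ms: float = A1_WINDOW_MS) -> float:
    """Mean F1 bandwidth (Hz) from Burg analysis at probes after vowel onset.

    Probes whose analysis fails (no in-band pole) are dropped with a
    warning; if every probe fails an :class:`EstimationFailure` is raised.
    """
    fs = token.fs
    v_start, v_end = token.sample_range(VOWEL)
    dec = int(round(fs / BURG_FS))
    fsd = fs / dec
    x = signal.decimate(token.samples, dec, ftype="fir")
    x = signal.lfilter([1.0, -BURG_PREEMPH], [1.0], x)
    half = int(round(win_ms / 2000.0 * fsd))

    # analysis windows start at the probe and extend rightward so they lie
    # wholly inside the vowel; a centered window at a 5 ms probe would reach
    # 7.5 ms back into the consonant, whose deliberately different F1
    # structure contaminates the fit
    estimates = []
    for probe_ms in probe_times_ms:
        start_full = v_start + probe_ms / 1000.0 * fs
        if start_full + 2 * half * dec > v_end:
            raise ValueError(f"probe {probe_ms} ms window exceeds the vowel")
        c = int(round(start_full / dec))
        seg = x[c:c + 2 * half]
        got = _burg_f1(seg * np.hanning(len(seg)), fsd, band)
        if got is None:
            warnings.warn(f"no F1 candidate at probe {probe_ms} ms",
                          stacklevel=2)
            continue
        estimates.append(got[1])
    if not estimates:
        raise EstimationFailure("Burg analysis found no F1 at any probe")
    return float(np.mean(estimates))


def measure_profile(token: SegmentedToken,
                    rms_order: str = "vowel_minus_consonant"
                    ) -> AcousticProfile:
    c = token.interval(CONSONANT)
    v = token.interval(VOWEL)
    return AcousticProfile(
        c_duration=c.duration * 1000.0,
        v_duration=v.duration * 1000.0,
        relative_rms=measure_relative_rms(token, order=rms_order),
        delta_a1=measure_delta_a1(token),
        bw1=measure_bw1(token),
        rms_order=rms_order,
    )


def profile_continuum(continuum, rms_order: str = "vowel_minus_consonant"
                      ) -> pd.DataFrame:
    """Cue battery for every step of a continuum, one row per step."""
    rows = []
    for step, token in enumerate(continuum.tokens):
        prof = measure_profile(token, rms_order=rms_order)
        rows.append({"vowel": continuum.vowel_context, "step": step,
                     **vars(prof)})
    return pd.DataFrame(rows)
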