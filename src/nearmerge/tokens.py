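"""Segmented CV tokens: a waveform plus silence/consonant/vowel interval labels.

A :class:`SegmentedToken` is the unit every stage of the pipeline passes
around: synthesis emits one, morphing consumes and produces them, and the
acoustic measures address their consonant (``C``) and vowel (``V``) intervals
by label.  Interval times are seconds from the start of the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SIL = "sil"
CONSONANT = "C"
VOWEL = "V"


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SegmentedToken:
    """A sampled waveform with labelled sil/C/V/sil intervals.

    Parameters
    ----------
    samples : float array, full-scale normalized (|x| <= 1 by convention).
    fs : sampling rate in samples/s.
    intervals : contiguous, non-overlapping intervals covering the waveform.
    meta : free-form provenance (category, vowel context, synthesis spec...).
    """

    samples: np.ndarray
    fs: int
    intervals: list[Interval]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("token waveform must be mono (1-D)")
        prev_end = 0.0
        for iv in self.intervals:
            if iv.start < prev_end - 1e-9:
                raise ValueError(f"overlapping intervals at {iv.start:.6f}s")
            if iv.end <= iv.start:
                raise ValueError(f"empty interval {iv.label!r} at {iv.start:.6f}s")
            prev_end = iv.end

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def interval(self, label: str) -> Interval:
        """First interval carrying `label` (C and V occur exactly once)."""
        for iv in self.intervals:
            if iv.label == label:
                return iv
        raise KeyError(f"token has no interval labelled {label!r}")

    def slice(self, label: str) -> np.ndarray:
        iv = self.interval(label)
        i0 = int(round(iv.start * self.fs))
        i1 = int(round(iv.end * self.fs))
        return self.samples[i0:i1]

    def sample_range(self, label: str) -> tuple[int, int]:
        iv = self.interval(label)
        return int(round(iv.start * self.fs)), int(round(iv.end * self.fs))

    @property
    def cv_boundary(self) -> float:
        """Consonant-vowel boundary time in seconds."""
        return self.interval(CONSONANT).end

    def with_samples(self, samples: np.ndarray) -> "SegmentedToken":
        """Copy of this token with a replaced waveform of identical length."""
        if len(samples) != len(self.samples):
            raise ValueError("replacement waveform must preserve sample count")
        return SegmentedToken(np.asarray(samples, float), self.fs,
                              list(self.intervals), dict(self.meta))

    def scaled(self, factor: float) -> "SegmentedToken":
        return self.with_samples(self.samples * factor)


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty signal has no RMS")
    return float(np.sqrt(np.mean(np.square(x))))


def db_rms(x: np.ndarray, ref: float = 2e-5) -> float:
    """RMS level in dB re `ref` (Praat-style SPL convention on full-scale floats)."""
    r = rms(x)
    if r == 0.0:
        raise ValueError("silent signal has no dB level")
    return 20.0 * np.log10(r / ref)


def make_intervals(sil_lead: float, c_dur: float, v_dur: float,
                   sil_trail: float) -> list[Interval]:
    """Standard sil/C/V/sil segmentation from durations in seconds."""
    t0 = sil_lead
    t1 = t0 + c_dur
    t2 = t1 + v_dur
    return [
        Interval(0.0, t0, SIL),
        Interval(t0, t1, CONSONANT),
        Interval(t1, t2, VOWEL),
        Interval(t2, t2 + sil_trail, SIL),
    ]
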