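"""Synthetic /n/-like and /l/-like CV endpoint tokens.

Source-filter synthesis stands in for the recorded endpoint syllables: a
monotone impulse-train voice source (with a first-order spectral tilt and a
small aspiration-noise component) drives a cascade of second-order formant
resonators.  The three cue dimensions that distinguish nasal from lateral
onsets are imposed with known ground truth:

* consonant RMS relative to the vowel (``consonant_gain_db``), calibrated
  to within a fraction of a dB by direct scaling;
* attenuation of first-formant energy in the consonant relative to the
  early vowel (``a1_attenuation_db``), imposed by shaping the consonant's
  250-1200 Hz band in the frequency domain and calibrated iteratively
  against the same spectral-peak measure the analysis module uses;
* first-formant bandwidth in the vowel (``formant_bandwidths[0]``), wider
  for nasal tokens (nasal coupling adds losses), realized directly by the
  F1 resonator.

A nasal murmur resonance (200 Hz) is added to the consonant of nasal
tokens.  `make_endpoint_pair` synthesizes both categories from the *same*
source excitation so the pair differs only in the specified cues.

Tokens carry 50 ms leading/trailing silence, per-context total speech
durations of 400 ms (/a/) and 500 ms (/i/), and a sil/C/V/sil segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .tokens import SegmentedToken, make_intervals, rms

FS_DEFAULT = 44_100
SILENCE_S = 0.050
SPEECH_TARGET_MS = {"a": 400.0, "i": 500.0}
MIN_CONSONANT_MS = 70.0

SOURCE_TILT = -0.9         # first-order zero of the glottal-ish source
ASPIRATION_DB = -5.0       # noise level re source RMS (breathy female voice)
MURMUR_HZ = 120.0
MURMUR_BW = 60.0
MURMUR_DB = -12.0          # murmur RMS re consonant RMS
F1_BAND = (250.0, 1200.0)   # band searched by the A1 peak measure
SHAPE_BAND = (100.0, 1400.0)  # synthesis-side attenuation band: extends past
                              # the measurement band on both sides so
                              # near-edge components cannot leak into the
                              # A1 search through the analysis window
CROSSFADE_MS = 5.0

VOWEL_FORMANTS = {"i": (310.0, 2400.0, 3100.0),
                  "a": (850.0, 1400.0, 2800.0)}
UPPER_BANDWIDTHS = (120.0, 150.0)
F0_DEFAULT = 200.0


class InvalidSpecError(ValueError):
    pass


class DegeneratePairError(ValueError):
    pass


@dataclass
class EndpointSpec:
    vowel_context: str
    category: str                      # "nasal" | "lateral"
    f0: float = F0_DEFAULT
    formant_freqs: tuple[float, ...] = ()
    formant_bandwidths: tuple[float, ...] = ()
    consonant_gain_db: float = -12.0   # consonant RMS re vowel RMS
    a1_attenuation_db: float = 20.0    # target delta-A1 across the boundary
    consonant_duration: float = 75.0   # ms
    vowel_duration: float = 425.0      # ms
    fs: int = FS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vowel_context not in SPEECH_TARGET_MS:
            raise InvalidSpecError(
                f"unknown vowel context {self.vowel_context!r}")
        if self.category not in ("nasal", "lateral"):
            raise InvalidSpecError(f"unknown category {self.category!r}")
        if not self.formant_freqs:
            self.formant_freqs = VOWEL_FORMANTS[self.vowel_context]
        if not self.formant_bandwidths:
            self.formant_bandwidths = (100.0,) + UPPER_BANDWIDTHS
        if len(self.formant_bandwidths) != len(self.formant_freqs):
            raise InvalidSpecError("formant frequency/bandwidth length mismatch")
        if self.consonant_duration < MIN_CONSONANT_MS:
            raise InvalidSpecError(
                f"consonant must be >= {MIN_CONSONANT_MS:.0f} ms")
        if self.vowel_duration <= 0 or self.consonant_duration <= 0:
            raise InvalidSpecError("durations must be positive")
        total = self.consonant_duration + self.vowel_duration
        target = SPEECH_TARGET_MS[self.vowel_context]
        if abs(total - target) > 0.5:
            raise InvalidSpecError(
                f"C+V duration {total:.1f} ms must equal the "
                f"{target:.0f} ms target for /{self.vowel_context}/")
        nyquist = self.fs / 2.0
        for f in self.formant_freqs:
            if f >= nyquist:
                raise InvalidSpecError(f"formant {f:.0f} Hz above Nyquist")
        for bw in self.formant_bandwidths:
            if bw <= 0:
                raise InvalidSpecError("bandwidths must be positive")


def _resonator_sos(freq: float, bw: float, fs: float) -> np.ndarray:
    """Second-order resonator section with unit DC gain."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a1, a2 = -2.0 * r * np.cos(theta), r * r
    b0 = 1.0 + a1 + a2
    return np.array([[b0, 0.0, 0.0, 1.0, a1, a2]])


def _cascade(freqs, bws, fs) -> np.ndarray:
    return np.vstack([_resonator_sos(f, b, fs) for f, b in zip(freqs, bws)])


def make_source(n: int, f0: float, fs: float, seed: int) -> np.ndarray:
    """Tilted impulse-train voice source with aspiration noise."""
    rng = np.random.default_rng(seed)
    src = np.zeros(n)
    period = fs / f0
    t = 0.0
    while t < n:
        src[int(t)] = 1.0
        t += period
    src = signal.lfilter([1.0, SOURCE_TILT], [1.0], src)
    noise = rng.standard_normal(n)
    src = src + 10.0 ** (ASPIRATION_DB / 20.0) * rms(src) * noise
    return src


def _band_gain(x: np.ndarray, fs: float, band: tuple[float, float],
               gain_db: float, edge_hz: float = 80.0) -> np.ndarray:
    """Scale the amplitude of `band` in the spectrum of x by gain_db.

    The raised-cosine transition regions lie *outside* the band so the
    requested gain applies uniformly across the whole band (the band is
    also the A1 peak-search region, so partial attenuation inside it would
    leave a spurious residual peak)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    g = 10.0 ** (gain_db / 20.0)
    mask = np.ones_like(freqs)
    lo, hi = band
    mask[(freqs >= lo) & (freqs <= hi)] = g
    for e0, e1, rising in ((lo - edge_hz, lo, True), (hi, hi + edge_hz, False)):
        edge = (freqs > e0) & (freqs < e1)
        t = (freqs[edge] - e0) / (e1 - e0)
        w = 0.5 - 0.5 * np.cos(np.pi * t)
        mask[edge] = 1.0 + (g - 1.0) * (w if rising else 1.0 - w)
    return np.fft.irfft(spec * mask, n=len(x))


def _a1_db(x: np.ndarray, fs: float, center: int,
           band: tuple[float, float] = F1_BAND, win_ms: float = 25.0) -> float:
    """Spectral-peak level (dB) in the F1 band of a Hann window at `center`.

    Mirrors the analysis-side A1 measure so synthesis calibration and
    measurement agree by construction.
    """
    half = int(round(win_ms / 2000.0 * fs))
    seg = x[max(0, center - half):center + half]
    seg = seg * np.hanning(len(seg))
    spec = np.abs(np.fft.rfft(seg, n=8192))
    freqs = np.fft.rfftfreq(8192, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    peak = spec[sel].max()
    return 20.0 * np.log10(max(peak, 1e-12))


def synth_endpoint(spec: EndpointSpec,
                   source: np.ndarray | None = None) -> SegmentedToken:
    """Synthesize one segmented CV endpoint token from its spec.

    Deterministic given the seed; a pre-built `source` (from `make_source`)
    may be supplied so two category variants share one excitation.
    """
    fs = spec.fs
    c_n = int(round(spec.consonant_duration / 1000.0 * fs))
    v_n = int(round(spec.vowel_duration / 1000.0 * fs))
    n = c_n + v_n
    if source is None:
        source = make_source(n, spec.f0, fs, spec.seed)
    elif len(source) < n:
        raise InvalidSpecError("provided source shorter than the token")

    cascade = _cascade(spec.formant_freqs, spec.formant_bandwidths, fs)
    filtered = signal.sosfilt(cascade, source[:n])
    vowel = filtered[c_n:]
    consonant = filtered[:c_n].copy()

    if spec.category == "nasal":
        murmur = signal.sosfilt(_resonator_sos(MURMUR_HZ, MURMUR_BW, fs),
                                source[:c_n])
        # remove the resonance skirt above the A1 search band's lower edge
        # so the murmur cannot set a floor on the realized A1 attenuation
        murmur = _band_gain(murmur, fs, (F1_BAND[0], 4000.0), -80.0)
        murmur *= 10.0 ** (MURMUR_DB / 20.0) * rms(consonant) / rms(murmur)
    else:
        murmur = 0.0

    # calibrate the F1-band shaping so the realized boundary A1 drop matches
    # the spec; the overall RMS rescale interacts with the band gain, so a
    # few fixed-point iterations are used
    offset = int(round(0.020 * fs))
    a1_after = _a1_db(vowel, fs, offset)
    gain_db = -spec.a1_attenuation_db
    shaped = consonant
    for _ in range(4):
        shaped = _band_gain(consonant, fs, SHAPE_BAND, gain_db) + murmur
        shaped *= 10.0 ** (spec.consonant_gain_db / 20.0) * rms(vowel) / rms(shaped)
        a1_before = _a1_db(shaped, fs, c_n - offset)
        realized = a1_after - a1_before
        gain_db += realized - spec.a1_attenuation_db
    consonant = shaped

    speech = np.concatenate([consonant, vowel])
    # short onset/offset ramps keep the token click-free at the silences
    xf = int(round(CROSSFADE_MS / 1000.0 * fs))
    if xf > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(xf) / xf)
        speech[:xf] *= ramp
        speech[-xf:] *= ramp[::-1]

    sil = np.zeros(int(round(SILENCE_S * fs)))
    wave = np.concatenate([sil, speech, sil])
    wave = 0.9 * wave / np.max(np.abs(wave))

    intervals = make_intervals(SILENCE_S, c_n / fs, v_n / fs, SILENCE_S)
    meta = {"category": spec.category, "vowel_context": spec.vowel_context,
            "f0": spec.f0, "seed": spec.seed,
            "true_bw1_hz": spec.formant_bandwidths[0],
            "target_relative_rms_db": -spec.consonant_gain_db,
            "target_delta_a1_db": spec.a1_attenuation_db}
    return SegmentedToken(wave, fs, intervals, meta)


@dataclass
class CueGapSpec:
    """Nasal/lateral cue values as (nasal, lateral) pairs.

    Defaults mirror the qualitative per-context cue structure of the
    measured continua: large, well-separated amplitude cues for /i/;
    compressed and direction-reversed amplitude cues for /a/."""

    consonant_gain_db: tuple[float, float]
    a1_attenuation_db: tuple[float, float]
    bw1_hz: tuple[float, float]

    def scaled(self, factor: float) -> "CueGapSpec":
        """Shrink every nasal/lateral gap about its midpoint by `factor`."""
        def shrink(pair):
            mid = (pair[0] + pair[1]) / 2.0
            return (mid + (pair[0] - mid) * factor,
                    mid + (pair[1] - mid) * factor)
        return CueGapSpec(shrink(self.consonant_gain_db),
                          shrink(self.a1_attenuation_db),
                          shrink(self.bw1_hz))

    def is_degenerate(self) -> bool:
        return all(abs(p[0] - p[1]) < 1e-9 for p in
                   (self.consonant_gain_db, self.a1_attenuation_db,
                    self.bw1_hz))


CUE_GAP_DEFAULTS = {
    "i": CueGapSpec(consonant_gain_db=(-17.5, -11.0),
                    a1_attenuation_db=(45.0, 34.0),
                    bw1_hz=(220.0, 100.0)),
    "a": CueGapSpec(consonant_gain_db=(-7.5, -9.5),
                    a1_attenuation_db=(2.5, 6.0),
                    bw1_hz=(180.0, 110.0)),
}

CONSONANT_MS_DEFAULT = {"i": 77.0, "a": 71.0}


def default_specs(vowel_context: str, seed: int = 0,
                  cue_gaps: CueGapSpec | None = None
                  ) -> tuple[EndpointSpec, EndpointSpec]:
    gaps = cue_gaps if cue_gaps is not None else CUE_GAP_DEFAULTS[vowel_context]
    c_ms = CONSONANT_MS_DEFAULT[vowel_context]
    v_ms = SPEECH_TARGET_MS[vowel_context] - c_ms
    specs = []
    for i, category in enumerate(("nasal", "lateral")):
        specs.append(EndpointSpec(
            vowel_context=vowel_context, category=category,
            formant_bandwidths=(gaps.bw1_hz[i],) + UPPER_BANDWIDTHS,
            consonant_gain_db=gaps.consonant_gain_db[i],
            a1_attenuation_db=gaps.a1_attenuation_db[i],
            consonant_duration=c_ms, vowel_duration=v_ms, seed=seed))
    return specs[0], specs[1]


def make_endpoint_pair(vowel_context: str,
                       cue_gap_spec: CueGapSpec | None = None,
                       seed: int = 0, gap_scale: float = 1.0,
                       strict: bool = False
                       ) -> tuple[SegmentedToken, SegmentedToken]:
    """Nasal and lateral endpoint tokens sharing durations, f0, vowel
    formant frequencies and source excitation, differing only in the
    requested cue values.

    With ``strict=True`` a fully degenerate gap specification (all cue
    gaps zero) raises :class:`DegeneratePairError`.
    """
    gaps = cue_gap_spec if cue_gap_spec is not None \
        else CUE_GAP_DEFAULTS[vowel_context]
    gaps = gaps.scaled(gap_scale)
    if strict and gaps.is_degenerate():
        raise DegeneratePairError("all cue gaps are zero")
    nasal_spec, lateral_spec = default_specs(vowel_context, seed=seed,
                                             cue_gaps=gaps)
    n = int(round((nasal_spec.consonant_duration +
                   nasal_spec.vowel_duration) / 1000.0 * nasal_spec.fs))
    source = make_source(n, nasal_spec.f0, nasal_spec.fs, seed)
    return (synth_endpoint(nasal_spec, source=source),
            synth_endpoint(lateral_spec, source=source))
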