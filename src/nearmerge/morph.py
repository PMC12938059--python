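"""Seven-step /n/->/l/ continua by STFT magnitude-envelope interpolation.

For each vowel context, the consonant-plus-early-vowel (CV) window of the
nasal and lateral endpoints is analyzed with a short-time Fourier transform
(Hann window, 1024-point FFT, 75% overlap, hop 256).  Step ``s`` of the
continuum mixes the magnitude envelopes linearly,

    alpha = s / 6,    E_step = (1 - alpha) E_n + alpha E_l,

while the phase spectrum of the *nasal* endpoint is reused at every step,
holding excitation and temporal structure constant.  The mixed spectrum is
inverted by single-pass overlap-add (no iterative phase retrieval), spliced
back into the nasal host token over the same window, peak-normalized to
0.99, and intensity-scaled to 70 dB (re 2e-5).

The nasal endpoint is pre-emphasized (coefficient 0.97) before analysis and
de-emphasized after resynthesis by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal import ShortTimeFFT, windows

from .tokens import CONSONANT, SegmentedToken, rms

N_FFT = 1024
OVERLAP = 0.75
HOP = int(N_FFT * (1.0 - OVERLAP))  # 256
PREEMPH_COEF = 0.97
N_STEPS = 7
COART_SPAN_MS = 50.0
PEAK_TARGET = 0.99
INTENSITY_TARGET_DB = 70.0
DB_REF = 2e-5


class IncompatibleStacksError(ValueError):
    pass


def preemphasize(waveform: np.ndarray, coefficient: float = PREEMPH_COEF
                 ) -> np.ndarray:
    """First-order high-pass: y[t] = x[t] - c*x[t-1], y[0] = x[0]."""
    x = np.asarray(waveform, float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if not 0.0 <= coefficient < 1.0:
        raise ValueError("pre-emphasis coefficient must lie in [0, 1)")
    y = x.copy()
    y[1:] -= coefficient * x[:-1]
    return y


def deemphasize(waveform: np.ndarray, coefficient: float = PREEMPH_COEF
                ) -> np.ndarray:
    """Inverse of :func:`preemphasize` (first-order leaky integrator)."""
    x = np.asarray(waveform, float)
    if x.size == 0:
        raise ValueError("empty waveform")
    return sps.lfilter([1.0], [1.0, -coefficient], x)


@dataclass
class SpectralFrameStack:
    """Framewise STFT magnitudes and phases with analysis metadata."""

    magnitudes: np.ndarray  # (frames, bins), >= 0
    phases: np.ndarray      # (frames, bins), radians
    fs: int
    n_fft: int = N_FFT
    hop: int = HOP
    window: str = "hann"
    n_samples: int = 0      # original signal length for exact inversion

    def __post_init__(self) -> None:
        if self.magnitudes.shape != self.phases.shape:
            raise IncompatibleStacksError("magnitude/phase shape mismatch")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.magnitudes.shape[1] != self.n_fft // 2 + 1:
            raise IncompatibleStacksError(
                f"expected {self.n_fft // 2 + 1} bins, "
                f"got {self.magnitudes.shape[1]}")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]


def _stft_op(fs: float) -> ShortTimeFFT:
    return ShortTimeFFT(windows.hann(N_FFT, sym=False), hop=HOP, fs=fs,
                        fft_mode="onesided")


def stft_analyze(waveform: np.ndarray, fs: int) -> SpectralFrameStack:
    x = np.asarray(waveform, float)
    if len(x) < N_FFT:
        raise ValueError(
            f"waveform ({len(x)} samples) shorter than one {N_FFT}-sample window")
    Z = _stft_op(fs).stft(x)  # (bins, frames)
    return SpectralFrameStack(magnitudes=np.abs(Z).T,
                              phases=np.angle(Z).T, fs=fs,
                              n_samples=len(x))


def istft_synthesize(stack: SpectralFrameStack,
                     n_samples: int | None = None) -> np.ndarray:
    """Overlap-add inversion of a (possibly modified) magnitude/phase stack."""
    Z = (stack.magnitudes * np.exp(1j * stack.phases)).T
    n = n_samples if n_samples is not None else stack.n_samples
    if n <= 0:
        raise ValueError("target sample count unknown; pass n_samples")
    return _stft_op(stack.fs).istft(Z, k1=n)


@dataclass(frozen=True)
class MorphSpec:
    """Continuum position: step index s in 0..6 and its mixing weight."""

    s: int

    def __post_init__(self) -> None:
        if not 0 <= self.s < N_STEPS:
            raise ValueError(f"step must lie in 0..{N_STEPS - 1}")

    @property
    def alpha(self) -> float:
        return self.s / (N_STEPS - 1)


def _align_frames(stack: SpectralFrameStack, n_frames: int) -> np.ndarray:
    """Map a stack's frames onto a host frame grid by nearest-frame lookup."""
    if stack.n_frames == n_frames:
        return stack.magnitudes
    src = np.round(np.linspace(0, stack.n_frames - 1, n_frames)).astype(int)
    return stack.magnitudes[src]


def interpolate_envelopes(stack_n: SpectralFrameStack,
                          stack_l: SpectralFrameStack,
                          morph: MorphSpec) -> SpectralFrameStack:
    """Linear framewise magnitude interpolation with the nasal phases."""
    for attr in ("fs", "n_fft", "hop"):
        if getattr(stack_n, attr) != getattr(stack_l, attr):
            raise IncompatibleStacksError(f"stacks differ in {attr}")
    if stack_n.magnitudes.shape[1] != stack_l.magnitudes.shape[1]:
        raise IncompatibleStacksError("stacks differ in bin count")
    mags_l = _align_frames(stack_l, stack_n.n_frames)
    alpha = morph.alpha
    mixed = (1.0 - alpha) * stack_n.magnitudes + alpha * mags_l
    return SpectralFrameStack(magnitudes=mixed,
                              phases=stack_n.phases.copy(),
                              fs=stack_n.fs, n_fft=stack_n.n_fft,
                              hop=stack_n.hop,
                              n_samples=stack_n.n_samples)


def scale_intensity(waveform: np.ndarray,
                    target_db: float = INTENSITY_TARGET_DB,
                    ref: float = DB_REF) -> np.ndarray:
    """Scale so 20 log10(RMS/ref) equals target_db."""
    x = np.asarray(waveform, float)
    r = rms(x)
    if r == 0.0:
        raise ValueError("cannot scale a silent waveform")
    return x * (ref * 10.0 ** (target_db / 20.0) / r)


@dataclass
class ContinuumSet:
    """The ordered 7-token morph series for one vowel context."""

    vowel_context: str
    tokens: list[SegmentedToken]
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.tokens) != N_STEPS:
            raise ValueError(f"continuum must hold exactly {N_STEPS} tokens")


def _cv_window(token: SegmentedToken, coart_span_ms: float) -> tuple[int, int]:
    """Sample range of the morphing window: consonant + early-vowel span."""
    c0, c1 = token.sample_range(CONSONANT)
    span = int(round(coart_span_ms / 1000.0 * token.fs))
    end = c1 + span
    if end > len(token.samples):
        raise ValueError("CV window exceeds token length")
    return c0, end


def morph_cv_window(n_token: SegmentedToken, l_token: SegmentedToken,
                    coart_span_ms: float = COART_SPAN_MS,
                    preemph: bool = True) -> list[np.ndarray]:
    """Raw morphed CV segments for s = 0..6 (before splicing/normalizing)."""
    if n_token.fs != l_token.fs:
        raise IncompatibleStacksError("endpoint sampling rates differ")
    fs = n_token.fs
    n0, n1 = _cv_window(n_token, coart_span_ms)
    l0, l1 = _cv_window(l_token, coart_span_ms)
    seg_n = n_token.samples[n0:n1]
    seg_l = l_token.samples[l0:l1]
    if preemph:
        seg_n = preemphasize(seg_n)
        seg_l = preemphasize(seg_l)
    stack_n = stft_analyze(seg_n, fs)
    stack_l = stft_analyze(seg_l, fs)
    out = []
    for s in range(N_STEPS):
        mixed = interpolate_envelopes(stack_n, stack_l, MorphSpec(s))
        y = istft_synthesize(mixed, n_samples=n1 - n0)
        if preemph:
            y = deemphasize(y)
        out.append(y)
    return out


def build_continuum(n_token: SegmentedToken, l_token: SegmentedToken,
                    coart_span_ms: float = COART_SPAN_MS,
                    preemph: bool = True,
                    peak_target: float = PEAK_TARGET,
                    intensity_db: float = INTENSITY_TARGET_DB,
                    normalize: bool = True) -> ContinuumSet:
    """Morph, splice into the nasal host, and normalize the 7-step series.

    Order of operations per emitted token: splice -> peak-normalize to
    `peak_target` -> scale average intensity to `intensity_db` re 2e-5.
    Set ``normalize=False`` to keep raw spliced waveforms (used by
    spectral-linearity checks).
    """
    segments = morph_cv_window(n_token, l_token, coart_span_ms, preemph)
    n0, n1 = _cv_window(n_token, coart_span_ms)
    tokens = []
    for s, seg in enumerate(segments):
        wave = n_token.samples.copy()
        wave[n0:n1] = seg
        if normalize:
            wave = wave * (peak_target / np.max(np.abs(wave)))
            wave = scale_intensity(wave, intensity_db)
        tok = SegmentedToken(wave, n_token.fs, list(n_token.intervals),
                             {**n_token.meta, "step": s,
                              "alpha": MorphSpec(s).alpha})
        tokens.append(tok)
    provenance = {"vowel_context": n_token.meta.get("vowel_context", "?"),
                  "coart_span_ms": coart_span_ms, "preemph": preemph,
                  "n_meta": dict(n_token.meta), "l_meta": dict(l_token.meta)}
    return ContinuumSet(vowel_context=provenance["vowel_context"],
                        tokens=tokens, provenance=provenance)
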