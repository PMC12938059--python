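# Methods

This note records the models, parameter choices, and numerical conventions
behind the package, and what the synthetic-data pipeline does and does not
establish about real listeners.

## Endpoint synthesis

Endpoints are source-filter syntheses, not recordings.  The voice source is
a monotone impulse train (f0 = 200 Hz, a plausible female fundamental) with
a first-order spectral-tilt zero (coefficient 0.9) and Gaussian aspiration
noise at −5 dB relative to the pulse-train RMS — a deliberately breathy
setting.  The noise level matters for analysis, not realism: first-formant
bandwidth estimates from linear prediction are only well behaved when the
excitation has a broadband stochastic component; with near-pure periodic
excitation, short-window Burg bandwidths are dominated by harmonic-capture
artifacts (errors of ±50–500 % in our calibration experiments).  The vowel
filter is a cascade of three second-order resonators (per-context formant
frequencies: /i/ 310/2400/3100 Hz, /a/ 850/1400/2800 Hz).

Three cues are imposed with known ground truth:

* **relative RMS** — the consonant is rescaled so its RMS sits at
  `consonant_gain_db` relative to the vowel; exact up to the later
  F1-band shaping, realized within ±1 dB.
* **ΔA1** — the consonant's 100–1400 Hz band is attenuated in the
  frequency domain; the attenuation is calibrated in a 4-iteration fixed
  point against the same windowed spectral-peak measure the analysis side
  uses.  The shaping band deliberately overhangs the 250–1200 Hz A1
  search band on both sides: partially attenuated transition regions or
  near-edge source harmonics otherwise leak through the 25 ms analysis
  window's skirts and cap the realizable attenuation (observed caps of
  ~13–20 dB before the overhang was added).  The nasal murmur (resonance
  at 120 Hz, bandwidth 60 Hz, −12 dB re consonant RMS) is cleaned of its
  own above-250 Hz skirt for the same reason.
* **BW1** — the vowel's F1 resonator bandwidth is set directly
  (nasal wide, lateral narrow), standing in for nasal-coupling losses.

`make_endpoint_pair` synthesizes both categories from one shared source
realization, so the pair differs only in the imposed cues and the
measurement errors of the two tokens are strongly correlated.  This is what
makes the cue-ordering contract (measured orderings follow the requested
gap signs) hold on every seed of a 20-seed sweep despite the irreducible
variance of bandwidth estimation.

Per-context defaults mirror the measured continua qualitatively: /i/ gets
large, well-separated amplitude cues (relative RMS 17.5 vs 11 dB, ΔA1 45
vs 34 dB), /a/ gets compressed cues with the direction of the amplitude
measures *reversed* (7.5 vs 9.5 dB, 2.5 vs 6 dB), as in the reference
acoustic battery for that context.  BW1 defaults keep the nasal-wider
ordering in both contexts.  Speech durations are 400 ms (/a/) and 500 ms
(/i/) plus 50 ms edge silences; consonants ≥ 70 ms.

## Morphing

The CV window (consonant plus a 50 ms early-vowel coarticulation span) is
pre-emphasized (0.97), analyzed with `scipy.signal.ShortTimeFFT` (Hann
1024, hop 256), magnitude-interpolated at α = s/6 with the nasal phases,
inverted by single-pass overlap-add, de-emphasized (matching inverse of
the pre-emphasis; a flag disables it), and spliced back into the nasal
host.  Emission order is splice → peak-normalize to 0.99 → scale average
intensity to 70 dB re 2×10⁻⁵ (RMS over the whole file, silences included).
Step 0 therefore reproduces the nasal endpoint bit-for-bit before
normalization; step-6 and step-3 spectra match the lateral analysis and
the endpoint mean to within the analysis–resynthesis projection error
(≲ 0.5 % Frobenius; the mixed spectrogram is not exactly consistent, so
re-analysis of the output is a projection, not an identity).  When the two
endpoints' frame counts differ, the lateral stack is mapped onto the nasal
frame grid by nearest-frame lookup; the nasal grid hosts because its phase
is reused.

## Acoustic measures

A1 is the peak level in 250–1200 Hz of a 25 ms Hann-windowed FFT; ΔA1 uses
windows centered 20 ms either side of the CV boundary.  BW1 decimates to
11,025 Hz, pre-emphasizes (0.97), fits an order-12 Burg AR model
(`statsmodels`) in 25 ms windows, converts roots to (frequency, bandwidth)
pairs, takes the lowest-frequency in-band pole, and averages over the
probes.  Probe windows start *at* the probe time and extend rightward so
they remain inside the vowel — a centered window at the 5 ms probe would
reach 7.5 ms into the consonant, whose deliberately different F1 structure
contaminates the fit.  Windowed, pre-emphasized Burg bandwidths carry both
variance (~±30 % per 25 ms window even under favorable excitation) and a
signal-dependent bias (≈ −25 % on noise-excited resonators); the probe
average tempers the variance only.  Tests therefore treat single-token
BW1 values as rough, and calibration checks average over spread-out,
independent probe windows.  The relative-RMS subtraction order is
configurable (default vowel − consonant) and recorded in every output row,
since the positive printed values in the reference battery are not
reconcilable with a single fixed order across both contexts.

## Task design

AX: per vowel block (always /i/ then /a/), 6 repetitions × (10 same +
10 different pairs), the different pairs being the five 2-step pairs in
both orders; 240 trials total, ISI 750 ms, ITI 550 ms.  Ten same pairs
cannot be filled evenly from seven steps; the default adds one extra
repetition of steps {0, 3, 6} to the seven identity pairs (configurable) —
chosen to cover the continuum with near-uniform frequency.
Identification: 7 steps × 6 reps × 2 left–right choice orders × 2 vowels =
168 trials.  "Pseudorandomized" is implemented as a uniform seeded shuffle
within block, with no adjacency constraints.  Practice blocks use a 3-step
VOT series (13/47/87 ms): 16 AX trials covering AA/BB/AB/BA and 12
identification trials.

## Observer simulation

AX responses are Bernoulli draws from the same F/H equations the estimator
inverts, which makes recovery tests sharp: discrepancies indicate
estimator defects, not model mismatch.  A latent-variable mode that
actually differences two unit-variance observations (respond "different"
iff |X_A − X_X| > k) is provided as a cross-check; it is distributionally
identical to the `standard` equation set.  Group defaults are the pooled
study values (d′: /i/ 1.03, /a/ 0.45; k: /i/ 1.87, /a/ 2.13); cohort
simulation optionally adds normal between-listener jitter (default SD 0.3
on both indices, truncated to valid ranges).  Identification uses a
guess/lapse logistic in step units — steep for /i/ (slope 0.55, boundary
3.5), flat and /l/-biased for /a/ (slope 4, boundary 1) — and RTs are
lognormal with covariate time-ratio multipliers (e.g., 1.09 per +1 SD of
age).

## Estimation and aggregation

Per listener × vowel, k is anchored on the Δ = 0 false-alarm rate and d′
solved from the Δ = 2 hit rate (bisection-bracketed `brentq`, |residual|
< 10⁻¹⁰; roots clamped at ±10).  Both **listener-mean** and **pooled-rate**
aggregations are emitted.  They genuinely differ: the rate→index transform
is nonlinear, so per-listener estimates at ~60 trials/cell carry a
finite-sample (Jensen) bias — in our calibration, listener-mean d′ in the
low-sensitivity /a/ context sits near 0.25 for a generative 0.45, while
pooled-rate estimates are essentially unbiased.  This is why pooled rates
are the recovery target at study scale, and why group values computed by
the two routes should not be expected to coincide.  Study-scale recovery
is asserted on the mean of 20 replicate simulated cohorts: a single cohort
at 1,920 trials/cell has a Monte-Carlo SE of ≈ 0.16 on /a/-context d′
(the hit-rate slope ∂H/∂d′ is only ≈ 0.086 there), so a one-cohort check
against a ±0.15 band would be uninformative.  Bootstrap CIs resample
listeners (not trials), 10,000 resamples, percentile method.

## Descriptives and RT preprocessing

Curves use Wilson score intervals (z = 1.959964).  RT preprocessing drops
missing RTs (timeouts), applies 0.1–3.0 s bounds, then trims per listener
beyond median ± 3 × MAD on log-RT, with the raw MAD (no 1.4826 constant —
the trimming rule is stated without one).  Per-listener statistics are
computed on the bounds-filtered data; idempotence holds under the
frozen-statistics convention (statistics from the first pass reused), and
output preserves input row order.  For AX, RT analysis is restricted to
correct Δ = 2 responses.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed; identical configs produce
bit-identical artifacts (hash-verified manifest).  Recovery checks use
2×10⁵ trials per cell (±0.05 band) and 20 replicate 32-listener cohorts at
the study's 60 trials/cell (±0.15 band on the replicate mean); bootstrap
coverage is checked at 120 replicates × 400 resamples.  These sizes keep
the full suite under a minute while leaving Monte-Carlo error well inside
each asserted tolerance.

## Limitations

The synthetic tokens exercise the measurement and modelling chain with
known ground truth; they are not perceptually realistic speech (monotone
f0, no articulatory dynamics, no tone), and passing tests show the
*pipeline* is correct, not that real listeners behave like the generative
observer.  Mixed-effects inference on accuracy and RTs (GLMM/LMM families,
planned contrasts) is out of scope — those are routine fits in standard
packages, and the descriptive and SDT layers here are what feed them.
BW1's variance and bias mean per-token bandwidths should only be read
comparatively (between tokens sharing a source) or after averaging many
independent windows.
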