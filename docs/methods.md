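# Methods

## The screening model

The package treats cardiac screening as a three-statistic threshold rule on
a denoised phonocardiogram. The underlying assumption is acoustic, not
morphological: a failing heart produces a *weak* sound, so a recording from
an unhealthy subject — at fixed, uncalibrated gain — has smaller mean
absolute amplitude, smaller variance, and smaller signal energy than a
healthy one. No segmentation into S1/systole/S2/diastole is attempted, no
pathology-specific acoustic model is fitted, and no classifier is trained:
the decision boundaries are fixed constants taken from the extreme observed
feature values of the two groups (the maximum over abnormal recordings and
the minimum over normal ones), which is why the rule is inclusive at both
bounds and leaves the open interval between them *indeterminate* rather than
forcing a call.

The per-feature verdicts are combined by majority vote among the
non-indeterminate votes, with ties indeterminate. The source material
presents the three features jointly without stating a combiner; majority
vote is the weakest combiner consistent with "all three features
discriminate", and it degrades gracefully when one feature falls in its gap.

Two documented inconsistencies in the source material were resolved in favor
of its threshold table: the variance direction (healthy variance is the
*larger* one, consistent with the louder-signal premise) and the mean range
(0.07–0.09).

## Denoising

Wavelet shrinkage with the symlet-4 family at level 4 (both defaults;
symlets are near-symmetric orthogonal wavelets, and level 4 at a 2 kHz rate
puts the 0–62 Hz band — where S1/S2 energy is concentrated — into the
untouched approximation cA₄). The shrinkage recipe is the standard
soft-threshold pipeline:

* noise scale σ̂ = median(|cD₁|)/0.6745, the Gaussian-consistent MAD
  estimate on the finest detail subband;
* universal threshold t = σ̂·√(2 ln n); by default one threshold per detail
  level with n the subband length (`threshold_scope="per_level"`), with a
  single global threshold at n = signal length available as an option —
  the source material names neither rule, so both are provided and neither
  is claimed to replicate its figures exactly;
* soft shrinkage sign(x)·max(|x|−t, 0) applied to every detail subband,
  never to the approximation;
* reconstruction, truncated to the input length.

**Boundary handling.** Periodization is the default: inputs are zero-padded
to a multiple of 2^level and the pad is dropped after reconstruction. This
makes the transform exactly orthogonal, so perfect reconstruction holds to
~1e-12, the coefficient mean square equals the signal mean square
(Parseval) to ~1e-12, and soft shrinkage can only contract the 2-norm.
Symmetric extension is accepted as an option but excluded from the energy
invariants. The DWT cascade itself is delegated to PyWavelets; filter
banks are re-validated at load time (equal lengths, lowpass sum √2,
orthonormality of even shifts to 1e-10) rather than trusted blindly.

**Numerical note.** Energy-conservation checks are stated on the per-sample
mean-square scale. On the raw total energy of a long unit-variance signal,
float64 accumulation alone contributes ~1e-12 relative error, which can
exceed a fixed 1e-9 absolute band while being physically meaningless; the
per-sample form is the scale the energy feature is defined on.

## Features

`dwt_energy` sums squared coefficients over cA and every cD level and
divides by the *original* sample count. The energy formula Σx²/n is
ambiguous between raw amplitudes and wavelet coefficients; with an
orthogonal periodized transform and no thresholding the two coincide
exactly, so the coefficient-sum reading is adopted — it remains well defined
after thresholding, which is when the features are actually computed
(`denoise_first=True` is the default, since denoising precedes analysis in
the pipeline). Variance uses the population divisor n, matching the 1/n
convention of the energy formula.

Auxiliary analyses: a Hann-window magnitude STFT (defaults 256-sample
window, 50% overlap at 2 kHz — no STFT parameters are prescribed by the
source material) and a moment fit of a normal distribution to the amplitude
histogram. Because a Gaussian's peak density is 1/(σ√2π), the loud
(high-σ) healthy signal has the *lower* peak density; the package states
the ordering in that literal form.

## The synthetic-data generator

`generate_pcg` builds each cardiac cycle from an S1 event at cycle start and
an S2 event after the systolic interval, each a sinusoid at its dominant
frequency (S1 35 Hz, S2 60 Hz — physiologically typical; defaults 30–45 and
50–70 Hz ranges) under a raised-cosine envelope of 0.14 s, normalised so the
envelope peak equals the requested amplitude. `s1_s2_gap` is the silent
interval between the end of S1 and the onset of S2. An optional murmur is a
Hann-tapered burst of 150–400 Hz band-limited noise spanning systole, and
wide-band sensor noise is i.i.d. Gaussian. One seeded generator per call; no
global state.

Defaults: 2 kHz sampling (heart-sound energy lies below ~600 Hz, so 2 kHz is
comfortably above Nyquist; the source material states no rate), 10 s
duration, 75 bpm.

**Presets.** `healthy` uses the defaults (S1 peak 1.0, S2 0.85, noise σ
0.01) and lands, after denoising, at mean ≈ 0.108, variance ≈ 0.059,
energy ≈ 0.059 — all above the healthy minima with ≥ 20% margin across
seeds. `unhealthy` is a globally tiny amplitude scale (S1 3·10⁻⁴, plus a
10⁻⁴ murmur at 90 bpm): the abnormal energy bound ≤ 2·10⁻⁸ together with
Jensen's inequality mean(x²) ≥ (mean|x|)² forces the mean absolute
amplitude below ~1.4·10⁻⁴, so the abnormal mean (≤ 0.07) and energy bounds
cannot describe the same gain unless the unhealthy recording is near-silent.
The presets were calibrated once against the extracted features and frozen;
they emulate the *screening contrast* the thresholds encode, not any
specific pathology. Consequently, passing tests demonstrate that the
pipeline implements the rule correctly on signals with the assumed amplitude
structure — they say nothing about clinical sensitivity or specificity on
real recordings, which additionally vary in gain, heart-rate variability,
respiration and sensor response.

## Degenerate inputs and tie-breaks

* All-zero signals denoise to themselves and screen unhealthy (0 lies at or
  below every abnormal maximum).
* Constant signals live entirely in the approximation and pass through
  denoising unchanged.
* σ = 0 in the Gaussian fit defines the density as +∞ at μ and 0 elsewhere.
* A feature value exactly at a boundary belongs to the boundary's class
  (the bounds are observed sample values).
* Odd-length inputs are zero-padded for the periodized cascade; the pad is
  removed on reconstruction.

## Problem sizes

The test suite and the acceptance script use 5–10 s signals at 2 kHz
(10⁴–2·10⁴ samples), 100 random signals of length 16–4096 for the
reconstruction/Parseval sweeps, 20 noise seeds per noise level for the
denoising benchmark, and 50 subjects per group for preset separation —
sizes at which every reported quantity is stable to well within its stated
tolerance while the whole suite runs in seconds.

## Known limitations

* The decision boundaries are absolute amplitudes: any gain change between
  recording and screening invalidates them. No normalisation is applied, by
  design.
* The murmur model is a generic band-limited burst, not a lesion-specific
  sound; heart-rate variability and respiratory modulation are not
  simulated.
* "Mean frequency" appears in the source material's summary as a
  discriminator but is never defined there; only the time/wavelet-domain
  mean, variance and energy are implemented.
* Symmetric-extension mode trades the exact energy invariants for reduced
  wrap-around artefacts; it is provided but not used by the screening
  defaults.
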