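# pcgscreen

Rule-based screening of phonocardiogram (PCG) recordings — heart sounds
captured with a digital stethoscope — into *healthy* / *unhealthy* /
*indeterminate*. The package is aimed at low-cost auscultation pipelines
where a full diagnostic model is out of reach but a loud-vs-weak heart
sound contrast already separates the groups.

The pipeline is:

1. **Denoise** by wavelet shrinkage: decompose with the symlet-4 wavelet
   (4 levels, periodized), estimate the noise scale from the finest detail
   subband, σ̂ = median(|cD₁|)/0.6745, soft-threshold every detail subband at
   the universal threshold t = σ̂·√(2 ln n), leave the approximation cA
   untouched, and reconstruct.
2. **Extract features** of the denoised signal:
   mean absolute amplitude (1/n)·Σ|xᵢ|, population variance
   (1/n)·Σ(xᵢ−x̄)², and the wavelet-coefficient energy
   E = Σc²/n over *all* coefficients (cA and every cD level). With an
   orthogonal periodized transform and no thresholding, Parseval's identity
   makes E equal the raw mean square (1/n)·Σxᵢ².
3. **Classify** each feature against fixed decision boundaries and take a
   majority vote:

   | feature  | unhealthy ≤ | healthy ≥ |
   |----------|-------------|-----------|
   | mean     | 0.07        | 0.09      |
   | variance | 0.01        | 0.015     |
   | energy   | 2·10⁻⁸      | 0.5·10⁻⁵  |

   Values in the open gap between the bounds are *indeterminate*; so is a
   tied vote.

A parametric simulator (`pcgscreen.synthetic`) generates labelled heart
sounds — periodic S1/S2 bursts, optional systolic murmur, additive sensor
noise — so the whole pipeline is testable without recordings.

## Worked example

```sh
$ pcgscreen simulate --preset healthy --seed 0 -o demo.wav
wrote demo.wav (20000 samples at 2000 Hz) and demo.json [label=healthy]
$ pcgscreen classify demo.wav
{
  "per_feature": {"mean": "healthy", "variance": "healthy", "energy": "healthy"},
  "overall": "healthy",
  "votes": {"healthy": 3, "unhealthy": 0, "indeterminate": 0},
  "features": {
    "mean": 0.10801394874346792,
    "variance": 0.05895846686753684,
    "energy": 0.05895849031695719
  },
  ...
}
```

The denoised 10-second synthetic subject has mean absolute amplitude 0.108
(above the 0.09 healthy minimum), variance 0.059 (above 0.015) and wavelet
energy 0.059 (above 0.5·10⁻⁵), so all three features vote healthy and the
command exits 0 (1 = unhealthy, 2 = indeterminate). The same library calls
are available in Python:

```python
from pcgscreen import preset, generate_pcg, screen
result = screen(generate_pcg(preset("unhealthy", seed=0)))
result.overall        # 'unhealthy'
result.features       # FeatureVector(abs_mean=3.5e-05, variance=4.9e-09, ...)
```

Other subcommands: `pcgscreen denoise` (writes the denoised WAV and,
optionally, one CSV per thresholded subband), `pcgscreen features`,
`pcgscreen spectrogram`. Logger CSV exports are accepted everywhere WAV is;
pass `--fs` since text exports carry no sampling rate.

**Amplitude convention.** Integer PCM is rescaled to [-1, 1]; float audio is
used as-is, and no gain normalisation is ever applied — the decision
boundaries are absolute amplitudes, and rescaling a recording would
invalidate them.

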