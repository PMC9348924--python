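"""Discriminative statistics of a (typically denoised) heart-sound signal.

Three scalar features separate healthy from unhealthy recordings:

* ``abs_mean`` — mean absolute amplitude, (1/n) * sum |x_i|;
* ``variance`` — population variance (divisor n), matching the 1/n
  convention of the energy formula;
* ``dwt_energy`` — mean squared wavelet coefficient per original sample,
  (sum over ALL coefficients, cA and every cD level, of c^2) / n.

With an orthogonal periodized transform and no thresholding, Parseval's
identity makes ``dwt_energy`` equal the raw mean square (1/n) * sum x_i^2
exactly, so the wavelet-domain and time-domain readings of the energy
formula coincide; after soft thresholding the coefficient-sum definition
remains well defined and is the one used.

Auxiliary analyses: an STFT magnitude spectrogram and a Gaussian fit to the
amplitude distribution (healthy recordings have larger amplitude spread, so
a SMALLER peak density 1/(sigma*sqrt(2*pi))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann
from scipy.stats import norm

from .signal_io import PcgSignal
from .wavelet import (
    DEFAULT_LEVEL,
    MultilevelDecomposition,
    WaveletSpec,
    decompose,
    reconstruct,
    threshold_decomposition,
)

__all__ = [
    "FeatureVector",
    "SpectrogramMatrix",
    "GaussianFit",
    "abs_mean",
    "variance",
    "dwt_energy",
    "extract_features",
    "spectrogram",
    "fit_gaussian",
    "pdf",
]


@dataclass(frozen=True)
class FeatureVector:
    """The three screening statistics of one signal."""

    abs_mean: float
    variance: float
    dwt_energy: float

    def __post_init__(self) -> None:
        for name in ("abs_mean", "variance", "dwt_energy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"mean": self.abs_mean, "variance": self.variance,
                "energy": self.dwt_energy}


def abs_mean(signal: PcgSignal) -> float:
    """Mean absolute amplitude (1/n) * sum |x_i|."""
    signal.validate()
    return float(np.mean(np.abs(signal.samples)))


def variance(signal: PcgSignal) -> float:
    """Population variance (divisor n)."""
    signal.validate()
    return float(np.var(signal.samples))


def dwt_energy(decomp: MultilevelDecomposition) -> float:
    """Mean squared DWT coefficient per original sample."""
    total = float(np.sum(decomp.cA ** 2))
    total += sum(float(np.sum(c ** 2)) for c in decomp.cD)
    return total / decomp.n_original


def extract_features(signal: PcgSignal,
                     wavelet: WaveletSpec | str | None = None,
                     level: int = DEFAULT_LEVEL,
                     denoise_first: bool = True,
                     threshold_scope: str = "per_level") -> FeatureVector:
    """Compute the three screening features of one signal.

    When ``denoise_first`` (the default, since denoising precedes analysis in
    the screening pipeline) the mean and variance are computed on the
    denoised signal and the energy on the thresholded decomposition that
    produced it; otherwise all three come from the raw signal and its
    unthresholded decomposition.
    """
    decomp = decompose(signal, wavelet, level=level)
    if denoise_first:
        decomp = threshold_decomposition(decomp, threshold_scope=threshold_scope)
        sig = reconstruct(decomp, wavelet)
    else:
        sig = signal
    return FeatureVector(abs_mean(sig), variance(sig), dwt_energy(decomp))


@dataclass
class SpectrogramMatrix:
    """STFT magnitudes: ``magnitudes[i, j]`` at ``times[i]``, ``freqs[j]``."""

    times: np.ndarray   # frame centres, seconds
    freqs: np.ndarray   # bin centres, Hz
    magnitudes: np.ndarray  # (frames, bins), >= 0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.shape != (len(self.times), len(self.freqs)):
            raise ValueError("magnitude matrix shape inconsistent with axes")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")


def spectrogram(signal: PcgSignal, window_length: int = 256,
                overlap: int = 128) -> SpectrogramMatrix:
    """Magnitude STFT with a Hann window.

    Frames hop by ``window_length - overlap`` samples; frequency bins span
    0 to fs/2.
    """
    signal.validate()
    if not 0 <= overlap < window_length:
        raise ValueError("require 0 <= overlap < window_length")
    if window_length > signal.n:
        raise ValueError("window_length exceeds signal length")
    hop = window_length - overlap
    sft = ShortTimeFFT(hann(window_length, sym=False), hop=hop, fs=signal.fs)
    S = sft.stft(signal.samples)  # (bins, frames), complex
    times = sft.t(signal.n)
    return SpectrogramMatrix(times=np.asarray(times),
                             freqs=np.asarray(sft.f),
                             magnitudes=np.abs(S).T)


@dataclass(frozen=True)
class GaussianFit:
    """Normal-distribution fit to the amplitude histogram."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def fit_gaussian(signal: PcgSignal) -> GaussianFit:
    """Moment fit: mu = sample mean, sigma = population standard deviation."""
    signal.validate()
    if signal.n < 2:
        raise ValueError("need at least 2 samples to fit a distribution")
    x = signal.samples
    return GaussianFit(mu=float(np.mean(x)), sigma=float(np.std(x)))


def pdf(fit: GaussianFit, x) -> np.ndarray | float:
    """Gaussian density of the fit at amplitude(s) ``x``.

    The degenerate sigma = 0 case is defined as +inf at mu and 0 elsewhere.
    """
    if fit.sigma == 0:
        xs = np.asarray(x, dtype=np.float64)
        out = np.where(xs == fit.mu, np.inf, 0.0)
        return float(out) if np.isscalar(x) else out
    out = norm.pdf(x, loc=fit.mu, scale=fit.sigma)
    return float(out) if np.isscalar(x) else out
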