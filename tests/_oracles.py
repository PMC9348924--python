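"""Independent reference computations used to cross-check the library.

These are deliberately written from first principles (explicit matrices,
direct sums, bisection against the public classifier API) and never call the
code paths they verify.
"""

import numpy as np
import pywt


def periodized_analysis_matrix(n: int, wavelet: str = "sym4") -> np.ndarray:
    """Explicit n x n orthogonal analysis matrix of one periodized DWT step.

    Row k of the top half computes cA[k] = sum_j lo[j] * x[(2k + L/2 - j) mod n]
    (circular wrap of the downsampled convolution); the bottom half uses the
    highpass filter.  Built by brute force from the filter taps.
    """
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo)
    hi = np.asarray(w.dec_hi)
    L = len(lo)
    assert n % 2 == 0
    M = np.zeros((n, n))
    for k in range(n // 2):
        for j in range(L):
            col = (2 * k + L // 2 - j) % n
            M[k, col] += lo[j]
            M[n // 2 + k, col] += hi[j]
    return M


def recover_boundary(predicate, lo: float, hi: float,
                     iters: int = 200) -> float:
    """Bisect for the switch point of a monotone boolean predicate.

    ``predicate(lo)`` must be False and ``predicate(hi)`` True; returns the
    smallest value (to bisection precision) at which it turns True.
    """
    assert not predicate(lo) and predicate(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return hi


def snr_db(clean: np.ndarray, x: np.ndarray) -> float:
    """10*log10 of clean-to-error energy ratio."""
    return 10.0 * np.log10(np.sum(clean ** 2) / np.sum((x - clean) ** 2))
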