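"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the library
calls) they are meant to check.
"""

import numpy as np


def direct_dft_onesided(x):
    """O(n^2) real-input DFT, non-negative frequencies only."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n // 2 + 1)
    j = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, j) / n)
    return basis @ x


def sorted_quantiles(values):
    """min, q1, median, q3, max by explicit linear interpolation between
    order statistics (index h = (n-1)p)."""
    s = sorted(float(v) for v in values)
    n = len(s)

    def interp(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return s[0], interp(0.25), interp(0.5), interp(0.75), s[-1]


def rectangle_band_power(freqs, density, f_lo, f_hi):
    """Riemann (rectangle) integral of a binned PSD over a band; the
    Parseval-exact reference for line spectra."""
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    return float(density[mask].sum() * df)
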