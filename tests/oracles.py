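"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: an exact 1-D
total-variation solver (Condat's direct taut-string algorithm), a dense-matrix
construction of the periodized analysis operator, and periodogram-based band
energies.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram


def tvd_exact(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact 1-D TV denoising, direct non-iterative algorithm (Condat 2013)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0:
                while k0 <= km:
                    x[k0] = vmin
                    k0 += 1
                k = km = k0
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            if umax > 0:
                while k0 <= kp:
                    x[k0] = vmax
                    k0 += 1
                k = kp = k0
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            vmin += umin / (k - k0 + 1)
            while k0 <= k:
                x[k0] = vmin
                k0 += 1
            return x
        if y[k + 1] + umin < vmin - lam:
            while k0 <= km:
                x[k0] = vmin
                k0 += 1
            k = km = kp = k0
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            while k0 <= kp:
                x[k0] = vmax
                k0 += 1
            k = km = kp = k0
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


def analysis_matrix(n: int, f: np.ndarray) -> np.ndarray:
    """Dense periodized analysis operator: A[m, (2m - k) mod n] += f[k].

    The accumulation form stays correct when n is shorter than the filter
    (taps wrap onto the same column more than once).
    """
    assert n % 2 == 0
    rows = np.zeros((n // 2, n))
    for m in range(n // 2):
        for k in range(f.size):
            rows[m, (2 * m - k) % n] += f[k]
    return rows


def dwt_matrix(n: int, g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Full one-level transform matrix [approx rows; detail rows]."""
    return np.vstack([analysis_matrix(n, g), analysis_matrix(n, h)])


def periodogram_band_fractions(
    samples: np.ndarray, fs: float, edges: dict[str, tuple[float, float]]
) -> dict[str, float]:
    """Fraction of total spectral power per band, from the raw periodogram."""
    freqs, power = periodogram(samples, fs=fs)
    total = power.sum()
    out = {}
    for band, (lo, hi) in edges.items():
        hi = min(hi, fs / 2 + 1)
        mask = (freqs >= lo) & (freqs < hi)
        out[band] = float(power[mask].sum() / total) if total > 0 else 0.0
    return out
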