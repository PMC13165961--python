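"""Minimal orthogonal Daubechies wavelet transform (periodized).

Implements the classic 4-tap Daubechies filter bank analytically (no
table lookup) with periodic boundary handling, which gives an exactly
orthonormal transform on even-length signals and hence perfect
reconstruction to machine precision.
"""

from __future__ import annotations

import numpy as np

_SQRT3 = np.sqrt(3.0)
# 4-tap Daubechies scaling (low-pass) filter, orthonormal: sum h^2 = 1.
DAUB4_LOWPASS = np.array(
    [1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]
) / (4.0 * np.sqrt(2.0))


def _highpass(h: np.ndarray) -> np.ndarray:
    # g[n] = (-1)^n h[K-1-n]
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def dwt_periodic(x: np.ndarray, h: np.ndarray = DAUB4_LOWPASS) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level; ``x`` must have even length."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n % 2 != 0:
        raise ValueError("signal length must be even")
    g = _highpass(h)
    k = np.arange(n // 2)
    idx = (2 * k[:, None] + np.arange(h.size)[None, :]) % n
    windows = x[idx]
    return windows @ h, windows @ g


def idwt_periodic(a: np.ndarray, d: np.ndarray, h: np.ndarray = DAUB4_LOWPASS) -> np.ndarray:
    """Inverse of :func:`dwt_periodic` (exact for orthonormal filters)."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.size != d.size:
        raise ValueError("approximation/detail length mismatch")
    g = _highpass(h)
    n = 2 * a.size
    y = np.zeros(n)
    for k in range(a.size):
        pos = (2 * k + np.arange(h.size)) % n
        np.add.at(y, pos, h * a[k] + g * d[k])
    return y


def wavedec(x: np.ndarray, level: int, h: np.ndarray = DAUB4_LOWPASS) -> list[np.ndarray]:
    """Multilevel decomposition ``[a_L, d_L, ..., d_1]`` (pywt ordering)."""
    x = np.asarray(x, dtype=float)
    details = []
    a = x
    for _ in range(level):
        if a.size % 2 != 0 or a.size < h.size:
            break
        a, d = dwt_periodic(a, h)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray], h: np.ndarray = DAUB4_LOWPASS) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_periodic(a, d, h)
    return a
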