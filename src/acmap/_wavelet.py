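"""Minimal orthogonal wavelet transform used for trace denoising.

Implements a periodized discrete wavelet transform with the 8-tap
symlet-4 filter pair and universal-threshold soft shrinkage.  Only what
the trace-rescaling control needs; not a general wavelet library.
"""

from __future__ import annotations

import numpy as np

# Symlet-4 decomposition low-pass filter (orthonormal, 8 taps).
_SYM4_LO = np.array(
    [
        0.03222310060404270,
        -0.01260396726203783,
        -0.09921954357684722,
        0.29785779560527736,
        0.80373875180591614,
        0.49761866763201545,
        -0.02963552764599851,
        -0.07576571478927333,
    ]
)
# Quadrature mirror high-pass: g[k] = (-1)^k h[N-1-k]
_SYM4_HI = (_SYM4_LO[::-1] * np.array([1, -1] * 4)).copy()


def _dwt_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """One level of the periodized analysis filter bank (len(x) even)."""
    n = x.size
    taps = lo.size
    # y[k] = sum_m f[m] * x[(2k + m) mod n]
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n
    windows = x[idx]
    return windows @ lo, windows @ hi


def _idwt_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Inverse of :func:`_dwt_step` (adjoint of the orthogonal analysis)."""
    n = 2 * a.size
    taps = lo.size
    x = np.zeros(n)
    ks = np.arange(a.size)
    for m in range(taps):
        pos = (2 * ks + m) % n
        np.add.at(x, pos, lo[m] * a)
        np.add.at(x, pos, hi[m] * d)
    return x


def wavedec(x: np.ndarray, level: int):
    """Periodized multilevel DWT; returns [a_L, d_L, ..., d_1]."""
    a = np.asarray(x, dtype=float)
    details = []
    for _ in range(level):
        a, d = _dwt_step(a, _SYM4_LO, _SYM4_HI)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs):
    """Inverse of :func:`wavedec`."""
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _idwt_step(a, d, _SYM4_LO, _SYM4_HI)
    return a


def _max_level(n: int) -> int:
    # stop while the approximation stays longer than the filter
    lev = 0
    while n % 2 == 0 and n // 2 >= _SYM4_LO.size and lev < 12:
        n //= 2
        lev += 1
    return lev


def denoise(x: np.ndarray, level: int | None = None) -> np.ndarray:
    """Wavelet-denoise a 1-D signal (sym4, universal soft threshold).

    The signal is reflect-padded to a power-of-two-friendly length, the
    finest-scale detail coefficients estimate the noise sigma via the
    median absolute deviation, and all detail coefficients are
    soft-thresholded at ``sigma * sqrt(2 log n)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * _SYM4_LO.size:
        return x.copy()
    # pad to a multiple of 2**level
    if level is None:
        level = max(1, int(np.floor(np.log2(n))) - 4)
    block = 2**level
    pad = (-n) % block
    xp = np.concatenate([x, x[-2 : -2 - pad : -1]]) if pad else x
    lev = min(level, _max_level(xp.size))
    if lev < 1:
        return x.copy()
    coeffs = wavedec(xp, lev)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6744897501960817
    thr = sigma * np.sqrt(2.0 * np.log(xp.size))
    for i in range(1, len(coeffs)):
        d = coeffs[i]
        coeffs[i] = np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
    out = waverec(coeffs)
    return out[:n]
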