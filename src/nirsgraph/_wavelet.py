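"""Minimal periodized orthogonal discrete wavelet transform.

Only what spike suppression needs: a multi-level analysis/synthesis pair
with perfect reconstruction.  The transform is the orthonormal periodized
pyramid: analysis row n of the approximation operator places the scaling
filter at position 2n (mod N), details use the quadrature-mirror filter;
synthesis is the transpose.  Requires even length at every level.
"""

from __future__ import annotations

import numpy as np

# Daubechies-4 (8-tap) scaling filter, sums to sqrt(2).
_DB4_H = np.array(
    [
        0.230377813308855230,
        0.714846570552541500,
        0.630880767929590400,
        -0.027983769416983850,
        -0.187034811718881140,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ]
)
_DB4_G = (_DB4_H[::-1] * np.array([1.0 if k % 2 == 0 else -1.0 for k in range(8)]))


def _analysis_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    assert n % 2 == 0
    half = n // 2
    a = np.zeros(half)
    d = np.zeros(half)
    pos = (2 * np.arange(half))[:, None] + np.arange(8)[None, :]
    xg = x[pos % n]  # (half, 8)
    a[:] = xg @ _DB4_H
    d[:] = xg @ _DB4_G
    return a, d


def _synthesis_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    half = a.shape[0]
    n = 2 * half
    x = np.zeros(n)
    pos = ((2 * np.arange(half))[:, None] + np.arange(8)[None, :]) % n
    np.add.at(x, pos, a[:, None] * _DB4_H[None, :])
    np.add.at(x, pos, d[:, None] * _DB4_G[None, :])
    return x


def wavedec(x: np.ndarray, level: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multi-level decomposition: returns (approximation, [d1, d2, ..., dL]).

    d1 is the finest detail level.  Length must be divisible by 2**level.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] % (1 << level) != 0:
        raise ValueError(f"length {x.shape[0]} not divisible by 2**{level}")
    details = []
    a = x
    for _ in range(level):
        a, d = _analysis_step(a)
        details.append(d)
    return a, details


def waverec(approx: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    a = approx
    for d in reversed(details):
        a = _synthesis_step(a, d)
    return a
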