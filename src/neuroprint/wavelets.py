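"""Minimal orthogonal Daubechies wavelet transform (periodized).

Implements just what the motion-correction stage needs: a multilevel
analysis/synthesis pair with perfect reconstruction. The analysis operator
uses shifts-by-two of the orthonormal Daubechies filters with circular
extension, so synthesis is its transpose.
"""
from __future__ import annotations

import numpy as np

from .types import InvalidArgumentError

# Orthonormal lowpass filters (sum = sqrt(2)).
_DB_FILTERS: dict[str, np.ndarray] = {
    "db1": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array([
        0.48296291314469025, 0.8365163037378079,
        0.22414386804185735, -0.12940952255092145,
    ]),
    "db3": np.array([
        0.3326705529509569, 0.8068915093133388, 0.4598775021193313,
        -0.13501102001039084, -0.08544127388224149, 0.035226291882100656,
    ]),
    "db4": np.array([
        0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
        -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
        0.032883011666982945, -0.010597401784997278,
    ]),
}


def _filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = _DB_FILTERS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown wavelet {name!r}; available: {sorted(_DB_FILTERS)}"
        ) from None
    hi = ((-1.0) ** np.arange(len(lo))) * lo[::-1]
    return lo, hi


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = len(x)
    half = n // 2
    k = np.arange(len(lo))
    idx = (2 * np.arange(half)[:, None] + k[None, :]) % n
    window = x[idx]
    return window @ lo, window @ hi


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = 2 * len(a)
    k = np.arange(len(lo))
    idx = (2 * np.arange(len(a))[:, None] + k[None, :]) % n
    x = np.zeros(n)
    np.add.at(x, idx, a[:, None] * lo[None, :] + d[:, None] * hi[None, :])
    return x


def wavedec(x: np.ndarray, wavelet: str = "db2", level: int = 5) -> list[np.ndarray]:
    """Multilevel periodized DWT -> [a_L, d_L, d_{L-1}, ..., d_1].

    Decomposition stops early (without error) when a level's length becomes
    odd or shorter than the filter; raises if not even one level fits.
    """
    lo, hi = _filters(wavelet)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("wavedec expects a 1-D series")
    if level < 1:
        raise InvalidArgumentError("level must be >= 1")
    if len(x) < len(lo) or len(x) % 2:
        raise InvalidArgumentError(
            f"series of length {len(x)} too short/odd for one {wavelet} level"
        )
    details: list[np.ndarray] = []
    a = x
    for _ in range(level):
        if len(a) < len(lo) or len(a) % 2:
            break
        a, d = _analysis_step(a, lo, hi)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str = "db2") -> np.ndarray:
    """Inverse of :func:`wavedec` (exact, orthogonal transform)."""
    lo, hi = _filters(wavelet)
    a = np.asarray(coeffs[0], dtype=float)
    for d in coeffs[1:]:
        a = _synthesis_step(a, np.asarray(d, dtype=float), lo, hi)
    return a
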