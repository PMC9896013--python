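"""Molar extinction coefficients for hemoglobin chromophores.

Values compiled from the standard tabulation of molar extinction
coefficients for oxy- and deoxy-hemoglobin (originally given in
1/(cm * M) on a log10 scale), converted here to the natural-log
convention consistent with OD = -ln(I / I_ref) and expressed per
mM * cm. Override via :func:`set_extinction_table` or a config file.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import InvalidArgumentError

_LN10 = float(np.log(10.0))

# 1/(cm*M), log10 convention: {wavelength_nm: (HbO2, Hb)}
_LOG10_PER_M = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

_table: dict[float, tuple[float, float]] = {
    wl: (e_hbo * _LN10 / 1000.0, e_hbr * _LN10 / 1000.0)
    for wl, (e_hbo, e_hbr) in _LOG10_PER_M.items()
}


def get_extinction(wavelength: float) -> tuple[float, float]:
    """(epsilon_HbO, epsilon_HbR) in 1/(mM*cm), natural-log convention."""
    try:
        return _table[float(wavelength)]
    except KeyError:
        raise InvalidArgumentError(
            f"no extinction entry for {wavelength} nm; "
            f"known: {sorted(_table)}"
        ) from None


def extinction_matrix(wavelengths: tuple[float, float] = (760.0, 850.0)) -> np.ndarray:
    """2x2 matrix, rows = wavelengths, columns = (HbO, HbR)."""
    mat = np.array([get_extinction(w) for w in wavelengths], dtype=float)
    if not np.isfinite(np.linalg.cond(mat)) or np.linalg.cond(mat) > 1e12:
        raise InvalidArgumentError("extinction matrix is singular")
    return mat


def set_extinction_table(table: dict[float, tuple[float, float]]) -> None:
    """Replace the compiled table (values in 1/(mM*cm), natural log)."""
    global _table
    if len(table) < 2:
        raise InvalidArgumentError("need at least two wavelengths")
    _table = {float(k): (float(v[0]), float(v[1])) for k, v in table.items()}


def load_extinction_file(path: str | Path) -> None:
    """Load a JSON override: {"760": [eps_hbo, eps_hbr], ...}."""
    with open(path) as fh:
        raw = json.load(fh)
    set_extinction_table({float(k): tuple(v) for k, v in raw.items()})
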