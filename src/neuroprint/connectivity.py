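"""AR prewhitening with BIC order selection and Pearson FC matrices.

Autocorrelated hemodynamic series inflate Pearson correlations; each channel
is therefore whitened by the residuals of a least-squares AR fit whose order
is chosen per series by BIC, before pairwise correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import FCMatrix, InvalidArgumentError, TimeSeriesRun

__all__ = [
    "PrewhitenResult",
    "select_ar_order_bic",
    "fit_ar",
    "prewhiten",
    "prewhiten_run",
    "fc_matrix",
    "fc_from_run",
    "vectorize_upper",
    "devectorize_upper",
    "default_max_order",
]


@dataclass
class PrewhitenResult:
    """Per-channel AR orders/coefficients and the aligned residual matrix."""

    order_p: np.ndarray           # per channel
    ar_coefficients: list[np.ndarray]
    residuals: np.ndarray         # channels x common residual length


def default_max_order(n_samples: int) -> int:
    """Default BIC search cap: min(30, n/10)."""
    return max(0, min(30, n_samples // 10))


def _lag_design(x: np.ndarray, max_order: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(x)
    y = x[max_order:]
    cols = [x[max_order - p: n - p] for p in range(1, max_order + 1)]
    return np.column_stack(cols) if cols else np.empty((n - max_order, 0)), y


def select_ar_order_bic(series: np.ndarray, max_order: int | None = None) -> int:
    """argmin over p in [0, max_order] of n*ln(sigma2_p) + p*ln(n).

    AR models are fit by ordinary least squares on the common sample window
    (the last ``n - max_order`` points), so residual variances are nested and
    comparable; ties break toward smaller p. A constant series returns 0
    with a warning.
    """
    x = np.asarray(series, dtype=float)
    if max_order is None:
        max_order = default_max_order(len(x))
    if max_order < 0:
        raise InvalidArgumentError("max_order must be >= 0")
    if max_order == 0:
        return 0
    if len(x) <= 3 * max_order:
        raise InvalidArgumentError(
            f"series length {len(x)} too short for max_order {max_order}"
        )
    x = x - x.mean()
    if np.all(x == 0):
        warnings.warn("constant series: AR order forced to 0", stacklevel=2)
        return 0
    design, y = _lag_design(x, max_order)
    n_eff = len(y)
    # One QR gives every nested-prefix OLS fit: RSS_p = |y|^2 - sum_{i<p} (q_i'y)^2
    q, _ = np.linalg.qr(design, mode="reduced")
    qty = q.T @ y
    rss = np.concatenate([[y @ y], (y @ y) - np.cumsum(qty**2)])
    rss = np.maximum(rss, 1e-300)
    orders = np.arange(max_order + 1)
    bic = n_eff * np.log(rss / n_eff) + orders * np.log(n_eff)
    return int(np.argmin(bic))


def fit_ar(series: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS AR fit; returns (coefficients, residuals of length n - order)."""
    x = np.asarray(series, dtype=float)
    if order < 0:
        raise InvalidArgumentError("order must be >= 0")
    if order >= len(x) / 3:
        raise InvalidArgumentError("order must be < length / 3")
    x = x - x.mean()
    if order == 0:
        return np.empty(0), x
    design, y = _lag_design(x, order)
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coefs, y - design @ coefs


def prewhiten(series: np.ndarray, order: int) -> np.ndarray:
    """Residuals of the fitted AR(order); order 0 returns the centred series."""
    return fit_ar(series, order)[1]


def prewhiten_run(
    run: TimeSeriesRun, max_order: int | None = None
) -> PrewhitenResult:
    """Prewhiten every channel (independent BIC order per channel).

    Residual lengths differ by channel (n - P_c); all are truncated to the
    common minimum by keeping the most recent samples, so the later Pearson
    correlation uses time-aligned points.
    """
    orders = np.empty(run.n_channels, dtype=int)
    coefs: list[np.ndarray] = []
    residuals: list[np.ndarray] = []
    for ci in range(run.n_channels):
        p = select_ar_order_bic(run.data[ci], max_order)
        c, r = fit_ar(run.data[ci], p)
        orders[ci] = p
        coefs.append(c)
        residuals.append(r)
    common = min(len(r) for r in residuals)
    aligned = np.stack([r[-common:] for r in residuals])
    return PrewhitenResult(order_p=orders, ar_coefficients=coefs, residuals=aligned)


def fc_matrix(run: TimeSeriesRun, prewhitened: np.ndarray | None = None) -> FCMatrix:
    """Pairwise Pearson correlation of prewhitened channels.

    Zero-variance channels get zero rows/columns (diagonal kept at 1) and
    are flagged in the result.
    """
    data = run.data if prewhitened is None else np.asarray(prewhitened, dtype=float)
    if data.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 channels")
    if data.shape[1] < 3:
        raise InvalidArgumentError("need at least 3 samples")
    sd = data.std(axis=1)
    flagged = tuple(int(i) for i in np.flatnonzero(sd == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(data)
    for i in flagged:
        values[i, :] = 0.0
        values[:, i] = 0.0
        values[i, i] = 1.0
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return FCMatrix(
        values=values,
        labels=run.channel_ids,
        subject_id=run.subject_id,
        run_id=run.run_id,
        contrast=run.contrast,
        flagged_channels=flagged,
    )


def fc_from_run(run: TimeSeriesRun, max_order: int | None = None) -> FCMatrix:
    """Convenience: prewhiten a run, then correlate."""
    pw = prewhiten_run(run, max_order)
    return fc_matrix(run, pw.residuals)


def vectorize_upper(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper triangle, diagonal excluded: length N(N-1)/2."""
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def devectorize_upper(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (unit diagonal restored)."""
    vec = np.asarray(vec, dtype=float)
    if len(vec) != n * (n - 1) // 2:
        raise InvalidArgumentError(
            f"vector of length {len(vec)} does not match n={n}"
        )
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out
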