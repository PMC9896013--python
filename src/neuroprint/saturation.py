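"""Accuracy-saturation model: Accuracy(%) = alpha * (1 - exp(-gamma * N)).

Fits the curve to mean accuracy versus ROI count, scores the fit with a
chi-square statistic, and derives the ROI counts at which the marginal
accuracy gain per added ROI drops below a stated rate.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from .types import AccuracyModelFit, InvalidArgumentError, NeuroprintError

__all__ = [
    "saturation_curve",
    "fit_saturation_model",
    "chi_square_gof",
    "ar_threshold",
    "FitConvergenceError",
]


class FitConvergenceError(NeuroprintError):
    pass


def saturation_curve(n_rois, alpha: float, gamma: float):
    return alpha * (1.0 - np.exp(-gamma * np.asarray(n_rois, dtype=float)))


def fit_saturation_model(
    roi_counts,
    mean_accuracies,
    rates: tuple[float, ...] = (0.5, 0.25),
    gamma0: float = 0.05,
) -> AccuracyModelFit:
    """Nonlinear least squares for (alpha, gamma), alpha in (0, 100].

    Initialisation: alpha0 = max observed accuracy, gamma0 = 0.05; bounds
    are enforced by the trust-region solver. The fit is deterministic given
    the data.
    """
    n = np.asarray(roi_counts, dtype=float)
    acc = np.asarray(mean_accuracies, dtype=float)
    if n.shape != acc.shape or n.size < 3:
        raise InvalidArgumentError("need >= 3 matching (roi_count, accuracy) points")
    if np.any(acc <= 0) or np.any(acc > 100):
        raise InvalidArgumentError("accuracies must lie in (0, 100]")
    alpha0 = min(100.0, float(acc.max()))
    try:
        popt, _ = optimize.curve_fit(
            saturation_curve,
            n,
            acc,
            p0=[alpha0, gamma0],
            bounds=([1e-9, 1e-9], [100.0, np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(f"saturation fit failed: {exc}") from exc
    alpha, gamma = float(popt[0]), float(popt[1])
    fitted = saturation_curve(n, alpha, gamma)
    chi2, dof, crit = chi_square_gof(acc, fitted)
    thresholds = {rate: ar_threshold(alpha, gamma, rate) for rate in rates}
    return AccuracyModelFit(
        alpha=alpha,
        gamma=gamma,
        chi2=chi2,
        dof=dof,
        critical_at_0p01=crit,
        ar_thresholds=thresholds,
    )


def chi_square_gof(
    observed, fitted, n_params: int = 2, significance: float = 0.01
) -> tuple[float, int, float | None]:
    """chi2 = sum (obs - fit)^2 / fit, on the percentage scale.

    Returns (chi2, dof, critical) where dof = n_points - n_params and
    ``critical`` is the lower ``significance`` quantile of the chi-square
    distribution at that dof (None when dof < 1): a fit is adequate at the
    chosen level when chi2 <= critical is *not* violated in the
    lower-tail sense used for goodness-of-fit acceptance.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 1:
        raise InvalidArgumentError("observed/fitted must match and be non-empty")
    if np.any(fit <= 0):
        raise InvalidArgumentError("fitted values must be positive")
    chi2 = float(np.sum((obs - fit) ** 2 / fit))
    dof = obs.size - n_params
    critical = float(stats.chi2.ppf(significance, dof)) if dof >= 1 else None
    return chi2, dof, critical


def ar_threshold(alpha: float, gamma: float, rate: float) -> int:
    """Smallest integer N with marginal gain alpha*gamma*exp(-gamma*N)
    below ``rate`` percent per ROI: ceil(ln(alpha*gamma/rate)/gamma), or 0
    when the gain is below the rate everywhere."""
    if alpha <= 0 or gamma <= 0 or rate <= 0:
        raise InvalidArgumentError("alpha, gamma and rate must be positive")
    if alpha * gamma <= rate:
        return 0
    return int(math.ceil(math.log(alpha * gamma / rate) / gamma))
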