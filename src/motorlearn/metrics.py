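"""Baseline-variability and learning-rate estimators.

Two notions of learning rate are used in trial-by-trial adaptation work and
both live here:

* the exponential time constant ``c`` of a learning curve
  ``y(t) = a + b exp(-c t)`` fit to error-vs-trial data, and
* the regression slope of the corrective response in a no-feedback test trial
  against the magnitude of the preceding perturbation (a one-shot learning
  proportion, usually reported as a percentage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExponentialFit",
    "SlopeFit",
    "fit_exponential",
    "half_life",
    "baseline_sd",
    "fit_learning_slope",
]


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting y(t) = a + b·exp(−c·t), t = 1..n within the window.

    ``c`` is the learning rate (trial⁻¹); ``p_value`` is the regression
    F-test of the fitted curve against a constant model.
    """

    a: float
    b: float
    c: float
    r_squared: float
    converged: bool
    sse: float = float("nan")
    n: int = 0
    p_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return bool(self.converged and self.p_value < 0.05)


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of test-trial deviation on perturbation magnitude.

    ``slope`` is sign-normalised so that an adaptive correction (deviation
    opposite the perturbation) is positive; multiply by 100 for the
    percentage scale.  ``intercept``, ``stderr`` and ``p_value`` come from
    the underlying regression (stderr/p are invariant to the sign flip).
    """

    slope: float
    intercept: float
    stderr: float
    p_value: float
    n: int

    @property
    def percent(self) -> float:
        return 100.0 * self.slope


_FAILED = ExponentialFit(np.nan, np.nan, np.nan, 0.0, False)


def _model(t, a, b, c):
    return a + b * np.exp(-c * t)


def fit_exponential(
    errors: Sequence[float],
    trial_offset: int = 1,
    init: Optional[tuple[float, float, float]] = None,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> ExponentialFit:
    """Least-squares exponential fit to an error-vs-trial curve.

    The fit window starts at ``trial_offset`` (1-based index into ``errors``)
    and time is re-indexed to t = 1 at the window's first trial.  To avoid
    local minima the optimiser is restarted from five deterministic rate
    guesses spanning c ∈ [1e-3, 1] (plus ``init`` when given) and the
    best-SSE solution wins.  Degenerate inputs (no curvature to fit) return
    ``converged=False`` rather than a spurious rate.
    """
    y = np.asarray(errors, dtype=float).ravel()[trial_offset - 1:]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 trials to fit an exponential")
    t = np.arange(1, n + 1, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return ExponentialFit(float(y[0]), 0.0, bounds[0], 0.0, False, sse=0.0, n=n, p_value=1.0)

    c_lo, c_hi = bounds
    tail = float(np.mean(y[-max(n // 10, 1):]))
    head = float(np.mean(y[: max(n // 10, 1)]))
    starts = [(tail, head - tail, c0) for c0 in np.geomspace(1e-3, 1.0, 5)]
    if init is not None:
        starts.append(tuple(map(float, init)))

    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _model,
                t,
                y,
                p0=(p0[0], p0[1], float(np.clip(p0[2], c_lo, c_hi))),
                bounds=([-np.inf, -np.inf, c_lo], [np.inf, np.inf, c_hi]),
                maxfev=20_000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return _FAILED
    (a, b, c), sse = best
    r2 = 1.0 - sse / sst
    # F-test of the 3-parameter curve against the constant model
    df_num, df_den = 2, n - 3
    if sse > 0 and df_den > 0:
        F = ((sst - sse) / df_num) / (sse / df_den)
        p = float(stats.f.sf(F, df_num, df_den))
    else:
        p = 0.0
    # a flat fit (b pinned to ~0 or c at a bound with no curvature) is not a
    # trustworthy rate estimate
    converged = bool(abs(b) > 0 and np.isfinite(c))
    return ExponentialFit(float(a), float(b), float(c), float(r2), converged, sse=sse, n=n, p_value=p)


def half_life(fit: ExponentialFit) -> float:
    """Trials until half the initial error is corrected: ln(2)/c."""
    if not np.isfinite(fit.c) or fit.c <= 0:
        raise ValueError("half_life requires a positive learning rate c")
    return float(np.log(2.0) / fit.c)


def baseline_sd(errors: Sequence[float], discard: int = 0) -> float:
    """Sample SD (n−1 denominator) of errors after dropping the first ``discard`` trials."""
    y = np.asarray(errors, dtype=float).ravel()
    if discard < 0:
        raise ValueError("discard must be >= 0")
    if len(y) <= discard + 1:
        raise ValueError("need more than discard+1 trials")
    return float(np.std(y[discard:], ddof=1))


def fit_learning_slope(
    perturbations: Sequence[float], test_deviations: Sequence[float]
) -> SlopeFit:
    """One-shot learning rate: OLS of test-trial deviation on perturbation size.

    A subject that corrects a fraction η of a perturbation deviates by −η·p
    on the following test trial, so the raw regression slope is −η; the
    returned ``slope`` is the sign-normalised +η.
    """
    x = np.asarray(perturbations, dtype=float).ravel()
    y = np.asarray(test_deviations, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("perturbations and test_deviations must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct perturbation magnitudes")
    if np.var(x) == 0:
        raise ValueError("perturbations have zero variance")
    res = stats.linregress(x, y)
    return SlopeFit(
        slope=-float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        p_value=float(res.pvalue),
        n=len(x),
    )
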