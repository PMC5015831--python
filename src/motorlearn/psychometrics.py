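"""Probit psychometric fitting for 2AFC discrimination data.

The psychometric function is P("positive" | d) = Φ((d − μ)/σ), where μ is
the point of subjective equality and σ the discrimination uncertainty (mm).
σ is the quantity of interest: it measures the sensory uncertainty of
localising the visual stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import NonIdentifiableError

__all__ = ["PsychometricFit", "fit_probit", "predict_prob"]

_P_CLIP = 1e-6


@dataclass(frozen=True)
class PsychometricFit:
    mu: float
    sigma: float
    nll: float
    converged: bool


def _aggregate(offsets, responses):
    """Normalise either binary rows or per-level (n_pos, n_total) to (d, k, n)."""
    offsets = np.asarray(offsets, dtype=float).ravel()
    responses = np.asarray(responses)
    if responses.ndim == 2 and responses.shape[1] == 2:
        k = responses[:, 0].astype(float)
        n = responses[:, 1].astype(float)
        if len(offsets) != len(k):
            raise ValueError("offsets and (n_pos, n_total) rows must align")
        return offsets, k, n
    responses = responses.astype(float).ravel()
    if len(offsets) != len(responses):
        raise ValueError("offsets and responses must have equal length")
    if not np.all(np.isin(responses, (0.0, 1.0))):
        raise ValueError("binary responses must be 0/1")
    levels = np.unique(offsets)
    k = np.array([responses[offsets == d].sum() for d in levels])
    n = np.array([(offsets == d).sum() for d in levels], dtype=float)
    return levels, k, n


def fit_probit(
    offsets: Sequence[float],
    responses: Union[Sequence[int], np.ndarray, pd.DataFrame],
) -> PsychometricFit:
    """Maximum-likelihood probit fit.

    Accepts either one binary response per row (offsets aligned with 0/1
    responses) or aggregated counts per level as an (n_pos, n_total) array.
    The Bernoulli likelihood is maximised by a derivative-free simplex
    (Nelder–Mead) from a moment-based start: μ₀ at the linearly interpolated
    50% crossing and σ₀ at half the stimulus range; fitted probabilities are
    clamped away from 0/1 for likelihood stability.
    """
    if isinstance(responses, pd.DataFrame):
        responses = responses.to_numpy()
    d, k, n = _aggregate(offsets, responses)
    if len(d) < 3:
        raise NonIdentifiableError("need at least 3 distinct stimulus levels")
    total_pos = k.sum()
    if total_pos == 0 or total_pos == n.sum():
        raise NonIdentifiableError("responses are all one category; sigma is not identifiable")

    prop = k / n
    order = np.argsort(d)
    ds, ps = d[order], prop[order]
    # moment start: 50% crossing by linear interpolation (monotonised), half-range sigma
    ps_mono = np.maximum.accumulate(ps)
    if ps_mono[0] >= 0.5:
        mu0 = ds[0]
    elif ps_mono[-1] <= 0.5:
        mu0 = ds[-1]
    else:
        mu0 = float(np.interp(0.5, ps_mono, ds))
    sigma0 = max((ds[-1] - ds[0]) / 2.0, 1e-3)

    def nll(theta):
        mu, log_sigma = theta
        p = stats.norm.cdf((d - mu) / np.exp(log_sigma))
        p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    res = optimize.minimize(
        nll,
        x0=(mu0, np.log(sigma0)),
        method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-10, maxiter=5000),
    )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return PsychometricFit(mu=mu, sigma=sigma, nll=float(res.fun), converged=bool(res.success))


def predict_prob(fit: PsychometricFit, offsets: Sequence[float]) -> np.ndarray:
    """Φ((d − μ)/σ) for each offset, clipped into the open interval (0, 1)."""
    d = np.asarray(offsets, dtype=float)
    p = stats.norm.cdf((d - fit.mu) / fit.sigma)
    return np.clip(p, _P_CLIP, 1 - _P_CLIP)
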