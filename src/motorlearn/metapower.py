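"""Meta-analytic pooling and permutation-based power machinery.

Workflow: per-subject learning curves from several studies are reduced to
(baseline variability, exponential learning rate) pairs; measures are
z-scored within each study so that studies with different units can be
pooled; the pooled table is correlated (Pearson and Spearman).  Permutation
tests calibrate null distributions of a mean difference or a correlation and
report the minimal effect detectable at a given alpha and power, and a
Fisher-z calculation gives the minimal sample size to detect a target
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .metrics import baseline_sd, fit_exponential

__all__ = [
    "StudyData",
    "synthesize_study",
    "synthesize_meta_cohort",
    "subject_rates",
    "zscore_pool",
    "pooled_correlation",
    "PermutationResult",
    "permutation_threshold",
    "correlation_sample_size",
]


@dataclass
class StudyData:
    """Per-subject raw sequences for one study.

    ``baseline`` and ``curves`` are parallel lists (one array per subject);
    ``baseline_window`` is the last-N rule used for the variability estimate
    (e.g. last 50 trials of the baseline session; studies with fewer
    baseline trials use 20 or 15).
    """

    label: str
    baseline: list = field(repr=False, default_factory=list)
    curves: list = field(repr=False, default_factory=list)
    baseline_window: int = 50
    true_sd: Optional[np.ndarray] = None
    true_rate: Optional[np.ndarray] = None

    @property
    def n_subjects(self) -> int:
        return len(self.curves)


def synthesize_study(
    label: str,
    n_subjects: int,
    n_curve_trials: int,
    seed: int,
    n_baseline_trials: int = 60,
    baseline_window: int = 50,
    rate_range: tuple[float, float] = (0.05, 0.2),
    sd_range: tuple[float, float] = (1.0, 4.0),
    amplitude_ratio: float = 10.0,
    rho: float = 0.0,
) -> StudyData:
    """Generate a synthetic study with known per-subject ground truth.

    Each subject i gets a baseline sequence of i.i.d. N(0, SDᵢ²) errors and a
    learning curve yₜ = bᵢ·exp(−cᵢ·t) + N(0, SDᵢ²) with initial error
    bᵢ = ``amplitude_ratio``·SDᵢ (adaptation starts well above the noise
    floor, as in step-perturbation experiments).  SDᵢ and cᵢ are drawn
    log-uniform/uniform over their ranges; ``rho`` induces a rank
    correlation between them via a shared Gaussian score (rho=0 is the null
    cohort).  Ground truth is kept on the returned object.
    """
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_subjects)
    z2 = rng.standard_normal(n_subjects)
    z_rate = rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * z2
    u_sd = stats.norm.cdf(z1)
    u_rate = stats.norm.cdf(z_rate)
    sd = sd_range[0] + (sd_range[1] - sd_range[0]) * u_sd
    rate = rate_range[0] + (rate_range[1] - rate_range[0]) * u_rate
    t = np.arange(1, n_curve_trials + 1)
    baseline = [rng.normal(0.0, s, size=n_baseline_trials) for s in sd]
    curves = [
        amplitude_ratio * s * np.exp(-c * t) + rng.normal(0.0, s, size=n_curve_trials)
        for s, c in zip(sd, rate)
    ]
    return StudyData(
        label=label,
        baseline=baseline,
        curves=curves,
        baseline_window=baseline_window,
        true_sd=sd,
        true_rate=rate,
    )


#: (label, n_subjects, curve-fit trials, baseline-window rule) for a
#: five-study synthetic cohort shaped like the published force-field /
#: visuomotor adaptation datasets used in the meta-analysis (132 subjects).
META_COHORT_LAYOUT = (
    ("study1", 16, 240, 15),
    ("study2", 37, 30, 50),
    ("study3", 36, 150, 50),
    ("study4", 30, 150, 20),
    ("study5", 13, 200, 50),
)


def synthesize_meta_cohort(seed: int, rho: float = 0.0) -> list[StudyData]:
    """Five synthetic studies (n = 16+37+36+30+13 = 132) with shared ``rho``."""
    ss = np.random.SeedSequence(seed).generate_state(len(META_COHORT_LAYOUT)) % (2**31)
    return [
        synthesize_study(label, n, n_trials, int(s), baseline_window=window, rho=rho)
        for (label, n, n_trials, window), s in zip(META_COHORT_LAYOUT, ss)
    ]


def subject_rates(study: StudyData) -> pd.DataFrame:
    """Per-subject (baseline SD, exponential rate, fit r², significance).

    Baseline SD uses the study's last-N window; the learning rate is the
    exponential time constant fit to the full learning curve.  Failed or
    non-significant fits are flagged, never silently dropped.
    """
    rows = []
    for i, (base, curve) in enumerate(zip(study.baseline, study.curves)):
        base = np.asarray(base, float)
        if len(curve) < 10:
            raise ValueError("each learning curve needs at least 10 trials")
        window = min(study.baseline_window, len(base))
        sd = baseline_sd(base[-window:])
        fit = fit_exponential(curve)
        rows.append(
            dict(
                study=study.label,
                subject=i,
                baseline_sd=sd,
                rate=fit.c,
                r_squared=fit.r_squared,
                converged=fit.converged,
                significant=fit.significant,
            )
        )
    return pd.DataFrame(rows)


def zscore_pool(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Z-score (variability, rate) within each study, then concatenate.

    Pooling on z-scores makes studies with different units commensurable;
    each study contributes mean-0, SD-1 columns.
    """
    parts = []
    for tab in tables:
        if len(tab) < 2:
            raise ValueError("each study needs at least 2 subjects")
        out = tab[["study", "subject"]].copy()
        for col, zcol in (("baseline_sd", "variability_z"), ("rate", "rate_z")):
            v = tab[col].to_numpy(float)
            s = v.std(ddof=1)
            if s == 0:
                raise UndefinedCorrelationError(f"zero within-study variance in {col}")
            out[zcol] = (v - v.mean()) / s
        parts.append(out)
    return pd.concat(parts, ignore_index=True)


def pooled_correlation(pooled: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson and Spearman correlation (r, two-tailed p) of the pooled table."""
    x = pooled["variability_z"].to_numpy(float)
    y = pooled["rate_z"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 pooled subjects")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("constant column in pooled table")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson": (float(pr.statistic), float(pr.pvalue)),
        "spearman": (float(sr.statistic), float(sr.pvalue)),
    }


@dataclass(frozen=True)
class PermutationResult:
    statistic: str
    observed: float
    p_value: float
    critical_value: float     # alpha-level two-sided critical |statistic| under the null
    null_sd: float
    detectable_effect: float  # minimal effect attaining the requested power
    n_perm: int
    alpha: float
    power: float


def _perm_null_mean_diff_paired(d: np.ndarray, n_perm: int, rng) -> np.ndarray:
    signs = rng.choice((-1.0, 1.0), size=(n_perm, len(d)))
    return (signs * d).mean(axis=1)


def _perm_null_mean_diff_unpaired(a, b, n_perm, rng):
    pool = np.concatenate([a, b])
    n_a = len(a)
    idx = np.argsort(rng.random((n_perm, len(pool))), axis=1)
    shuffled = pool[idx]
    return shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)


def _perm_null_correlation(a, b, n_perm, rng):
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    idx = np.argsort(rng.random((n_perm, len(b))), axis=1)
    return (bz[idx] @ az) / len(a)


def permutation_threshold(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    *,
    statistic: str = "mean_difference",
    paired: bool = False,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    power: float = 0.8,
    seed: int = 0,
    n_sim: int = 2_000,
) -> PermutationResult:
    """Permutation null calibration plus minimal detectable effect.

    ``statistic='mean_difference'``: with ``paired=True`` the null reshuffles
    the signs of the paired differences; otherwise group labels are
    reshuffled.  ``statistic='correlation'``: one margin is permuted.  The
    two-sided critical value is the (1−alpha) quantile of |null statistic|.

    The minimal detectable effect is found by Monte-Carlo against the fixed
    permutation critical value: a normal alternative with the observed
    spread is shifted (mean difference) or given an induced correlation
    (bivariate-normal ρ), and the smallest effect reaching the requested
    power is located by bisection.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    a = np.asarray(a, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    if statistic == "mean_difference":
        if b is None:
            d = a  # already paired differences
        else:
            b_arr = np.asarray(b, dtype=float).ravel()
            if paired:
                if len(a) != len(b_arr):
                    raise ValueError("paired samples must have equal length")
                d = a - b_arr
            else:
                d = None
        if paired or b is None:
            if len(d) < 2 or np.all(d == d[0]):
                raise ValueError("degenerate paired differences")
            null = _perm_null_mean_diff_paired(d, n_perm, rng)
            observed = float(d.mean())
            sd_eff = float(d.std(ddof=1)) / np.sqrt(len(d))
        else:
            b_arr = np.asarray(b, dtype=float).ravel()
            if len(a) < 2 or len(b_arr) < 2:
                raise ValueError("each group needs at least 2 values")
            null = _perm_null_mean_diff_unpaired(a, b_arr, n_perm, rng)
            observed = float(a.mean() - b_arr.mean())
            sd_eff = float(
                np.sqrt(a.var(ddof=1) / len(a) + b_arr.var(ddof=1) / len(b_arr))
            )
        crit = float(np.quantile(np.abs(null), 1 - alpha))
        # power(Δ) under a normal sampling model for the statistic
        means = rng.normal(0.0, sd_eff, size=n_sim)

        def attained_power(delta: float) -> float:
            return float(np.mean(np.abs(means + delta) > crit))

    elif statistic == "correlation":
        if b is None:
            raise ValueError("correlation statistic needs two paired vectors")
        b_arr = np.asarray(b, dtype=float).ravel()
        if len(a) != len(b_arr) or len(a) < 3:
            raise ValueError("correlation needs paired vectors of length >= 3")
        if a.std() == 0 or b_arr.std() == 0:
            raise UndefinedCorrelationError("zero variance input to correlation permutation")
        null = _perm_null_correlation(a, b_arr, n_perm, rng)
        observed = float(stats.pearsonr(a, b_arr).statistic)
        crit = float(np.quantile(np.abs(null), 1 - alpha))
        n = len(a)
        x_sim = rng.standard_normal((n_sim, n))
        e_sim = rng.standard_normal((n_sim, n))

        def attained_power(rho: float) -> float:
            y = rho * x_sim + np.sqrt(1 - rho**2) * e_sim
            xc = x_sim - x_sim.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            r = (xc * yc).sum(axis=1) / np.sqrt(
                (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
            )
            return float(np.mean(np.abs(r) > crit))

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    p_value = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1))

    lo, hi = 0.0, 0.999 if statistic == "correlation" else crit + 10 * max(sd_eff, 1e-12)
    if attained_power(hi) < power:
        detectable = float("nan")
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if attained_power(mid) >= power:
                hi = mid
            else:
                lo = mid
        detectable = hi

    return PermutationResult(
        statistic=statistic,
        observed=observed,
        p_value=p_value,
        critical_value=crit,
        null_sd=float(null.std(ddof=1)),
        detectable_effect=float(detectable),
        n_perm=n_perm,
        alpha=alpha,
        power=power,
    )


def correlation_sample_size(r: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest n detecting a correlation ``r`` via the Fisher-z approximation.

    Power at sample size n is Φ(atanh(r)·√(n−3) − z_{1−α/2}); returns the
    smallest integer n (≥ 4) whose power reaches the target.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie strictly between 0 and 1")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    fz = np.arctanh(r)
    n = 4
    while True:
        attained = stats.norm.cdf(fz * np.sqrt(n - 3) - z_crit)
        if attained >= power:
            return n
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample-size search did not terminate")
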