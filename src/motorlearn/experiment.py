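"""Synthetic block-design adaptation experiments with simulated subjects.

Four experiment templates are provided, matching the trial structure of a
trial-by-trial visual-perturbation paradigm:

* ``Exp1`` — reaching to two directions (10°, 150°), two sessions;
  perturbations [0, ±15, ±30] mm; 520 trials total.
* ``Exp2`` — reaching to two distances (75, 150 mm); same structure as Exp1.
* ``Exp3`` — one target, perturbations in the movement (parallel) or
  orthogonal direction, interleaved; perturbations [0, ±5, ±10] mm;
  500 trials total.
* ``Exp4`` — isometric force pulses to 2 N / 4 N targets; perturbations
  [0, ±0.3, ±0.6] N; 700 trials total.

Each adaptation block is ``n`` trials: (n−2) veridical null trials, one
perturbation trial, and one no-feedback test trial whose deviation measures
one-shot learning.  Simulated subjects are single-state error-corrective
learners whose correction gain η follows cue combination: a visual error is
weighted by the relative reliability of vision against non-visual cues,
η = g·σ_P²/(σ_P² + σ_V²), making η the ground-truth learning rate that the
analysis pipeline should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .metrics import SlopeFit, fit_learning_slope

__all__ = [
    "EXPERIMENTS",
    "BlockDesign",
    "SubjectModel",
    "SubjectMetrics",
    "CohortCorrelations",
    "make_design",
    "simulate_subject",
    "estimate_subject_metrics",
    "cohort_analysis",
    "generate_2afc",
    "TWO_AFC_OFFSETS",
]

#: stimulus offsets (mm) and repetitions of the 2AFC position-discrimination task
TWO_AFC_OFFSETS: tuple[float, ...] = (-2.1, -1.4, -0.7, 0.0, 0.7, 1.4, 2.1)
TWO_AFC_REPS = 20

# experiment templates: conditions, perturbation sets, per-magnitude block
# sizes, and per-session phase lengths (familiarization, baseline, adaptation)
_TEMPLATES = {
    "Exp1": dict(
        conditions=("10deg", "150deg"),
        sessions_per_condition=True,
        magnitudes=(0.0, 15.0, -15.0, 30.0, -30.0),
        block_sizes=(3, 3, 3, 4, 4, 4, 4, 5, 5, 5),
        phases=(20, 40, 200),
        units="mm",
    ),
    "Exp2": dict(
        conditions=("75mm", "150mm"),
        sessions_per_condition=True,
        magnitudes=(0.0, 15.0, -15.0, 30.0, -30.0),
        block_sizes=(3, 3, 3, 4, 4, 4, 4, 5, 5, 5),
        phases=(20, 40, 200),
        units="mm",
    ),
    "Exp3": dict(
        conditions=("parallel", "orthogonal"),
        sessions_per_condition=False,  # interleaved in one session
        magnitudes=(0.0, 5.0, -5.0, 10.0, -10.0),
        block_sizes=(4,) * 10,
        phases=(60, 40, 400),
        units="mm",
    ),
    "Exp4": dict(
        conditions=("2N", "4N"),
        sessions_per_condition=True,
        magnitudes=(0.0, 0.3, -0.3, 0.6, -0.6),
        block_sizes=(4, 4, 4, 5, 5, 5, 5, 6, 6, 6),
        phases=(60, 40, 250),
        units="N",
    ),
}
EXPERIMENTS = tuple(_TEMPLATES)


@dataclass
class BlockDesign:
    """Complete ordered trial skeleton for one experiment.

    ``trials`` has one row per trial with columns: condition, phase
    (familiarization | baseline | adaptation), block (0 outside adaptation),
    trial_in_block, trial_type (familiarization | baseline | null | perturb |
    test), perturbation, feedback.
    """

    experiment_id: str
    conditions: tuple[str, ...]
    magnitudes: tuple[float, ...]
    block_sizes: tuple[int, ...]
    phases: tuple[int, int, int]
    units: str
    seed: int
    trials: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _condition_blocks(rng, condition, magnitudes, block_sizes):
    blocks = [(condition, m, s) for m in magnitudes for s in block_sizes]
    rng.shuffle(blocks)
    return blocks


def make_design(experiment_id: str, seed: int = 0) -> BlockDesign:
    """Build the full randomized trial sequence for one experiment.

    Block order (and block-size assignment per magnitude) is shuffled with
    the session-level seed.  Design invariants: each adaptation block ends
    with exactly one perturbation trial followed by one no-feedback test
    trial, and every magnitude appears in exactly 10 blocks per condition.
    """
    if experiment_id not in _TEMPLATES:
        raise ValueError(f"unknown experiment id {experiment_id!r}; expected one of {EXPERIMENTS}")
    t = _TEMPLATES[experiment_id]
    rng = np.random.default_rng(seed)
    n_fam, n_base, _ = t["phases"]
    rows: list[dict] = []

    def add_phase(condition, phase, n, trial_type):
        for i in range(n):
            rows.append(
                dict(
                    condition=condition,
                    phase=phase,
                    block=0,
                    trial_in_block=i + 1,
                    trial_type=trial_type,
                    perturbation=0.0,
                    feedback=True,
                )
            )

    def add_blocks(blocks, start_index=1):
        for b, (condition, mag, size) in enumerate(blocks, start=start_index):
            for i in range(size):
                if i < size - 2:
                    ttype, pert, fb = "null", 0.0, True
                elif i == size - 2:
                    ttype, pert, fb = "perturb", mag, True
                else:
                    ttype, pert, fb = "test", 0.0, False
                rows.append(
                    dict(
                        condition=condition,
                        phase="adaptation",
                        block=b,
                        trial_in_block=i + 1,
                        trial_type=ttype,
                        perturbation=pert,
                        feedback=fb,
                    )
                )

    if t["sessions_per_condition"]:
        for condition in t["conditions"]:
            add_phase(condition, "familiarization", n_fam, "familiarization")
            add_phase(condition, "baseline", n_base, "baseline")
            add_blocks(_condition_blocks(rng, condition, t["magnitudes"], t["block_sizes"]))
    else:
        # one session; the two perturbation-direction channels are interleaved.
        # Familiarization/baseline trials are alternately labelled so each
        # channel gets an equal share of baseline endpoints.
        for i in range(n_fam):
            cond = t["conditions"][i % 2]
            rows.append(
                dict(condition=cond, phase="familiarization", block=0, trial_in_block=i + 1,
                     trial_type="familiarization", perturbation=0.0, feedback=True)
            )
        for i in range(n_base):
            cond = t["conditions"][i % 2]
            rows.append(
                dict(condition=cond, phase="baseline", block=0, trial_in_block=i + 1,
                     trial_type="baseline", perturbation=0.0, feedback=True)
            )
        blocks = [
            (c, m, s) for c in t["conditions"] for m in t["magnitudes"] for s in t["block_sizes"]
        ]
        rng.shuffle(blocks)
        add_blocks(blocks)

    trials = pd.DataFrame(rows)
    return BlockDesign(
        experiment_id=experiment_id,
        conditions=t["conditions"],
        magnitudes=t["magnitudes"],
        block_sizes=t["block_sizes"],
        phases=t["phases"],
        units=t["units"],
        seed=seed,
        trials=trials,
    )


@dataclass(frozen=True)
class SubjectModel:
    """Generative model of a behaving subject.

    ``motor_noise_sd`` is the execution noise of the endpoint (mm or N).
    A visually perturbed error is weighted by the reliability of vision
    relative to non-visual (proprioceptive/force) feedback, so the effective
    correction gain to a visual perturbation is

        η = g · σ_P² / (σ_P² + σ_V²)

    Defaults give η = 0.1, in the range of one-shot learning rates measured
    in planar reaching.
    """

    motor_noise_sd: float = 3.0
    sigma_v: float = 1.5
    sigma_p: float = 0.5
    max_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if self.sigma_v <= 0 or self.sigma_p <= 0:
            raise ValueError("sensory SDs must be positive")
        if not 0 <= self.eta <= 1:
            raise ValueError("derived correction gain eta must lie in [0, 1]")

    @property
    def eta(self) -> float:
        return self.max_gain * self.sigma_p**2 / (self.sigma_p**2 + self.sigma_v**2)


def simulate_subject(
    model: SubjectModel, design: BlockDesign, seed: int = 0, subject: int = 0
) -> pd.DataFrame:
    """Simulate one subject through a design.

    A single intended aim point is kept per condition (sessions and Exp3
    channels are independent).  On feedback trials the aim is corrected by
    η times the perceived error (endpoint plus any visual perturbation,
    relative to the target at 0); no-feedback test trials leave it unchanged.
    Endpoints are the intended aim plus execution noise, so baseline
    endpoints have SD ≈ ``motor_noise_sd``.
    """
    rng = np.random.default_rng(seed)
    eta = model.eta
    intended = {c: 0.0 for c in design.conditions}
    out = design.trials.copy()
    n = len(out)
    noise = rng.normal(0.0, model.motor_noise_sd, size=n)
    endpoint = np.empty(n)
    cond = out["condition"].to_numpy()
    pert = out["perturbation"].to_numpy()
    fb = out["feedback"].to_numpy()
    for i in range(n):
        c = cond[i]
        e = intended[c] + noise[i]
        endpoint[i] = e
        if fb[i]:
            perceived = e + pert[i]
            intended[c] = intended[c] - eta * perceived
    out.insert(0, "subject", subject)
    out["endpoint"] = endpoint
    return out


@dataclass(frozen=True)
class SubjectMetrics:
    condition: str
    baseline_sd: float
    slope: SlopeFit


def estimate_subject_metrics(
    records: pd.DataFrame, exclude_magnitudes: Iterable[float] = ()
) -> dict[str, SubjectMetrics]:
    """Per-condition baseline SD and one-shot learning slope from a trial table.

    Baseline SD is the sample SD of baseline-phase endpoints; the slope
    regresses each block's test-trial deviation on the magnitude of the
    preceding perturbation trial.  ``exclude_magnitudes`` drops blocks whose
    |perturbation| is in the set (e.g. re-analysis without the two largest
    perturbations).  Familiarization trials are never used.
    """
    excl = {abs(float(m)) for m in exclude_magnitudes}
    out: dict[str, SubjectMetrics] = {}
    for condition, grp in records.groupby("condition", sort=False):
        base = grp.loc[grp["phase"] == "baseline", "endpoint"]
        perturbs = grp[(grp["trial_type"] == "perturb")]
        tests = grp[(grp["trial_type"] == "test")]
        if len(base) < 2 or tests.empty:
            raise ValueError(f"condition {condition!r} lacks baseline or test trials")
        bmag = perturbs.set_index("block")["perturbation"]
        tdev = tests.set_index("block")["endpoint"]
        blocks = bmag.index.intersection(tdev.index)
        mags = bmag.loc[blocks].to_numpy()
        devs = tdev.loc[blocks].to_numpy()
        keep = ~np.isin(np.abs(mags), list(excl)) if excl else np.ones(len(mags), bool)
        out[str(condition)] = SubjectMetrics(
            condition=str(condition),
            baseline_sd=float(np.std(base.to_numpy(), ddof=1)),
            slope=fit_learning_slope(mags[keep], devs[keep]),
        )
    return out


@dataclass(frozen=True)
class CohortCorrelations:
    """Pearson correlations between variability and learning rate in a cohort."""

    within: dict[str, tuple[float, float]]   # condition -> (r, p)
    pooled_raw: tuple[float, float]
    pooled_normalized: tuple[float, float]   # per-condition z-scored, then pooled


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a correlated column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_analysis(metrics: pd.DataFrame) -> CohortCorrelations:
    """Correlate variability with learning rate within and across conditions.

    ``metrics`` needs columns subject, condition, variability, learning_rate.
    Returns within-condition correlations, the pooled raw correlation, and
    the correlation after z-scoring both measures within each condition
    (removing condition-level mean differences).
    """
    required = {"subject", "condition", "variability", "learning_rate"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    if metrics["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    within = {}
    zparts = []
    for condition, grp in metrics.groupby("condition", sort=False):
        v = grp["variability"].to_numpy(float)
        lr = grp["learning_rate"].to_numpy(float)
        within[str(condition)] = _pearson(v, lr)
        zparts.append(
            np.column_stack([(v - v.mean()) / v.std(ddof=1), (lr - lr.mean()) / lr.std(ddof=1)])
        )
    v_all = metrics["variability"].to_numpy(float)
    lr_all = metrics["learning_rate"].to_numpy(float)
    z = np.vstack(zparts)
    return CohortCorrelations(
        within=within,
        pooled_raw=_pearson(v_all, lr_all),
        pooled_normalized=_pearson(z[:, 0], z[:, 1]),
    )


def generate_2afc(
    sigma_true: float,
    mu_true: float = 0.0,
    seed: int = 0,
    offsets: Sequence[float] = TWO_AFC_OFFSETS,
    n_reps: int = TWO_AFC_REPS,
) -> pd.DataFrame:
    """Binary 2AFC response table for a probit observer.

    For each stimulus offset d (mm) the observer responds "positive" with
    probability Φ((d − μ)/σ); each offset is presented ``n_reps`` times.
    Columns: offset_mm, response (0/1).
    """
    if sigma_true <= 0:
        raise ValueError("sigma_true must be positive")
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(offsets, dtype=float), n_reps)
    p = stats.norm.cdf((d - mu_true) / sigma_true)
    resp = (rng.random(len(d)) < p).astype(int)
    return pd.DataFrame({"offset_mm": d, "response": resp})
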