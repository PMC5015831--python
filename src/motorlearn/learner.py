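"""Two-timescale Kalman-filter model of trial-by-trial motor adaptation.

The learner tracks a hidden perturbation state with two components — a slow
process with high retention and a fast process with low retention — whose sum
is the motor output.  On every trial the model predicts its output, observes
noisy feedback, and corrects a fraction of the prediction error (the
innovation) given by the Kalman gain.  Movement error is identified with the
innovation, so baseline variability is the standard deviation of innovations
over unperturbed trials and the learning curve is the innovation sequence
after a step perturbation of the feedback.

State-space form (per trial k)::

    x_k = A x_{k-1} + w_k,   w_k ~ N(0, Q)      (state drift)
    Z_k = H x_k + v_k,       v_k ~ N(0, R)      (observed feedback)

with the standard Kalman recursion for the estimate x̂ and covariance P:

    x̂_{k|k-1} = A x̂_{k-1|k-1}
    P_{k|k-1} = A P_{k-1|k-1} Aᵀ + Q
    y_k = Z_k − H x̂_{k|k-1}
    S_k = H P_{k|k-1} Hᵀ + R
    K_k = P_{k|k-1} Hᵀ S_k⁻¹
    x̂_{k|k} = x̂_{k|k-1} + K_k y_k
    P_{k|k} = (I − K_k H) P_{k|k-1}

Suboptimal learning is modelled by scaling the applied gain (``gain_scale``)
in both the state and covariance updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import ConvergenceError, NumericalDegeneracyError

__all__ = [
    "LearnerParams",
    "PerturbationSchedule",
    "SimTrace",
    "KalmanStep",
    "StepProtocol",
    "generate_observations",
    "kalman_step",
    "simulate_learner",
    "steady_state_solution",
    "asymptotic_compensation",
    "run_step_protocol",
]


@dataclass
class LearnerParams:
    """Parameters of the two-state optimal learner.

    Defaults are the values that make the simulation quantitatively similar to
    human adaptation: baseline variability about 6% of a typical movement
    amplitude, asymptotic compensation of a constant perturbation about 92%,
    and a learning half-life of roughly 35 trials.

    Attributes
    ----------
    A : (2, 2) diagonal retention matrix; first diagonal entry is the slow
        state (retention 0.998), second the fast state (0.75).
    Q : (2, 2) diagonal process-noise covariance (a.u.²) — trial-to-trial
        drift of the hidden states.
    R : scalar observation-noise variance (a.u.²) — sensory uncertainty of
        the feedback.
    H : (2,) observation row summing the two hidden states into the output.
    x0 : (2,) initial state, zero by default (model initialised to output 0).
    P0 : (2, 2) initial estimate covariance; defaults to Q (the filter burns
        in within tens of trials, so this choice is inert for any quantity
        computed after a burn-in).
    """

    A: np.ndarray = field(default_factory=lambda: np.diag([0.998, 0.75]))
    Q: np.ndarray = field(default_factory=lambda: np.diag([1.46e-7, 1.46e-7]))
    R: float = 3.0e-4
    H: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    x0: np.ndarray = field(default_factory=lambda: np.zeros(2))
    P0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.H = np.asarray(self.H, dtype=float).reshape(2)
        self.x0 = np.asarray(self.x0, dtype=float).reshape(2)
        self.R = float(self.R)
        if self.A.shape != (2, 2) or self.Q.shape != (2, 2):
            raise ValueError("A and Q must be 2x2 matrices")
        if np.any(self.A != np.diag(np.diag(self.A))):
            raise ValueError("A must be diagonal")
        if np.any(self.Q != np.diag(np.diag(self.Q))):
            raise ValueError("Q must be diagonal")
        a = np.diag(self.A)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("diagonal entries of A must lie in (0, 1]")
        if np.any(np.diag(self.Q) < 0):
            raise ValueError("Q diagonal entries must be >= 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.P0 is None:
            self.P0 = self.Q.copy()
        else:
            self.P0 = np.asarray(self.P0, dtype=float)
            if self.P0.shape != (2, 2) or not np.allclose(self.P0, self.P0.T):
                raise ValueError("P0 must be a symmetric 2x2 matrix")
            if np.any(np.linalg.eigvalsh(self.P0) < -1e-12):
                raise ValueError("P0 must be positive semidefinite")

    def with_scaled(self, *, R: float = 1.0, Q: float = 1.0, Q_fast: float = 1.0) -> "LearnerParams":
        """Return a copy with R and/or Q (or only the fast-state noise) multiplied."""
        if min(R, Q, Q_fast) <= 0:
            raise ValueError("scaling factors must be positive")
        Qnew = self.Q * Q
        Qnew = Qnew @ np.diag([1.0, Q_fast])
        return replace(self, Q=Qnew, R=self.R * R, P0=None)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Constant (step) offset added to the observed feedback from ``onset`` onward.

    ``onset`` is 1-based and inclusive: the onset trial is the first perturbed
    trial.  The default magnitude −0.3 is the step used throughout the
    simulations (a constant 0.3 subtracted from the observation).
    """

    onset: int
    magnitude: float = -0.3

    def __post_init__(self) -> None:
        if self.onset < 1:
            raise ValueError("onset must be >= 1 (1-based trial index)")


class KalmanStep(NamedTuple):
    posterior_x: np.ndarray
    posterior_P: np.ndarray
    next_prior_x: np.ndarray
    next_prior_P: np.ndarray
    gain: np.ndarray
    innovation: float
    innovation_variance: float


@dataclass
class SimTrace:
    """Per-trial record of a simulated run.  All arrays share length n_trials.

    ``observation`` is the feedback actually presented to the filter, i.e.
    including any scheduled perturbation; ``perturbation`` records the offset
    applied on each trial.  The innovation identity
    ``innovation == observation − prediction`` holds on every trial.
    """

    prior_x: np.ndarray        # (n, 2) predicted state before feedback
    posterior_x: np.ndarray    # (n, 2) state after the update
    prior_P: np.ndarray        # (n, 2, 2)
    prediction: np.ndarray     # (n,) H · prior_x
    observation: np.ndarray    # (n,) perturbed feedback
    perturbation: np.ndarray   # (n,)
    innovation: np.ndarray     # (n,) movement error
    innovation_variance: np.ndarray  # (n,)
    gain: np.ndarray           # (n, 2)

    @property
    def n_trials(self) -> int:
        return len(self.innovation)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per trial (1-based trial index)."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "observation": self.observation,
                "perturbation": self.perturbation,
                "prediction": self.prediction,
                "innovation": self.innovation,
                "gain_slow": self.gain[:, 0],
                "gain_fast": self.gain[:, 1],
                "posterior_slow": self.posterior_x[:, 0],
                "posterior_fast": self.posterior_x[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_observations(params: LearnerParams, n_trials: int, seed: int) -> np.ndarray:
    """Simulate the open-loop linear dynamical system (no feedback correction).

    Runs x_k = A x_{k-1} + w_k, Z_k = H x_k + v_k from x_0 = params.x0 and
    returns the observation sequence Z — a stationary sequence around zero
    used as the feedback stream for the closed-loop learner.  Deterministic
    given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.diag(params.A)
    q = np.diag(params.Q)
    w = rng.normal(0.0, np.sqrt(q), size=(n_trials, 2))
    v = rng.normal(0.0, np.sqrt(params.R), size=n_trials)
    x = np.empty((n_trials, 2))
    prev = params.x0
    for k in range(n_trials):
        prev = a * prev + w[k]
        x[k] = prev
    return x @ params.H + v


def kalman_step(
    params: LearnerParams,
    prior_x: np.ndarray,
    prior_P: np.ndarray,
    z: float,
    gain_scale: float = 1.0,
) -> KalmanStep:
    """One measurement-update + time-update cycle of the filter.

    Returns the posterior state/covariance for the current trial, the prior
    for the next trial, and the gain, innovation and innovation variance.  A
    ``gain_scale`` different from 1 applies the scaled gain in both the state
    and the covariance update (a deliberately suboptimal learner).
    """
    H = params.H
    prior_x = np.asarray(prior_x, dtype=float).reshape(2)
    prior_P = np.asarray(prior_P, dtype=float).reshape(2, 2)
    S = float(H @ prior_P @ H) + params.R
    if S <= 0:
        raise NumericalDegeneracyError(f"innovation variance S={S} is not positive")
    K = (prior_P @ H) / S
    y = float(z) - float(H @ prior_x)
    Ka = gain_scale * K
    posterior_x = prior_x + Ka * y
    posterior_P = (np.eye(2) - np.outer(Ka, H)) @ prior_P
    next_prior_x = params.A @ posterior_x
    next_prior_P = params.A @ posterior_P @ params.A.T + params.Q
    return KalmanStep(posterior_x, posterior_P, next_prior_x, next_prior_P, K, y, S)


def simulate_learner(
    params: LearnerParams,
    observations: np.ndarray,
    schedule: Optional[PerturbationSchedule] = None,
    gain_scale: float = 1.0,
) -> SimTrace:
    """Run the closed-loop learner over a feedback sequence.

    On trials at or after ``schedule.onset`` (1-based) the observation
    presented to the filter is ``Z_k + schedule.magnitude``.  The recorded
    trace stores the perturbed observation, so the innovation identity holds
    with respect to what the learner actually saw.
    """
    observations = np.asarray(observations, dtype=float).ravel()
    n = len(observations)
    if n == 0:
        raise ValueError("observations must be non-empty")
    if gain_scale <= 0:
        raise ValueError("gain_scale must be positive")

    pert = np.zeros(n)
    if schedule is not None:
        pert[schedule.onset - 1:] = schedule.magnitude
    z_seen = observations + pert

    a1, a2 = float(params.A[0, 0]), float(params.A[1, 1])
    q1, q2 = float(params.Q[0, 0]), float(params.Q[1, 1])
    h1, h2 = float(params.H[0]), float(params.H[1])
    r = params.R
    gs = gain_scale

    prior_x = np.empty((n, 2))
    posterior_x = np.empty((n, 2))
    prior_P = np.empty((n, 2, 2))
    prediction = np.empty(n)
    innovation = np.empty(n)
    innovation_variance = np.empty(n)
    gain = np.empty((n, 2))

    # scalarised recursion on the 2x2 covariance (kept as four entries because
    # (I − KH)P is asymmetric when the applied gain is not the optimal one)
    x1, x2 = float(params.x0[0]), float(params.x0[1])
    p11, p12 = float(params.P0[0, 0]), float(params.P0[0, 1])
    p21, p22 = float(params.P0[1, 0]), float(params.P0[1, 1])
    zv = z_seen
    for k in range(n):
        xp1 = a1 * x1
        xp2 = a2 * x2
        Pp11 = a1 * a1 * p11 + q1
        Pp12 = a1 * a2 * p12
        Pp21 = a2 * a1 * p21
        Pp22 = a2 * a2 * p22 + q2
        hp1 = h1 * Pp11 + h2 * Pp21   # H · Pp (row), and Pp · Hᵀ below
        hp2 = h1 * Pp12 + h2 * Pp22
        S = h1 * hp1 + h2 * hp2 + r
        if S <= 0:
            raise NumericalDegeneracyError(f"innovation variance S={S} at trial {k + 1}")
        K1 = (Pp11 * h1 + Pp12 * h2) / S
        K2 = (Pp21 * h1 + Pp22 * h2) / S
        pred = h1 * xp1 + h2 * xp2
        y = zv[k] - pred
        g1 = gs * K1
        g2 = gs * K2
        x1 = xp1 + g1 * y
        x2 = xp2 + g2 * y
        p11 = Pp11 - g1 * (h1 * Pp11 + h2 * Pp21)
        p12 = Pp12 - g1 * (h1 * Pp12 + h2 * Pp22)
        p21 = Pp21 - g2 * (h1 * Pp11 + h2 * Pp21)
        p22 = Pp22 - g2 * (h1 * Pp12 + h2 * Pp22)

        prior_x[k, 0] = xp1
        prior_x[k, 1] = xp2
        posterior_x[k, 0] = x1
        posterior_x[k, 1] = x2
        prior_P[k, 0, 0] = Pp11
        prior_P[k, 0, 1] = Pp12
        prior_P[k, 1, 0] = Pp21
        prior_P[k, 1, 1] = Pp22
        prediction[k] = pred
        innovation[k] = y
        innovation_variance[k] = S
        gain[k, 0] = K1
        gain[k, 1] = K2

    return SimTrace(
        prior_x=prior_x,
        posterior_x=posterior_x,
        prior_P=prior_P,
        prediction=prediction,
        observation=zv,
        perturbation=pert,
        innovation=innovation,
        innovation_variance=innovation_variance,
        gain=gain,
    )


def steady_state_solution(
    params: LearnerParams, tol: float = 1e-14, max_iter: int = 1_000_000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fixed point of the covariance recursion: (P∞ prior covariance, K∞, S∞).

    Iterates the prediction/update covariance recursions from P0 until
    successive prior covariances change by less than ``tol`` (max-abs).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    A, Q, H, R = params.A, params.Q, params.H, params.R
    P = A @ params.P0 @ A.T + Q
    for _ in range(max_iter):
        S = float(H @ P @ H) + R
        K = (P @ H) / S
        P_post = (np.eye(2) - np.outer(K, H)) @ P
        P_next = A @ P_post @ A.T + Q
        if np.max(np.abs(P_next - P)) < tol:
            S = float(H @ P_next @ H) + R
            K = (P_next @ H) / S
            return P_next, K, S
        P = P_next
    raise ConvergenceError(f"covariance iteration did not converge within {max_iter} iterations")


def asymptotic_compensation(params: LearnerParams, magnitude: float = -0.3) -> float:
    """Fraction of a constant feedback offset compensated after learning asymptotes.

    At steady state the deterministic estimate obeys
    x* = A x* + K∞ (c − H A x*) for a constant offset c; the compensated
    fraction is H x*/c.  By linearity the result is independent of the sign
    (and size) of c.
    """
    if magnitude == 0:
        raise ValueError("magnitude must be nonzero")
    _, K, _ = steady_state_solution(params)
    A, H = params.A, params.H
    M = np.eye(2) - A + np.outer(K, H @ A)
    try:
        x = np.linalg.solve(M, K * magnitude)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(f"singular steady-state system: {exc}") from exc
    return float(H @ x) / magnitude


@dataclass(frozen=True)
class StepProtocol:
    """The step-perturbation protocol used for all learning-rate measurements.

    A 10000-trial unperturbed baseline run (first ``n_discard`` trials dropped
    from variability estimates to exclude transients) followed by a fresh
    continuation of ``n_post`` trials with a constant offset added to the
    feedback; the continuation starts from the baseline's final posterior
    (single continuous run).
    """

    n_baseline: int = 10_000
    n_discard: int = 1_000
    n_post: int = 3_000
    magnitude: float = -0.3

    def __post_init__(self) -> None:
        if self.n_baseline <= self.n_discard:
            raise ValueError("n_baseline must exceed n_discard")
        if self.n_post < 1:
            raise ValueError("n_post must be >= 1")


def run_step_protocol(
    params: LearnerParams,
    seed: int,
    protocol: StepProtocol = StepProtocol(),
    gain_scale: float = 1.0,
) -> SimTrace:
    """Simulate baseline + step-perturbation as one continuous run.

    Returns the full trace of ``n_baseline + n_post`` trials; the perturbation
    onset is trial ``n_baseline + 1`` (1-based).
    """
    n_total = protocol.n_baseline + protocol.n_post
    obs = generate_observations(params, n_total, seed)
    schedule = PerturbationSchedule(onset=protocol.n_baseline + 1, magnitude=protocol.magnitude)
    return simulate_learner(params, obs, schedule=schedule, gain_scale=gain_scale)
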