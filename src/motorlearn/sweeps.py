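"""Parameter sweeps relating baseline variability to learning rate.

Four manipulations of the optimal learner are swept, each predicting a
different variability–learning-rate relation:

* ``observation_noise`` — scale R; variability rises, learning slows.
* ``process_noise`` — scale Q; variability and learning rate rise together.
* ``gain`` — scale the applied Kalman gain; variability is minimised at the
  optimal gain (factor 1) while the learning rate keeps increasing with the
  gain over the simulated range.
* ``fast_state_noise`` — scale only the fast state's process noise;
  variability rises and learning (to a sustained step) slows.

Each (manipulation, factor) cell runs the full baseline + step-perturbation
protocol over a common set of seeds and averages the baseline SD and the
fitted exponential rate across seeds.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .learner import LearnerParams, StepProtocol, run_step_protocol
from .metrics import baseline_sd, fit_exponential

__all__ = ["MANIPULATIONS", "NOISE_FACTORS", "GAIN_FACTORS", "run_sweep", "default_sweeps"]

MANIPULATIONS = ("observation_noise", "process_noise", "gain", "fast_state_noise")

#: factor grids used for the standard sweep set
NOISE_FACTORS: tuple[float, ...] = tuple(float(f) for f in range(1, 11))
GAIN_FACTORS: tuple[float, ...] = (1 / 16, 1 / 8, 1 / 4, 1, 4, 8, 16)


def _seed_set(seed: int, n_seeds: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)


def run_sweep(
    base: LearnerParams,
    manipulation: str,
    factors: Sequence[float],
    n_seeds: int = 20,
    protocol: StepProtocol = StepProtocol(),
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep one manipulation over a factor grid.

    Returns a table with one row per factor: seed-averaged baseline
    variability (SD of unperturbed innovations after the discard window) and
    seed-averaged exponential learning rate ``c`` fit to the post-onset
    error curve.  The same seed set is reused across factors so that e.g.
    gain scales are compared on identical feedback sequences.
    """
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"unknown manipulation {manipulation!r}; expected one of {MANIPULATIONS}")
    factors = [float(f) for f in factors]
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be strictly positive")
    seeds = _seed_set(seed, n_seeds)

    rows = []
    for f in factors:
        gain_scale = 1.0
        if manipulation == "observation_noise":
            params = base.with_scaled(R=f)
        elif manipulation == "process_noise":
            params = base.with_scaled(Q=f)
        elif manipulation == "fast_state_noise":
            params = base.with_scaled(Q_fast=f)
        else:
            params = base
            gain_scale = f
        sds = np.empty(n_seeds)
        rates = np.empty(n_seeds)
        for i, s in enumerate(seeds):
            trace = run_step_protocol(params, int(s), protocol=protocol, gain_scale=gain_scale)
            inn = trace.innovation
            sds[i] = baseline_sd(inn[: protocol.n_baseline], discard=protocol.n_discard)
            fit = fit_exponential(inn[protocol.n_baseline:])
            rates[i] = fit.c if fit.converged else np.nan
        rows.append(
            {
                "manipulation": manipulation,
                "factor": f,
                "variability": float(np.mean(sds)),
                "learning_rate": float(np.nanmean(rates)),
                "n_seeds": n_seeds,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def default_sweeps(
    base: Optional[LearnerParams] = None,
    seed: int = 0,
    n_seeds: int = 20,
    protocol: StepProtocol = StepProtocol(),
) -> pd.DataFrame:
    """Run all four manipulations on their standard factor grids.

    Noise manipulations use integer factors 1..10; the gain manipulation uses
    the grid {1/16, 1/8, 1/4, 1, 4, 8, 16}.  Returns the concatenated sweep
    table (one row per manipulation × factor).
    """
    base = base if base is not None else LearnerParams()
    parts = []
    for manip in MANIPULATIONS:
        grid = GAIN_FACTORS if manip == "gain" else NOISE_FACTORS
        parts.append(run_sweep(base, manip, grid, n_seeds=n_seeds, protocol=protocol, seed=seed))
    return pd.concat(parts, ignore_index=True)
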