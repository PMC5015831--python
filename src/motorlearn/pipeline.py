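"""Configuration and end-to-end pipeline runner.

`run_pipeline` executes a configurable subset of stages — learner
simulation, parameter sweeps, a synthetic cohort experiment, psychometric
fitting, meta-analysis, and permutation power — and writes CSV artifacts
plus a machine-readable JSON summary with a provenance block (config hash,
seeds, package version).  Every stochastic stage derives its seed from the
config, so a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError
from .experiment import (
    SubjectModel,
    cohort_analysis,
    estimate_subject_metrics,
    generate_2afc,
    make_design,
    simulate_subject,
)
from .learner import LearnerParams, StepProtocol, asymptotic_compensation, run_step_protocol
from .metapower import (
    correlation_sample_size,
    permutation_threshold,
    pooled_correlation,
    subject_rates,
    synthesize_meta_cohort,
    zscore_pool,
)
from .metrics import baseline_sd, fit_exponential, half_life
from .psychometrics import fit_probit
from .sweeps import default_sweeps

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "sweep", "experiment", "psychofit", "meta", "power")

#: amplitude reference (a.u.) against which the learner's baseline SD is
#: expressed as a percentage — the magnitude of the step perturbation
AMPLITUDE_REFERENCE = 0.3


@dataclass
class RunConfig:
    """Flat, serialisable pipeline configuration.

    Defaults are the standard study conditions: the default learner
    parameters, a 10000-trial baseline with the first 1000 trials discarded,
    a −0.3 step perturbation with 3000 post-onset trials, 20 seeds per
    averaged quantity, and the standard sweep grids.
    """

    stages: tuple[str, ...] = ("simulate",)
    seed: int = 0
    out_dir: str = "motorlearn_out"
    # learner / protocol
    n_baseline: int = 10_000
    n_discard: int = 1_000
    n_post: int = 3_000
    perturbation: float = -0.3
    n_seeds: int = 20
    # sweeps
    sweep_n_seeds: int = 20
    # synthetic experiment
    experiment_id: str = "Exp1"
    n_subjects: int = 20
    motor_noise_sd: float = 3.0
    sigma_v: float = 1.5
    sigma_p: float = 0.5
    # psychometrics
    psychofit_sigma_true: float = 1.63
    # power
    power_n: int = 132
    power_n_perm: int = 10_000

    def protocol(self) -> StepProtocol:
        return StepProtocol(
            n_baseline=self.n_baseline,
            n_discard=self.n_discard,
            n_post=self.n_post,
            magnitude=self.perturbation,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    params = LearnerParams()
    protocol = cfg.protocol()
    seeds = _seeds(cfg.seed, cfg.n_seeds)
    sds, hls = [], []
    for s in seeds:
        trace = run_step_protocol(params, s, protocol=protocol)
        inn = trace.innovation
        sds.append(baseline_sd(inn[: protocol.n_baseline], discard=protocol.n_discard))
        fit = fit_exponential(inn[protocol.n_baseline:])
        if fit.converged:
            hls.append(half_life(fit))
    trace0 = run_step_protocol(params, seeds[0], protocol=protocol)
    trace0.to_csv(out / "trace.csv")
    comp = asymptotic_compensation(params, protocol.magnitude)
    return {
        "asymptotic_compensation_percent": 100.0 * comp,
        "half_life_trials": float(np.mean(hls)),
        "baseline_sd": float(np.mean(sds)),
        "baseline_sd_percent_of_amplitude": 100.0 * float(np.mean(sds)) / AMPLITUDE_REFERENCE,
        "n_seeds": cfg.n_seeds,
    }


def _stage_sweep(cfg: RunConfig, out: Path) -> dict:
    table = default_sweeps(seed=cfg.seed, n_seeds=cfg.sweep_n_seeds, protocol=cfg.protocol())
    table.to_csv(out / "sweeps.csv", index=False)
    summary = {}
    for manip, grp in table.groupby("manipulation"):
        rho_v = float(pd.Series(grp["factor"]).corr(grp["variability"], method="spearman"))
        rho_r = float(pd.Series(grp["factor"]).corr(grp["learning_rate"], method="spearman"))
        summary[manip] = {"variability_rank_corr": rho_v, "rate_rank_corr": rho_r}
    return summary


def _stage_experiment(cfg: RunConfig, out: Path) -> dict:
    design = make_design(cfg.experiment_id, seed=cfg.seed)
    model = SubjectModel(
        motor_noise_sd=cfg.motor_noise_sd, sigma_v=cfg.sigma_v, sigma_p=cfg.sigma_p
    )
    seeds = _seeds(cfg.seed + 1, cfg.n_subjects)
    tables, rows = [], []
    for i, s in enumerate(seeds):
        rec = simulate_subject(model, design, seed=s, subject=i)
        tables.append(rec)
        for condition, m in estimate_subject_metrics(rec).items():
            rows.append(
                dict(
                    subject=i,
                    condition=condition,
                    variability=m.baseline_sd,
                    learning_rate=m.slope.slope,
                )
            )
    pd.concat(tables, ignore_index=True).to_csv(out / "trials.csv", index=False)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "subject_metrics.csv", index=False)
    corr = cohort_analysis(metrics)
    return {
        "experiment_id": cfg.experiment_id,
        "n_subjects": cfg.n_subjects,
        "true_eta": model.eta,
        "mean_learning_rate_percent": 100.0 * float(metrics["learning_rate"].mean()),
        "mean_variability": float(metrics["variability"].mean()),
        "normalized_r": corr.pooled_normalized[0],
        "normalized_p": corr.pooled_normalized[1],
    }


def _stage_psychofit(cfg: RunConfig, out: Path) -> dict:
    table = generate_2afc(cfg.psychofit_sigma_true, seed=cfg.seed)
    table.to_csv(out / "responses_2afc.csv", index=False)
    fit = fit_probit(table["offset_mm"], table["response"])
    return {
        "sigma_true": cfg.psychofit_sigma_true,
        "sigma_fit": fit.sigma,
        "mu_fit": fit.mu,
        "converged": fit.converged,
    }


def _stage_meta(cfg: RunConfig, out: Path) -> dict:
    studies = synthesize_meta_cohort(cfg.seed)
    tables = [subject_rates(s) for s in studies]
    pooled = zscore_pool(tables)
    pooled.to_csv(out / "pooled_zscores.csv", index=False)
    corr = pooled_correlation(pooled)
    return {
        "n_total": int(len(pooled)),
        "pearson_r": corr["pearson"][0],
        "pearson_p": corr["pearson"][1],
        "spearman_r": corr["spearman"][0],
        "spearman_p": corr["spearman"][1],
    }


def _stage_power(cfg: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    x = rng.standard_normal(cfg.power_n)
    y = rng.standard_normal(cfg.power_n)
    res = permutation_threshold(
        x, y, statistic="correlation", n_perm=cfg.power_n_perm, seed=cfg.seed
    )
    return {
        "critical_r": res.critical_value,
        "detectable_r": res.detectable_effect,
        "n": cfg.power_n,
        "min_n_for_r_0.76": correlation_sample_size(0.76),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sweep": _stage_sweep,
    "experiment": _stage_experiment,
    "psychofit": _stage_psychofit,
    "meta": _stage_meta,
    "power": _stage_power,
}


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the configured stages and write artifacts + summary.json.

    Stage failures abort with a stage-labelled error.  Returns the summary
    dict (also written to ``summary.json``), which carries a provenance
    block: config hash, seed, and package version.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineStageError(unknown[0], f"unknown stage; expected one of {ALL_STAGES}")
    summary: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.to_dict(),
        }
    }
    for stage in config.stages:
        try:
            summary[stage] = _STAGE_FUNCS[stage](config, out)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
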