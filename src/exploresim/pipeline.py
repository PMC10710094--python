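"""End-to-end study driver: cohort -> task simulation -> metrics -> analysis.

Chains the package's stages into reproducible, seeded runs that write tidy
CSVs plus a JSON report mirroring the analysis structure of the study:
information gathering (exploration regression, condition-interaction mixed
models with marginal effects, mediation through habitual responding) and
foraging (environment manipulation check, optimality t tests).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, analysis, metrics as metrics_mod
from .cohort import EffectConfig, cohort_table, generate_cohort, simulate_study
from .fitting import first_free_design, fit
from .orchard import mvt_optimal_threshold, poor_config, rich_config


@dataclass
class RunConfig:
    """Seeds, sizes and effect structure of one reproducible run."""

    n_participants: int = 84
    cohort_seed: int = 1
    study_seed: int = 2
    bootstrap_seed: int = 3
    n_boot: int = 5000
    effect: EffectConfig = field(default_factory=EffectConfig)
    tasks: tuple = ("horizon", "orchard")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], dict):
            d["effect"] = EffectConfig(**d["effect"])
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["tasks"] = list(self.tasks)
        return out


def _manifest(config: RunConfig, stage: str) -> dict:
    return {"package": "exploresim", "version": __version__, "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": config.to_dict()}


def run_simulate(config: RunConfig, outdir) -> dict[str, Path]:
    """Generate a cohort, simulate both tasks, and write the trial logs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.n_participants, config.effect,
                             seed=config.cohort_seed,
                             include_foraging="orchard" in config.tasks)
    logs = simulate_study(cohort, seed=config.study_seed, tasks=config.tasks)
    paths = {}
    tab = cohort_table(cohort)
    tab.to_csv(outdir / "cohort.csv", index=False)
    paths["cohort"] = outdir / "cohort.csv"
    for task, df in logs.items():
        path = outdir / f"{task}_trials.csv"
        df.to_csv(path, index=False)
        paths[task] = path
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_manifest(config, "simulate"), fh, indent=1)
    return paths


def compute_metrics(indir, config: RunConfig | None = None) -> pd.DataFrame:
    """Participant-level metric table from the trial logs in ``indir``."""
    indir = Path(indir)
    horizon = orchard = None
    hp, op = indir / "horizon_trials.csv", indir / "orchard_trials.csv"
    if hp.exists():
        horizon = pd.read_csv(hp)
    if op.exists():
        orchard = pd.read_csv(op)
    if horizon is None and orchard is None:
        raise FileNotFoundError(f"no trial logs found in {indir}")
    optimal = None
    if orchard is not None:
        optimal = {"rich": mvt_optimal_threshold(rich_config()),
                   "poor": mvt_optimal_threshold(poor_config())}
    return metrics_mod.participant_metrics(horizon, orchard, optimal)


def run_fits(indir, outdir, per_horizon: bool = True, seed: int = 0) -> Path:
    """Fit the choice model per participant; writes fits.csv."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = pd.read_csv(indir / "horizon_trials.csv")
    design = first_free_design(trials)
    rows = []
    for pid, sub in design.groupby("participant_id", sort=False):
        res = fit(sub, per_horizon=per_horizon, seed=seed,
                  participant_id=pid)
        p = res.params
        rows.append({"participant_id": pid,
                     "info_bonus_short": p.for_horizon("short")[0],
                     "info_bonus_long": p.for_horizon("long")[0],
                     "spatial_bias": p.spatial_bias,
                     "repeat_bonus": p.repeat_bonus,
                     "decision_noise_short": p.for_horizon("short")[2],
                     "decision_noise_long": p.for_horizon("long")[2],
                     "nll": res.negative_log_likelihood,
                     "n_trials": res.n_trials_used,
                     "converged": res.converged})
    path = outdir / "fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _result_to_dict(res: analysis.RegressionResult) -> dict:
    return {"method": res.method, "n_participants": res.n_participants,
            "n_trials": res.n_trials, "warnings": res.warnings,
            "terms": res.table.replace({np.nan: None}).to_dict("records")}


def run_analyze(indir, outdir, config: RunConfig | None = None) -> dict:
    """All analyses over previously simulated logs; writes CSVs + report."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    cohort_path = indir / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"missing {cohort_path}")
    participants = pd.read_csv(cohort_path)
    metric_table = compute_metrics(indir, config)
    metric_table.to_csv(outdir / "metrics.csv", index=False)
    merged = metric_table.merge(participants, on="participant_id")

    report: dict = {"information_gathering": {}, "foraging": {}}
    horizon_path = indir / "horizon_trials.csv"
    if horizon_path.exists():
        kept, excluded = metrics_mod.exclude_outliers(merged,
                                                      "p_explore_overall")
        report["information_gathering"]["excluded_participants"] = excluded
        reg = analysis.exploration_regression(kept)
        report["information_gathering"]["exploration_regression"] = \
            _result_to_dict(reg)
        trials = pd.read_csv(horizon_path)
        kept_trials = trials[~trials["participant_id"].isin(excluded)]
        table = metrics_mod.first_free_choice_table(kept_trials)
        for moderator, outcome in (("horizon", "explore"),
                                   ("conflict", "explore"),
                                   ("uncertainty", "habitual")):
            glmm = analysis.trial_glmm(table, participants, outcome=outcome,
                                       moderator=moderator)
            entry = _result_to_dict(glmm)
            entry["marginal_effects"] = [asdict(m) for m in
                                         analysis.marginal_effects(glmm)]
            report["information_gathering"][f"{outcome}_{moderator}_glmm"] = \
                entry
        med = analysis.mediate(kept, n_boot=config.n_boot,
                               seed=config.bootstrap_seed)
        report["information_gathering"]["mediation"] = asdict(med)

    orchard_path = indir / "orchard_trials.csv"
    if orchard_path.exists():
        kept_f, excluded_f = metrics_mod.exclude_outliers(
            merged.dropna(subset=["exit_threshold_rich"]),
            "exit_threshold_rich")
        report["foraging"]["excluded_participants"] = excluded_f
        foraging = pd.read_csv(orchard_path)
        foraging = foraging[~foraging["participant_id"].isin(excluded_f)]
        trees = metrics_mod.tree_exit_thresholds(foraging)
        env = analysis.environment_effect(trees, participants)
        report["foraging"]["environment_effect"] = _result_to_dict(env)
        opt = analysis.optimality_tests(kept_f)
        report["foraging"]["optimality_tests"] = opt.to_dict("records")

    with open(outdir / "report.json", "w") as fh:
        json.dump({"manifest": _manifest(config, "analyze"),
                   "results": report}, fh, indent=1, default=float)
    return report


def run_reproduce(config: RunConfig, outdir) -> dict:
    """simulate + analyze in one call; returns the report dict."""
    outdir = Path(outdir)
    run_simulate(config, outdir / "data")
    return run_analyze(outdir / "data", outdir / "results", config)
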