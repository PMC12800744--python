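"""End-to-end orchestration: task -> behaviour -> fits -> BMS -> EEG -> GLM.

Each stage writes plain TSV/JSON (plus one compressed array container per
EEG dataset) into the output directory and a marker file recording the
config hash and derived seed, so re-runs with ``resume=True`` skip stages
whose inputs have not changed.  All randomness derives from a single
master seed via stable per-stage offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import responses
from .eeg import EEGDataset, make_covariates, make_layout, synthesize_eeg
from .evaluation import parameter_recovery, rfx_bms
from .fitting import default_priors, fit_bayes_optimal, fit_map, from_unconstrained
from .glm import (DESIGNS, GLMDesign, covariate_correlation, first_level,
                  group_test, latency_order, phase_erps)
from .hgf import VARIANTS, ModelParams, filter_beliefs, regressor_table
from .task import TaskConfig, TaskSchedule, make_schedule

log = logging.getLogger("socialhgf")

STAGES = ("schedule", "behavior", "fit", "bms", "recover", "eeg", "glm", "report")


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(self.errors))


@dataclass
class RunConfig:
    """Validated pipeline settings (defaults emulate the published cohort)."""

    cohort_size: int = 43
    master_seed: int = 1
    variants: tuple[str, ...] = VARIANTS
    generating_variant: str = "mean_reverting"
    n_perm: int = 1000
    n_bms_samples: int = 200_000
    fit_restarts: int = 3
    fit_max_evals: int = 1500
    recovery_subjects: int = 43
    run_recovery: bool = True
    run_eeg: bool = True
    eeg_noise: tuple[float, float, float] = (0.2, 20.0, 8.0)
    glm_window: tuple[float, float] = (100.0, 550.0)
    cluster_p: float = 0.001
    task: TaskConfig = field(default_factory=TaskConfig)

    def validate(self) -> list[str]:
        errors = []
        if self.cohort_size < 1:
            errors.append("cohort_size must be >= 1")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        if self.n_bms_samples < 1000:
            errors.append("n_bms_samples must be >= 1000")
        if len(set(self.variants)) != len(self.variants):
            errors.append("duplicate model variant in variants")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            errors.append(f"unknown variants: {sorted(unknown)}")
        if self.generating_variant not in VARIANTS:
            errors.append(f"unknown generating_variant {self.generating_variant!r}")
        if not 0 < self.cluster_p < 1:
            errors.append("cluster_p must lie in (0, 1)")
        if self.recovery_subjects < 2:
            errors.append("recovery_subjects must be >= 2")
        return errors

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        d["eeg_noise"] = list(self.eeg_noise)
        d["glm_window"] = list(self.glm_window)
        d["task"] = asdict(self.task)
        d["task"]["phase_lengths"] = list(self.task.phase_lengths)
        d["task"]["volatile_block_length_range"] = list(
            self.task.volatile_block_length_range)
        d["task"]["cue_prob_set"] = list(self.task.cue_prob_set)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse a YAML/JSON config file into a RunConfig, strictly.

    Unknown keys and invalid values are collected and reported together in
    a :class:`ConfigError`.
    """
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    errors = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    errors.extend(f"unknown key: {k}" for k in sorted(unknown))
    kwargs = {k: v for k, v in raw.items() if k in known}
    task_raw = kwargs.pop("task", {})
    if not isinstance(task_raw, dict):
        errors.append("task must be a mapping")
        task_raw = {}
    task_known = set(TaskConfig.__dataclass_fields__)
    errors.extend(f"unknown key: task.{k}" for k in sorted(set(task_raw) - task_known))
    task_raw = {k: v for k, v in task_raw.items() if k in task_known}
    for tup_key in ("phase_lengths", "volatile_block_length_range", "cue_prob_set"):
        if tup_key in task_raw:
            task_raw[tup_key] = tuple(task_raw[tup_key])
    for tup_key in ("variants", "eeg_noise", "glm_window"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    try:
        task = TaskConfig(**task_raw)
    except (TypeError, ValueError) as e:
        errors.append(f"task: {e}")
        task = TaskConfig()
    try:
        cfg = RunConfig(task=task, **kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(errors + [str(e)])
    errors.extend(cfg.validate())
    if errors:
        raise ConfigError(errors)
    return cfg


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return int((master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31))


def _marker(outdir: Path, stage: str) -> Path:
    return outdir / f".{stage}.done.json"


def _stage_fresh(outdir: Path, stage: str, cfg_hash: str,
                 outputs: list[Path]) -> bool:
    m = _marker(outdir, stage)
    if not m.exists():
        return False
    try:
        info = json.loads(m.read_text())
    except json.JSONDecodeError:
        return False
    return info.get("config_hash") == cfg_hash and all(p.exists() for p in outputs)


def _finish(outdir: Path, stage: str, cfg_hash: str, seed: int, t0: float):
    wall = time.perf_counter() - t0
    _marker(outdir, stage).write_text(json.dumps(
        {"config_hash": cfg_hash, "seed": seed, "wall_s": round(wall, 3)}))
    log.info("stage=%s seed=%d wall=%.2fs", stage, seed, wall)


def stage_schedule(cfg: RunConfig, outdir: Path) -> TaskSchedule:
    seed = derive_seed(cfg.master_seed, "schedule")
    schedule = make_schedule(cfg.task.with_seed(seed))
    schedule.to_tsv(outdir / "schedule.tsv")
    (outdir / "task_config.json").write_text(
        json.dumps({**cfg.to_dict()["task"], "seed": seed}, indent=2))
    return schedule


def stage_behavior(cfg: RunConfig, outdir: Path,
                   schedule: TaskSchedule) -> pd.DataFrame:
    """Draw a synthetic cohort from the priors and simulate its choices."""
    seed = derive_seed(cfg.master_seed, "behavior")
    rng = np.random.default_rng(seed)
    priors = default_priors(cfg.generating_variant)
    names = priors.free_names
    rows, choice_rows = [], []
    s = 0
    while s < cfg.cohort_size:
        x = priors.means() + priors.sds() * rng.standard_normal(len(names))
        params = from_unconstrained(x, priors,
                                    ModelParams(variant=cfg.generating_variant))
        try:
            sim = responses.simulate_choices(params, schedule,
                                             seed=int(rng.integers(2**31)))
        except (FloatingPointError, RuntimeError):
            continue
        rows.append({"subject": s, **{k: getattr(params, k) for k in names}})
        for _, r in sim.iterrows():
            choice_rows.append({"subject": s, "trial": int(r["trial"]),
                                "p_follow": r["p_follow"], "y": int(r["y"])})
        s += 1
    pd.DataFrame(rows).to_csv(outdir / "cohort_params.tsv", sep="\t", index=False)
    choices = pd.DataFrame(choice_rows)
    choices.to_csv(outdir / "choices.tsv", sep="\t", index=False)
    return choices


def stage_fit(cfg: RunConfig, outdir: Path, schedule: TaskSchedule,
              choices: pd.DataFrame) -> pd.DataFrame:
    seed = derive_seed(cfg.master_seed, "fit")
    rng = np.random.default_rng(seed)
    bayes_base = {v: fit_bayes_optimal(schedule.u, v)
                  for v in cfg.variants if v.startswith("bayes_optimal")}
    rows = []
    param_names = ("kappa2", "omega2", "m3", "mu2_0", "mu3_0", "zeta", "nu")
    for s, grp in choices.groupby("subject"):
        y = grp.sort_values("trial")["y"].to_numpy()
        for variant in cfg.variants:
            fit = fit_map(schedule, y, variant,
                          n_restarts=cfg.fit_restarts,
                          seed=int(rng.integers(2**31)),
                          max_evals=cfg.fit_max_evals,
                          base_params=bayes_base.get(variant))
            rows.append({
                "subject": s, "variant": variant,
                **{k: getattr(fit.map_estimates, k) for k in param_names},
                "neg_log_joint": fit.neg_log_joint,
                "log_evidence": fit.log_evidence,
                "evidence_method": fit.evidence_method,
                "converged": fit.converged,
            })
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "fits.tsv", sep="\t", index=False)
    return fits


def stage_bms(cfg: RunConfig, outdir: Path, fits: pd.DataFrame) -> dict:
    seed = derive_seed(cfg.master_seed, "bms")
    L = fits.pivot(index="subject", columns="variant",
                   values="log_evidence")[list(cfg.variants)]
    result = rfx_bms(L.to_numpy(), n_samples=cfg.n_bms_samples, seed=seed,
                     model_names=tuple(cfg.variants))
    out = {
        "models": list(cfg.variants),
        "frequencies": result.frequencies.tolist(),
        "exceedance": result.exceedance.tolist(),
        "bor": result.bor,
        "pep": result.pep.tolist(),
        "winner": cfg.variants[result.winner],
    }
    (outdir / "bms.json").write_text(json.dumps(out, indent=2))
    return out


def stage_recovery(cfg: RunConfig, outdir: Path,
                   schedule: TaskSchedule) -> dict:
    seed = derive_seed(cfg.master_seed, "recover")
    report = parameter_recovery(cfg.recovery_subjects,
                                variant=cfg.generating_variant, seed=seed,
                                schedule=schedule,
                                n_restarts=cfg.fit_restarts,
                                max_evals=cfg.fit_max_evals)
    report.estimates.to_csv(outdir / "recovery_estimates.tsv", sep="\t",
                            index=False)
    report.truths.to_csv(outdir / "recovery_truths.tsv", sep="\t", index=False)
    out = {
        "recovery_r": report.recovery_r.round(4).to_dict(),
        "estimate_corr": report.estimate_corr.round(4).to_dict(),
        "n_failed": report.n_failed,
    }
    (outdir / "recovery.json").write_text(json.dumps(out, indent=2))
    return out


def _fitted_regressors(cfg: RunConfig, schedule: TaskSchedule,
                       fits: pd.DataFrame, winner: str):
    tables = []
    sub = fits[fits["variant"] == winner].sort_values("subject")
    for _, row in sub.iterrows():
        params = ModelParams(
            kappa2=row["kappa2"], omega2=row["omega2"], m3=row["m3"],
            mu2_0=row["mu2_0"], mu3_0=row["mu3_0"], zeta=row["zeta"],
            nu=row["nu"], variant=winner if not winner.startswith("bayes_optimal")
            else "mean_reverting",
        )
        traj = filter_beliefs(params, schedule.u)
        table, _ = regressor_table(traj, schedule, params.zeta)
        tables.append(table)
    return tables


def stage_eeg(cfg: RunConfig, outdir: Path, schedule: TaskSchedule,
              fits: pd.DataFrame, winner: str) -> EEGDataset:
    seed = derive_seed(cfg.master_seed, "eeg")
    layout = make_layout()
    tables = _fitted_regressors(cfg, schedule, fits, winner)
    covariates = make_covariates(len(tables), seed=derive_seed(
        cfg.master_seed, "covariates"))
    dataset = synthesize_eeg(tables, layout=layout, phases=schedule.phase,
                             covariates=covariates, noise=cfg.eeg_noise,
                             seed=seed)
    dataset.save(outdir / "eeg_dataset.npz")
    covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    long = pd.concat(
        [t.assign(subject=i, trial=np.arange(1, len(t) + 1))
         for i, t in enumerate(tables)], ignore_index=True)
    long.to_csv(outdir / "regressors.tsv", sep="\t", index=False)
    return dataset


def stage_glm(cfg: RunConfig, outdir: Path, dataset: EEGDataset) -> dict:
    seed = derive_seed(cfg.master_seed, "glm")
    rng = np.random.default_rng(seed)
    results = {}
    pair_corrs = {}
    beta_store = {}
    for design_name, pair in DESIGNS.items():
        design = GLMDesign(design_name, pair)
        betas, _, pc = first_level(dataset, design)
        pair_corrs[design_name] = float(np.mean(pc))
        for j, reg in enumerate(pair):
            beta_store[reg] = betas[:, j]
            results[reg] = group_test(
                betas[:, j], dataset.times, dataset.layout,
                n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
                window=cfg.glm_window, cluster_p=cfg.cluster_p)
    ordered, missing = latency_order(results)
    ordered_peak, _ = latency_order(results, criterion="peak")
    _, contrasts = phase_erps(dataset, n_perm=cfg.n_perm,
                              seed=int(rng.integers(2**31)),
                              window=cfg.glm_window)
    cov = covariate_correlation(
        beta_store["pi2"], dataset.covariates["gf_social"], dataset.times,
        dataset.layout, n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
        window=cfg.glm_window)

    clusters = pd.concat(
        [r.clusters.assign(regressor=name) for name, r in results.items()
         if len(r.clusters)], ignore_index=True) if results else pd.DataFrame()
    if len(clusters):
        clusters.to_csv(outdir / "glm_clusters.tsv", sep="\t", index=False)
    out = {
        "pair_correlations": pair_corrs,
        "latency_order": ordered,
        "latency_order_peak": ordered_peak,
        "not_detected": missing,
        "phase_contrasts": {
            k: {"significant": bool(r.significant),
                "peak_time_ms": r.peak_time_ms,
                "peak_channel": r.peak_channel,
                "peak_f": r.peak_f}
            for k, r in contrasts.items()},
        "covariate_pi2_gf_social": {
            "significant": bool(cov.mask.any()),
            "peak_time_ms": cov.peak_time_ms,
            "peak_t": cov.peak_t,
        },
        "regressor_peaks": {
            k: {"peak_time_ms": r.peak_time_ms, "peak_channel": r.peak_channel,
                "peak_f": r.peak_f, "significant": bool(r.significant)}
            for k, r in results.items()},
    }
    (outdir / "glm_summary.json").write_text(json.dumps(out, indent=2))
    return out


def stage_report(cfg: RunConfig, outdir: Path, bms: dict, recovery: dict | None,
                 glm: dict | None) -> dict:
    summary = {
        "config_hash": cfg.hash(),
        "master_seed": cfg.master_seed,
        "winning_model": bms["winner"],
        "pep": dict(zip(bms["models"], bms["pep"])),
        "model_frequencies": dict(zip(bms["models"], bms["frequencies"])),
        "recovery": recovery,
        "glm": glm,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    lines = [
        f"socialhgf pipeline summary (seed {cfg.master_seed}, "
        f"config {cfg.hash()})",
        f"winning model: {bms['winner']} "
        f"(PEP {max(bms['pep']):.3f}, f {max(bms['frequencies']):.3f})",
    ]
    if recovery:
        lines.append("recovery r: " + ", ".join(
            f"{k}={v:.2f}" for k, v in recovery["recovery_r"].items()))
    if glm:
        lines.append("latency ordering: " + " -> ".join(
            f"{k}@{t:.0f}ms" for k, t in glm["latency_order"]))
        if glm["not_detected"]:
            lines.append("not detected: " + ", ".join(glm["not_detected"]))
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary


def run_pipeline(cfg: RunConfig, outdir, resume: bool = False) -> dict:
    """Execute all stages; raises on the first stage failure."""
    errors = cfg.validate()
    if errors:
        raise ConfigError(errors)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    (outdir / "run_config.json").write_text(json.dumps(cfg.to_dict(), indent=2))

    def run(stage, fn, outputs, loader=None):
        t0 = time.perf_counter()
        paths = [outdir / o for o in outputs]
        if resume and loader and _stage_fresh(outdir, stage, cfg_hash, paths):
            log.info("stage=%s skipped (resume)", stage)
            return loader()
        try:
            result = fn()
        except Exception:
            log.exception("stage=%s failed", stage)
            raise
        _finish(outdir, stage, cfg_hash, derive_seed(cfg.master_seed, stage), t0)
        return result

    schedule = run("schedule", lambda: stage_schedule(cfg, outdir),
                   ["schedule.tsv"],
                   lambda: TaskSchedule.from_tsv(outdir / "schedule.tsv"))
    choices = run("behavior", lambda: stage_behavior(cfg, outdir, schedule),
                  ["choices.tsv"],
                  lambda: pd.read_csv(outdir / "choices.tsv", sep="\t"))
    fits = run("fit", lambda: stage_fit(cfg, outdir, schedule, choices),
               ["fits.tsv"],
               lambda: pd.read_csv(outdir / "fits.tsv", sep="\t"))
    bms = run("bms", lambda: stage_bms(cfg, outdir, fits), ["bms.json"],
              lambda: json.loads((outdir / "bms.json").read_text()))
    recovery = None
    if cfg.run_recovery:
        recovery = run("recover", lambda: stage_recovery(cfg, outdir, schedule),
                       ["recovery.json"],
                       lambda: json.loads((outdir / "recovery.json").read_text()))
    glm_summary = None
    if cfg.run_eeg:
        dataset = run("eeg",
                      lambda: stage_eeg(cfg, outdir, schedule, fits,
                                        bms["winner"]),
                      ["eeg_dataset.npz"],
                      lambda: EEGDataset.load(outdir / "eeg_dataset.npz"))
        if not dataset.regressors:
            dataset.regressors = _fitted_regressors(cfg, schedule, fits,
                                                    bms["winner"])
        glm_summary = run("glm", lambda: stage_glm(cfg, outdir, dataset),
                          ["glm_summary.json"],
                          lambda: json.loads(
                              (outdir / "glm_summary.json").read_text()))
    return run("report",
               lambda: stage_report(cfg, outdir, bms, recovery, glm_summary),
               ["summary.json"],
               lambda: json.loads((outdir / "summary.json").read_text()))
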