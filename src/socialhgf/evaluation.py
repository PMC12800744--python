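"""Random-effects Bayesian model selection and recovery harnesses.

``rfx_bms`` implements the variational Dirichlet scheme for group-level
model comparison: per-subject log evidences are combined into posterior
model frequencies, exceedance probabilities are obtained by Monte-Carlo
sampling of the Dirichlet posterior, and the Bayes omnibus risk (the
posterior probability that all models are equally frequent) protects the
exceedance probabilities against chance differences:
PEP = (1 - BOR) * EP + BOR / K.

The recovery harnesses close the loop on the generative model: parameters
are drawn from the priors, choices simulated on the task schedule, models
refit, and truth-vs-estimate structure reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi
from scipy.stats import kendalltau, pearsonr

from . import responses
from .fitting import (PriorSpec, default_priors, fit_bayes_optimal, fit_map,
                      from_unconstrained)
from .hgf import VARIANTS, ModelParams
from .task import TaskConfig, TaskSchedule, make_schedule

__all__ = [
    "BMSResult",
    "RecoveryReport",
    "rfx_bms",
    "parameter_recovery",
    "model_recovery",
    "kendall_tau",
]


@dataclass
class BMSResult:
    alpha: np.ndarray
    frequencies: np.ndarray
    exceedance: np.ndarray
    bor: float
    pep: np.ndarray
    model_names: tuple[str, ...] = ()

    @property
    def winner(self) -> int:
        return int(np.argmax(self.pep))


def _dirichlet_vb(L: np.ndarray, tol: float = 1e-6, max_iter: int = 10_000):
    """Variational posterior Dirichlet(alpha) over model frequencies."""
    n, K = L.shape
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = L + (psi(alpha) - psi(alpha.sum()))
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    logu = L + (psi(alpha) - psi(alpha.sum()))
    g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
    return alpha, g


def _free_energy(L: np.ndarray, alpha: np.ndarray, g: np.ndarray) -> float:
    """Variational free energy of the random-effects model."""
    K = L.shape[1]
    alpha0 = np.ones(K)
    Elogr = psi(alpha) - psi(alpha.sum())
    # entropy of q(r) and q(m)
    Sqf = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1) * Elogr).sum()
    Sqm = -np.sum(g * np.log(g + 1e-300))
    ELJ = gammaln(alpha0.sum()) - gammaln(alpha0).sum() + ((alpha0 - 1) * Elogr).sum()
    ELJ += np.sum(g * (Elogr[None, :] + L))
    return float(ELJ + Sqf + Sqm)


def _null_free_energy(L: np.ndarray) -> float:
    """Evidence of the null model: frequencies fixed and equal (1/K)."""
    K = L.shape[1]
    return float(np.sum(logsumexp(L - np.log(K), axis=1)))


def rfx_bms(log_evidence, n_samples: int = 1_000_000, seed: int = 0,
            model_names=()) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models
    evidence matrix."""
    L = np.asarray(log_evidence, dtype=np.float64)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 models) evidence matrix")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    alpha, g = _dirichlet_vb(L)
    freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_samples))
    # tie-safe argmax (ties are measure-zero for continuous alpha anyway)
    ep = np.bincount(np.argmax(samples, axis=1), minlength=L.shape[1]) / n_samples

    f1 = _free_energy(L, alpha, g)
    f0 = _null_free_energy(L)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pep = (1.0 - bor) * ep + bor / L.shape[1]
    return BMSResult(alpha=alpha, frequencies=freq, exceedance=ep, bor=bor,
                     pep=pep, model_names=tuple(model_names))


@dataclass
class RecoveryReport:
    truths: pd.DataFrame
    estimates: pd.DataFrame
    recovery_r: pd.Series
    estimate_corr: pd.DataFrame
    n_failed: int = 0
    confusion: pd.DataFrame | None = None
    bms: dict = field(default_factory=dict)


def _draw_subject(rng: np.random.Generator, priors: PriorSpec,
                  variant: str) -> tuple[ModelParams, np.ndarray]:
    x = priors.means() + priors.sds() * rng.standard_normal(len(priors.free_names))
    return from_unconstrained(x, priors, ModelParams(variant=variant)), x


def parameter_recovery(n_subjects: int, variant: str = "mean_reverting",
                       priors: PriorSpec | None = None, seed: int = 0,
                       schedule: TaskSchedule | None = None,
                       n_restarts: int = 3, max_evals: int = 1500,
                       max_redraws: int = 50) -> RecoveryReport:
    """Draw subjects from the priors, simulate choices, refit, and report
    truth-vs-estimate correlations and estimate interdependencies.

    Parameter draws whose trajectories diverge (extreme volatility) are
    redrawn; refits that fail outright are excluded and counted.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    priors = priors or default_priors(variant)
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = make_schedule(TaskConfig(seed=int(rng.integers(2**31))))
    names = priors.free_names
    truths, estimates = [], []
    n_failed = 0
    for s in range(n_subjects):
        for _ in range(max_redraws):
            params, x_true = _draw_subject(rng, priors, variant)
            try:
                sim = responses.simulate_choices(
                    params, schedule, seed=int(rng.integers(2**31)))
                break
            except (FloatingPointError, RuntimeError, OverflowError):
                continue
        else:
            n_failed += 1
            continue
        try:
            fit = fit_map(schedule, sim["y"].to_numpy(), variant,
                          priors=priors, n_restarts=n_restarts,
                          seed=int(rng.integers(2**31)), max_evals=max_evals)
        except Exception:
            n_failed += 1
            continue
        truths.append(x_true)
        estimates.append(fit.map_transformed)

    truths = pd.DataFrame(truths, columns=names)
    estimates = pd.DataFrame(estimates, columns=names)
    recovery_r = pd.Series(
        {k: pearsonr(truths[k], estimates[k]).statistic for k in names},
        name="recovery_r",
    )
    estimate_corr = estimates.corr()
    return RecoveryReport(truths=truths, estimates=estimates,
                          recovery_r=recovery_r, estimate_corr=estimate_corr,
                          n_failed=n_failed)


def model_recovery(n_subjects: int, seed: int = 0,
                   generating=("standard", "mean_reverting"),
                   fit_variants=VARIANTS,
                   schedule: TaskSchedule | None = None,
                   n_restarts: int = 3, max_evals: int = 1500,
                   n_samples: int = 200_000) -> RecoveryReport:
    """Simulate cohorts from each generating variant, fit all candidate
    variants, run group BMS per condition, and report the winner table."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = make_schedule(TaskConfig(seed=int(rng.integers(2**31))))
    bayes_base = {}

    def generating_params(variant, prng):
        if variant.startswith("bayes_optimal"):
            if variant not in bayes_base:
                bayes_base[variant] = fit_bayes_optimal(schedule.u, variant)
            base = bayes_base[variant]
            resp = PriorSpec({k: default_priors("mean_reverting")[k]
                              for k in ("zeta", "nu")})
            drawn, _ = _draw_subject(prng, resp, base.variant)
            return base.replace(zeta=drawn.zeta, nu=drawn.nu)
        params, _ = _draw_subject(prng, default_priors(variant), variant)
        return params

    confusion = pd.DataFrame(0, index=list(generating),
                             columns=list(fit_variants))
    bms_results = {}
    for gen in generating:
        L = np.zeros((n_subjects, len(fit_variants)))
        s = 0
        attempts = 0
        while s < n_subjects and attempts < 50 * n_subjects:
            attempts += 1
            try:
                params = generating_params(gen, rng)
                sim = responses.simulate_choices(
                    params, schedule, seed=int(rng.integers(2**31)))
            except (FloatingPointError, RuntimeError, OverflowError):
                continue
            y = sim["y"].to_numpy()
            for j, fv in enumerate(fit_variants):
                fit = fit_map(schedule, y, fv, n_restarts=n_restarts,
                              seed=int(rng.integers(2**31)),
                              max_evals=max_evals,
                              base_params=bayes_base.get(fv))
                L[s, j] = fit.log_evidence
            s += 1
        result = rfx_bms(L, n_samples=n_samples,
                         seed=int(rng.integers(2**31)),
                         model_names=tuple(fit_variants))
        bms_results[gen] = result
        confusion.loc[gen, fit_variants[result.winner]] += 1

    empty = pd.DataFrame()
    return RecoveryReport(truths=empty, estimates=empty,
                          recovery_r=pd.Series(dtype=float),
                          estimate_corr=empty, confusion=confusion,
                          bms=bms_results)


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall's tau-b with its p-value.

    Uses exact enumeration of the null distribution for n <= 9 (valid in
    the absence of ties) and the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied vector has undefined tau")
    has_ties = (len(np.unique(x)) < len(x)) or (len(np.unique(y)) < len(y))
    method = "exact" if (len(x) <= 9 and not has_ties) else "asymptotic"
    res = kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)
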