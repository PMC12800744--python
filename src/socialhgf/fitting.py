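"""MAP estimation, Laplace model evidence and ideal-observer null models.

Free parameters are estimated in an unconstrained space (kappa2 via log,
zeta via logit, the rest via identity) under independent Gaussian priors in
that space.  The negative log joint (Bernoulli choice likelihood plus prior
density, including normalisation constants) is minimised by derivative-free
simplex search from several jittered starts.  Log model evidence is
approximated by a Laplace integral at the MAP, with a finite-difference
Hessian; when the Hessian is not positive definite a BIC-style penalty is
used instead and the substitution is recorded in the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hgf import ModelParams, _loglik_loop, _surprise_loop
from .task import TaskSchedule

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "FitResult",
    "default_priors",
    "to_unconstrained",
    "from_unconstrained",
    "fit_map",
    "laplace_evidence",
    "fit_bayes_optimal",
]

_LN2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ParamPrior:
    transform: str  # identity | log | logit
    mean: float     # in transformed space
    variance: float
    fixed: bool = False

    def __post_init__(self):
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.fixed and self.variance <= 0:
            raise ValueError("free parameters need positive prior variance")


def _fwd(value: float, transform: str) -> float:
    if transform == "identity":
        return value
    if transform == "log":
        if value <= 0:
            raise ValueError("log transform needs a positive value")
        return math.log(value)
    if value <= 0.0 or value >= 1.0:
        raise ValueError("logit transform needs a value in (0, 1)")
    return math.log(value / (1.0 - value))


def _inv(x: float, transform: str) -> float:
    if transform == "identity":
        return x
    if transform == "log":
        return math.exp(x)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class PriorSpec:
    """Priors over model parameters, keyed by parameter name.

    ``free_names`` fixes the parameter ordering used by the unconstrained
    vector representation.
    """

    priors: dict[str, ParamPrior]

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(k for k, p in self.priors.items() if not p.fixed)

    def __getitem__(self, name: str) -> ParamPrior:
        return self.priors[name]

    def means(self) -> np.ndarray:
        return np.array([self.priors[k].mean for k in self.free_names])

    def sds(self) -> np.ndarray:
        return np.sqrt([self.priors[k].variance for k in self.free_names])


#: weakly informative toolbox-style defaults (transformed space)
_DEFAULTS = {
    "kappa2": ParamPrior("log", math.log(1.0), 0.25),
    "omega2": ParamPrior("identity", -3.0, 16.0),
    "m3": ParamPrior("identity", 1.0, 1.0),
    "mu2_0": ParamPrior("identity", 0.0, 1.0),
    "mu3_0": ParamPrior("identity", 1.0, 1.0),
    "zeta": ParamPrior("logit", 0.0, 1.0),
    "nu": ParamPrior("identity", 2.0, 4.0),
}

_PERCEPTUAL = ("kappa2", "omega2", "m3", "mu2_0", "mu3_0")


def default_priors(variant: str = "mean_reverting") -> PriorSpec:
    """Default priors; the free set depends on the model variant.

    The mean-reverting HGF frees seven parameters (kappa2, omega2, m3,
    mu2_0, mu3_0, zeta, nu); the standard HGF has no m3; the Bayes-optimal
    null models free only the response parameters zeta and nu.
    """
    priors = {}
    for name, p in _DEFAULTS.items():
        if name == "m3" and variant != "mean_reverting":
            continue
        fixed = variant.startswith("bayes_optimal") and name not in ("zeta", "nu")
        priors[name] = ParamPrior(p.transform, p.mean, p.variance, fixed=fixed)
    return PriorSpec(priors)


def to_unconstrained(params: ModelParams, priors: PriorSpec) -> np.ndarray:
    return np.array(
        [_fwd(getattr(params, k), priors[k].transform) for k in priors.free_names]
    )


def from_unconstrained(x: np.ndarray, priors: PriorSpec,
                       base: ModelParams | None = None) -> ModelParams:
    base = base or ModelParams()
    updates = {
        k: _inv(float(v), priors[k].transform)
        for k, v in zip(priors.free_names, x)
    }
    return base.replace(**updates)


@dataclass
class FitResult:
    map_estimates: ModelParams
    map_transformed: np.ndarray
    free_names: tuple[str, ...]
    neg_log_joint: float
    log_evidence: float
    hessian: np.ndarray = field(repr=False)
    hessian_cond: float
    evidence_method: str  # "laplace" or "bic"
    n_restarts_used: int
    converged: bool
    n_trials: int


def _make_objective(schedule: TaskSchedule, y: np.ndarray, base: ModelParams,
                    priors: PriorSpec):
    u, c = schedule.u, schedule.c
    names = priors.free_names
    means = priors.means()
    variances = np.array([priors[k].variance for k in names])
    log_norm = 0.5 * np.sum(_LN2PI + np.log(variances))
    mr = base.mean_reverting
    vals = {k: getattr(base, k) for k in
            ("kappa2", "omega2", "theta", "phi3", "m3",
             "mu2_0", "sigma2_0", "mu3_0", "sigma3_0", "zeta", "nu")}
    transforms = [priors[k].transform for k in names]

    def objective(x: np.ndarray) -> float:
        v = dict(vals)
        for k, tr, xi in zip(names, transforms, x):
            v[k] = _inv(float(xi), tr)
        ll = _loglik_loop(
            u, c, y, v["kappa2"], v["omega2"], v["theta"], v["phi3"],
            v["m3"], v["mu2_0"], v["sigma2_0"], v["mu3_0"], v["sigma3_0"],
            v["zeta"], v["nu"], mr,
        )
        if not np.isfinite(ll):
            return 1e10
        prior_pen = 0.5 * np.sum((x - means) ** 2 / variances) + log_norm
        return -ll + prior_pen

    return objective


_WALL = 1e9  # objective values above this mark a filter-divergence wall


def _fd_hessian(f, x: np.ndarray, prior_var: np.ndarray | None = None,
                rel_step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian, robust to divergence walls.

    The MAP can sit close to the region where the filter diverges (the
    objective returns a huge sentinel there).  Steps that hit the wall are
    shrunk; coordinates that remain unusable fall back to the prior
    curvature on the diagonal, which keeps the Laplace evidence finite and
    comparable across models.
    """
    d = len(x)
    if prior_var is None:
        prior_var = np.ones(d)
    h = rel_step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    good = np.ones(d, dtype=bool)
    for i in range(d):
        for _ in range(4):
            ei = np.zeros(d)
            ei[i] = h[i]
            if f(x + ei) < _WALL and f(x - ei) < _WALL:
                break
            h[i] /= 4.0
        else:
            good[i] = False
    H = np.zeros((d, d))
    for i in range(d):
        if not good[i]:
            H[i, i] = 1.0 / prior_var[i]
            continue
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            if not good[j]:
                continue
            ej = np.zeros(d)
            ej[j] = h[j]
            vals = (f(x + ei + ej), f(x + ei - ej),
                    f(x - ei + ej), f(x - ei - ej))
            if max(vals) >= _WALL:
                continue  # leave the cross term at zero
            H[i, j] = H[j, i] = (
                vals[0] - vals[1] - vals[2] + vals[3]
            ) / (4.0 * h[i] * h[j])
    return H


#: eigenvalue clamp for the MAP Hessian — curvature below the weakest prior
#: curvature or above the wall scale is numerically untrustworthy
_EIG_FLOOR = 1e-3
_EIG_CAP = 1e7


def _evidence_from_hessian(nlj: float, H: np.ndarray, n_trials: int):
    d = H.shape[0]
    if d == 0:
        return -nlj, "laplace", 1.0
    eigs = np.linalg.eigvalsh(H)
    if np.all(eigs > 0) and eigs[0] >= _EIG_FLOOR and eigs[-1] <= _EIG_CAP:
        sign, logdet = np.linalg.slogdet(H)
        cond = float(eigs[-1] / eigs[0])
        return -nlj + 0.5 * d * _LN2PI - 0.5 * logdet, "laplace", cond
    clamped = np.clip(eigs, _EIG_FLOOR, _EIG_CAP)
    logdet = float(np.sum(np.log(clamped)))
    cond = float(clamped[-1] / clamped[0])
    return -nlj + 0.5 * d * _LN2PI - 0.5 * logdet, "laplace_clamped", cond


def fit_map(schedule: TaskSchedule, choices, variant: str = "mean_reverting",
            priors: PriorSpec | None = None, n_restarts: int = 5,
            seed: int = 0, base_params: ModelParams | None = None,
            max_evals: int = 2000) -> FitResult:
    """MAP fit of the chosen model variant to one subject's choices.

    ``n_restarts`` simplex searches are run: the first from the prior
    means, the rest from jittered starts (half a prior SD).  Deterministic
    under a fixed seed.  For Bayes-optimal variants the perceptual
    parameters are first optimised on the inputs alone (see
    :func:`fit_bayes_optimal`) and only zeta and nu are fitted.
    """
    y = np.asarray(choices, dtype=np.float64).ravel()
    if len(y) != len(schedule):
        raise ValueError("choices and schedule differ in length")
    if y.size and not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("choices must be binary (0/1)")
    priors = priors or default_priors(variant)
    if base_params is None:
        if variant.startswith("bayes_optimal"):
            base_params = fit_bayes_optimal(schedule.u, variant)
        else:
            base_params = ModelParams(variant=variant)
    base_params = base_params.replace(variant=variant)
    objective = _make_objective(schedule, y, base_params, priors)

    names = priors.free_names
    d = len(names)
    means, sds = priors.means(), priors.sds()
    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    for r in range(max(1, n_restarts)):
        x0 = means if r == 0 else means + 0.5 * sds * rng.standard_normal(d)
        if d == 0:
            best = (objective(np.array([])), np.array([]), True)
            n_converged = 1
            break
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"fatol": 1e-6, "xatol": 1e-6,
                                "maxfev": max_evals, "maxiter": max_evals})
        n_converged += bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x, float), bool(res.success))
    nlj, x_map, _ = best
    converged = n_converged > 0
    if not converged:
        warnings.warn("no restart converged; returning best point found")

    prior_var = np.array([priors[k].variance for k in names])
    H = _fd_hessian(objective, x_map, prior_var) if d else np.zeros((0, 0))
    log_ev, method, cond = _evidence_from_hessian(nlj, H, len(y))
    return FitResult(
        map_estimates=from_unconstrained(x_map, priors, base_params),
        map_transformed=x_map,
        free_names=names,
        neg_log_joint=nlj,
        log_evidence=float(log_ev),
        hessian=H,
        hessian_cond=cond,
        evidence_method=method,
        n_restarts_used=max(1, n_restarts),
        converged=converged,
        n_trials=len(y),
    )


def laplace_evidence(fit: FitResult) -> float:
    """Laplace log evidence recomputed from the stored fit diagnostics."""
    log_ev, _, _ = _evidence_from_hessian(fit.neg_log_joint, fit.hessian,
                                          fit.n_trials)
    return float(log_ev)


def fit_bayes_optimal(inputs, variant: str = "bayes_optimal_mean_reverting",
                      priors: PriorSpec | None = None, n_restarts: int = 3,
                      seed: int = 0, max_evals: int = 2000) -> ModelParams:
    """Ideal-observer perceptual parameters for an input sequence.

    Minimises the total Bernoulli surprise of the inputs under the filter
    (plus the perceptual priors), yielding the perceptual parameters of the
    'null' models in which behaviour is explained by zeta and nu alone.
    """
    u = np.asarray(inputs, dtype=np.float64).ravel()
    if u.size and not np.all((u == 0.0) | (u == 1.0)):
        raise ValueError("inputs must be binary (0/1)")
    if u.size and (u.min() == u.max()):
        warnings.warn("degenerate input sequence (all identical)")
    mr = variant in ("mean_reverting", "bayes_optimal_mean_reverting")
    base_variant = "mean_reverting" if mr else "standard"
    spec = priors or default_priors(base_variant)
    names = tuple(k for k in spec.free_names if k in _PERCEPTUAL)
    sub = PriorSpec({k: spec[k] for k in names})
    means, sds = sub.means(), sub.sds()
    base = ModelParams(variant=base_variant)
    transforms = [sub[k].transform for k in names]
    variances = sds ** 2

    def objective(x):
        v = {k: getattr(base, k) for k in
             ("kappa2", "omega2", "theta", "phi3", "m3",
              "mu2_0", "sigma2_0", "mu3_0", "sigma3_0")}
        for k, tr, xi in zip(names, transforms, x):
            v[k] = _inv(float(xi), tr)
        s = _surprise_loop(u, v["kappa2"], v["omega2"], v["theta"], v["phi3"],
                           v["m3"], v["mu2_0"], v["sigma2_0"], v["mu3_0"],
                           v["sigma3_0"], mr)
        if not np.isfinite(s):
            return 1e10
        return s + 0.5 * np.sum((x - means) ** 2 / variances)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        x0 = means if r == 0 else means + 0.5 * sds * rng.standard_normal(len(names))
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"fatol": 1e-6, "xatol": 1e-6,
                                "maxfev": max_evals, "maxiter": max_evals})
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x, float))
    _, x_opt = best
    params = from_unconstrained(x_opt, sub, base)
    return params.replace(variant=variant)
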