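"""Three-level binary hierarchical Gaussian filter (HGF).

Level 1 is the observed advice accuracy u (Bernoulli), level 2 the adviser's
fidelity tendency x2 (Gaussian random walk, linked to level 1 through a
logistic sigmoid), and level 3 the log-volatility x3 of the adviser's
intentions, which sets the step size of x2 via exp(kappa2*x3 + omega2).

Two variants are implemented:

* ``standard`` — x3 performs a pure random walk with variance theta;
* ``mean_reverting`` — x3 additionally drifts towards an equilibrium m3 at
  rate phi3 (a discrete-time Ornstein-Uhlenbeck process), modelling a
  baseline expectation about how volatile the adviser is.

The trial-wise inversion follows the canonical binary-HGF variational
update scheme (the reference semantics of the open-source HGF toolbox):
belief updates are precision-weighted prediction errors, with the
second-level update Delta mu2 = delta1 / pi2 and the third-level update
proportional to (w2 / pi3) * delta2, where w2 = v2 * pihat2 is the
volatility weight.

The per-trial loop is JIT-compiled with numba when available; a pure-Python
fallback with identical semantics is used otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "BeliefTrajectory",
    "FilterDivergenceError",
    "sigmoid",
    "filter_beliefs",
    "derived_pes",
    "regressor_table",
    "VARIANTS",
]

VARIANTS = (
    "standard",
    "mean_reverting",
    "bayes_optimal_standard",
    "bayes_optimal_mean_reverting",
)

#: variants whose third level carries the mean-reverting drift
_MEAN_REVERTING = {"mean_reverting", "bayes_optimal_mean_reverting"}

# column order of the raw trajectory matrix produced by the filter loop
_COLS = (
    "muhat1", "muhat2", "mu2", "pihat2", "pi2", "muhat3", "mu3",
    "pihat3", "pi3", "delta1", "delta2", "v2", "gamma2",
)


class FilterDivergenceError(RuntimeError):
    """Raised when a precision collapses or a state becomes non-finite."""

    def __init__(self, trial: int, quantity: str):
        self.trial = trial
        self.quantity = quantity
        super().__init__(
            f"belief filtering diverged at trial {trial}: "
            f"non-finite or non-positive {quantity}"
        )


@dataclass(frozen=True)
class ModelParams:
    """Perceptual and response parameters of one subject.

    kappa2   coupling of level 3 onto the level-2 step size (>= 0)
    omega2   tonic log-volatility of level 2
    theta    meta-volatility, variance of the level-3 walk (fixed 0.5)
    phi3     drift rate towards m3 in the mean-reverting variant (fixed 0.1)
    m3       drift equilibrium of level 3 (free in the mean-reverting HGF)
    mu2_0 / sigma2_0, mu3_0 / sigma3_0   initial means and variances
    zeta     social weight of advice vs. cue in the integrated belief, (0,1)
    nu       inverse decision temperature; choice slope beta = exp(-muhat3 + nu)
    """

    kappa2: float = 1.0
    omega2: float = -3.0
    theta: float = 0.5
    phi3: float = 0.1
    m3: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    zeta: float = 0.5
    nu: float = 2.0
    variant: str = "mean_reverting"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.kappa2 < 0:
            raise ValueError("kappa2 must be >= 0")
        if self.theta <= 0 or self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("theta, sigma2_0 and sigma3_0 must be > 0")
        if not 0.0 <= self.phi3 <= 1.0:
            raise ValueError("phi3 must lie in [0, 1]")
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must lie strictly in (0, 1)")

    @property
    def mean_reverting(self) -> bool:
        return self.variant in _MEAN_REVERTING

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class BeliefTrajectory:
    """Per-trial sufficient statistics and prediction errors of the filter.

    All arrays share the length of the input sequence.  Predictions (hatted
    quantities) are the beliefs available *before* the trial's outcome;
    ``muhat1`` is the predicted advice accuracy used to align regressors
    with outcome onset.
    """

    muhat1: np.ndarray
    muhat2: np.ndarray
    mu2: np.ndarray
    pihat2: np.ndarray
    pi2: np.ndarray
    muhat3: np.ndarray
    mu3: np.ndarray
    pihat3: np.ndarray
    pi3: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    v2: np.ndarray
    gamma2: np.ndarray
    u: np.ndarray
    params: ModelParams = field(repr=False, default_factory=ModelParams)

    def __len__(self) -> int:
        return len(self.muhat1)

    @property
    def mu1(self) -> np.ndarray:
        """Posterior at level 1 equals the observed input."""
        return self.u

    def to_frame(self) -> pd.DataFrame:
        data = {name: getattr(self, name) for name in _COLS}
        data["u"] = self.u
        df = pd.DataFrame(data)
        df.insert(0, "trial", np.arange(1, len(self) + 1))
        return df


def sigmoid(z):
    """Logistic sigmoid 1 / (1 + exp(-z)), numerically saturating."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def _filter_loop(u, kappa2, omega2, theta, phi3, m3,
                 mu2_0, sigma2_0, mu3_0, sigma3_0, mean_reverting):
    """Sequential HGF updates.  Returns (trajectory matrix, error trial, error col).

    error trial is -1 on success; otherwise the 1-based trial at which a
    precision collapsed or a state left the finite range, with error col
    indexing the offending column of ``_COLS``.
    """
    n = u.shape[0]
    out = np.empty((n, 13))
    mu2 = mu2_0
    sigma2 = sigma2_0
    mu3 = mu3_0
    sigma3 = sigma3_0
    for t in range(n):
        muhat2 = mu2
        if mean_reverting:
            muhat3 = mu3 + phi3 * (m3 - mu3)
        else:
            muhat3 = mu3
        # prediction at level 1 from the level-2 prediction
        if muhat2 >= 0.0:
            muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        else:
            e = np.exp(muhat2)
            muhat1 = e / (1.0 + e)
        v2 = np.exp(kappa2 * muhat3 + omega2)
        pihat2 = 1.0 / (sigma2 + v2)
        delta1 = u[t] - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        if not (pi2 > 0.0 and np.isfinite(pi2)):
            return out, t + 1, 4
        mu2 = muhat2 + delta1 / pi2
        # third level: volatility PE and precision-weighted update
        dmu2 = mu2 - muhat2
        delta2 = (1.0 / pi2 + dmu2 * dmu2) * pihat2 - 1.0
        pihat3 = 1.0 / (sigma3 + theta)
        w2 = v2 * pihat2
        pi3 = pihat3 + 0.5 * kappa2 * kappa2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if not (pi3 > 0.0 and np.isfinite(pi3)):
            return out, t + 1, 8
        mu3 = muhat3 + 0.5 * kappa2 * (w2 / pi3) * delta2
        if not (np.isfinite(mu2) and np.isfinite(mu3)):
            return out, t + 1, 6
        sigma2 = 1.0 / pi2
        sigma3 = 1.0 / pi3
        out[t, 0] = muhat1
        out[t, 1] = muhat2
        out[t, 2] = mu2
        out[t, 3] = pihat2
        out[t, 4] = pi2
        out[t, 5] = muhat3
        out[t, 6] = mu3
        out[t, 7] = pihat3
        out[t, 8] = pi3
        out[t, 9] = delta1
        out[t, 10] = delta2
        out[t, 11] = v2
        out[t, 12] = kappa2 * w2  # gamma2, the auxiliary expected precision
    return out, -1, 0


def _loglik_loop(u, c, y, kappa2, omega2, theta, phi3, m3,
                 mu2_0, sigma2_0, mu3_0, sigma3_0, zeta, nu, mean_reverting):
    """Filter + Bernoulli response log-likelihood in one pass (hot path)."""
    n = u.shape[0]
    mu2 = mu2_0
    sigma2 = sigma2_0
    mu3 = mu3_0
    sigma3 = sigma3_0
    ll = 0.0
    for t in range(n):
        muhat2 = mu2
        if mean_reverting:
            muhat3 = mu3 + phi3 * (m3 - mu3)
        else:
            muhat3 = mu3
        if muhat2 >= 0.0:
            muhat1 = 1.0 / (1.0 + np.exp(-muhat2))
        else:
            e = np.exp(muhat2)
            muhat1 = e / (1.0 + e)
        v2 = np.exp(kappa2 * muhat3 + omega2)
        pihat2 = 1.0 / (sigma2 + v2)
        delta1 = u[t] - muhat1
        pi2 = pihat2 + muhat1 * (1.0 - muhat1)
        if not (pi2 > 0.0 and np.isfinite(pi2)):
            return np.nan
        mu2 = muhat2 + delta1 / pi2
        dmu2 = mu2 - muhat2
        delta2 = (1.0 / pi2 + dmu2 * dmu2) * pihat2 - 1.0
        pihat3 = 1.0 / (sigma3 + theta)
        w2 = v2 * pihat2
        pi3 = pihat3 + 0.5 * kappa2 * kappa2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if not (pi3 > 0.0 and np.isfinite(pi3)):
            return np.nan
        mu3_new = muhat3 + 0.5 * kappa2 * (w2 / pi3) * delta2
        if not (np.isfinite(mu2) and np.isfinite(mu3_new)):
            return np.nan
        mu3 = mu3_new
        sigma2 = 1.0 / pi2
        sigma3 = 1.0 / pi3
        # response model: integrated belief and volatility-modulated sigmoid
        b = zeta * muhat1 + (1.0 - zeta) * c[t]
        if b < 1e-8:
            b = 1e-8
        elif b > 1.0 - 1e-8:
            b = 1.0 - 1e-8
        beta = np.exp(-muhat3 + nu)
        if beta > 1e10:
            beta = 1e10
        logit = beta * (np.log(b) - np.log(1.0 - b))
        if np.isnan(logit):
            logit = 0.0
        if logit >= 0.0:
            p = 1.0 / (1.0 + np.exp(-logit))
        else:
            e = np.exp(logit)
            p = e / (1.0 + e)
        if p < 1e-12:
            p = 1e-12
        elif p > 1.0 - 1e-12:
            p = 1.0 - 1e-12
        if y[t] == 1.0:
            ll += np.log(p)
        else:
            ll += np.log(1.0 - p)
    return ll


def _surprise_loop(u, kappa2, omega2, theta, phi3, m3,
                   mu2_0, sigma2_0, mu3_0, sigma3_0, mean_reverting):
    """Total Bernoulli surprise of the input sequence under the filter."""
    traj, err, _ = _filter_loop(u, kappa2, omega2, theta, phi3, m3,
                                mu2_0, sigma2_0, mu3_0, sigma3_0,
                                mean_reverting)
    if err >= 0:
        return np.nan
    s = 0.0
    for t in range(u.shape[0]):
        m = traj[t, 0]
        if m < 1e-8:
            m = 1e-8
        elif m > 1.0 - 1e-8:
            m = 1.0 - 1e-8
        if u[t] == 1.0:
            s -= np.log(m)
        else:
            s -= np.log(1.0 - m)
    return s


try:  # JIT-compile the hot loops; semantics are identical either way
    import numba

    _filter_loop = numba.njit(cache=True)(_filter_loop)
    _loglik_loop = numba.njit(cache=True)(_loglik_loop)
    _surprise_loop = numba.njit(cache=True)(_surprise_loop)
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    pass


def filter_beliefs(params: ModelParams, inputs) -> BeliefTrajectory:
    """Run the deterministic belief filter over a binary input sequence.

    Raises :class:`FilterDivergenceError` identifying the trial and the
    offending quantity if a precision collapses.
    """
    u = np.asarray(inputs, dtype=np.float64).ravel()
    if u.size and not np.all((u == 0.0) | (u == 1.0)):
        raise ValueError("inputs must be binary (0/1)")
    traj, err_trial, err_col = _filter_loop(
        u, params.kappa2, params.omega2, params.theta, params.phi3,
        params.m3, params.mu2_0, params.sigma2_0, params.mu3_0,
        params.sigma3_0, params.mean_reverting,
    )
    if err_trial >= 0:
        raise FilterDivergenceError(err_trial, _COLS[err_col])
    cols = {name: traj[:, i].copy() for i, name in enumerate(_COLS)}
    return BeliefTrajectory(u=u, params=params, **cols)


def derived_pes(trajectory: BeliefTrajectory, schedule, zeta: float):
    """Cue PE, integrated predicted outcome and outcome PE per trial.

    delta_c = u - c;  mu_b = zeta*muhat1 + (1-zeta)*c;  delta_b = u - mu_b.
    """
    c = np.asarray(schedule.c if hasattr(schedule, "c") else schedule,
                   dtype=np.float64)
    if len(c) != len(trajectory):
        raise ValueError(
            f"schedule length {len(c)} != trajectory length {len(trajectory)}"
        )
    u = trajectory.u
    delta_c = u - c
    mu_b = zeta * trajectory.muhat1 + (1.0 - zeta) * c
    delta_b = u - mu_b
    return delta_c, mu_b, delta_b


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"regressor {name!r} has zero variance")
    return (x - x.mean()) / sd


#: the three within-design regressor pairs used by the single-trial GLMs
REGRESSOR_PAIRS = {
    "PEs": ("delta_c", "delta_b"),
    "lowPE": ("abs_delta1", "pi2"),
    "highPE": ("delta2", "pi3"),
}


def regressor_table(trajectory: BeliefTrajectory, schedule, zeta: float,
                    signed_advice_pe: bool = False):
    """z-scored single-trial GLM regressors and their within-pair correlations.

    Emits the three regressor pairs (delta_c, delta_b), (|delta1| or signed
    delta1, pi2) and (delta2, pi3), each column z-scored across trials.
    Returns ``(table, pair_correlations)`` where the correlations are plain
    Pearson r within each design pair.
    """
    delta_c, _, delta_b = derived_pes(trajectory, schedule, zeta)
    advice_pe = trajectory.delta1 if signed_advice_pe else np.abs(trajectory.delta1)
    raw = {
        "delta_c": delta_c,
        "delta_b": delta_b,
        "abs_delta1": advice_pe,
        "pi2": trajectory.pi2,
        "delta2": trajectory.delta2,
        "pi3": trajectory.pi3,
    }
    table = pd.DataFrame({k: _zscore(np.asarray(v, float), k) for k, v in raw.items()})
    if signed_advice_pe:
        table = table.rename(columns={"abs_delta1": "delta1"})
    pair_corr = {}
    for design, (a, b) in REGRESSOR_PAIRS.items():
        a_ = "delta1" if (signed_advice_pe and a == "abs_delta1") else a
        pair_corr[design] = float(np.corrcoef(table[a_], table[b])[0, 1])
    return table, pair_corr
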