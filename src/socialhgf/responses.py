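"""Response model: from beliefs to advice-taking choices.

On each trial the participant integrates the advice-based probability
muhat1 with the cue-based probability c into a single belief
b = zeta*muhat1 + (1-zeta)*c, and follows the advice with probability
b^beta / (b^beta + (1-b)^beta), where the sigmoid slope
beta = exp(-muhat3 + nu) is flattened by the currently estimated
volatility of the adviser's intentions: the more volatile the adviser
seems, the more exploratory the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hgf import ModelParams, filter_beliefs, _loglik_loop
from .task import TaskSchedule

_EPS = 1e-8

__all__ = [
    "integrate_belief",
    "choice_prob",
    "simulate_choices",
    "log_likelihood",
    "ChoiceRecord",
]


@dataclass(frozen=True)
class ChoiceRecord:
    trial: int
    b: float
    beta: float
    p_follow: float
    y: int


def integrate_belief(muhat1, c, zeta: float):
    """Convex combination of advice- and cue-based probabilities."""
    c = np.clip(np.asarray(c, dtype=np.float64), _EPS, 1.0 - _EPS)
    out = zeta * np.asarray(muhat1, dtype=np.float64) + (1.0 - zeta) * c
    if out.ndim == 0:
        return float(out)
    return out


def choice_prob(b, muhat3, nu: float):
    """Probability of following the advice.

    Computed in log-space as 1 / (1 + exp(-beta * logit(b))) with
    beta = exp(-muhat3 + nu), which is algebraically b^beta / (b^beta +
    (1-b)^beta) but does not overflow for large beta.
    """
    b = np.clip(np.asarray(b, dtype=np.float64), _EPS, 1.0 - _EPS)
    beta = np.exp(-np.asarray(muhat3, dtype=np.float64) + nu)
    logit = beta * (np.log(b) - np.log1p(-b))
    out = np.empty_like(logit)
    pos = logit >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-logit[pos]))
    e = np.exp(logit[~pos])
    out[~pos] = e / (1.0 + e)
    if out.ndim == 0:
        return float(out)
    return out


def response_probabilities(params: ModelParams, schedule: TaskSchedule) -> pd.DataFrame:
    """Deterministic per-trial b, beta and p_follow for given parameters."""
    traj = filter_beliefs(params, schedule.u)
    b = integrate_belief(traj.muhat1, schedule.c, params.zeta)
    beta = np.exp(-traj.muhat3 + params.nu)
    p = choice_prob(b, traj.muhat3, params.nu)
    return pd.DataFrame(
        {"trial": np.arange(1, len(traj) + 1), "b": b, "beta": beta, "p_follow": p}
    )


def simulate_choices(params: ModelParams, schedule: TaskSchedule,
                     seed: int) -> pd.DataFrame:
    """Simulate advice-taking: y(t) ~ Bernoulli(p_follow(t)), seeded."""
    probs = response_probabilities(params, schedule)
    rng = np.random.default_rng(seed)
    probs = probs.copy()
    probs["y"] = (rng.random(len(probs)) < probs["p_follow"]).astype(int)
    return probs


def log_likelihood(params: ModelParams, schedule: TaskSchedule, choices) -> float:
    """Bernoulli log-likelihood of a binary choice sequence."""
    y = np.asarray(choices, dtype=np.float64).ravel()
    if len(y) != len(schedule):
        raise ValueError("choices and schedule differ in length")
    if y.size and not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("choices must be binary (0/1)")
    ll = _loglik_loop(
        schedule.u, schedule.c, y,
        params.kappa2, params.omega2, params.theta, params.phi3, params.m3,
        params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0,
        params.zeta, params.nu, params.mean_reverting,
    )
    if not np.isfinite(ll):
        raise FloatingPointError("likelihood diverged (precision collapse)")
    return float(ll)
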