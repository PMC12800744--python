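# socialhgf

Hierarchical Bayesian modelling of social learning under volatility, end
to end and fully synthetic: a binary-lottery advice-taking task, belief
filtering with standard and mean-reverting three-level binary
hierarchical Gaussian filters (HGF), MAP fitting with Laplace model
evidence and random-effects Bayesian model selection, and a
mass-univariate single-trial EEG GLM stage with permutation-based
family-wise error control that recovers planted computational effects and
their temporal hierarchy.

It is aimed at computational-psychiatry and model-based-neuroimaging
researchers who want a self-contained, seedable sandbox for this analysis
family — for method validation, power analysis, recovery studies, and
teaching — without any recorded data.

## The model in brief

Participants predict a binary lottery by combining a pie-chart cue with
advice from an adviser whose intentions alternate between helpful and
misleading. The HGF tracks the advice accuracy `u_t` hierarchically:

* level 1 — advice accuracy, Bernoulli with `p = s(x2)`;
* level 2 — adviser fidelity `x2`, a Gaussian random walk with step
  variance `exp(kappa2 * x3 + omega2)`;
* level 3 — volatility of the adviser's intentions `x3`; in the
  mean-reverting variant `x3` drifts toward an equilibrium `m3` at rate
  `phi3` (discrete-time Ornstein–Uhlenbeck).

Belief updates are precision-weighted prediction errors, e.g.
`mu2 <- muhat2 + delta1 / pi2` with `delta1 = u - muhat1`. Choices follow
the integrated belief `b = zeta * muhat1 + (1 - zeta) * c` through a
sigmoid with slope `beta = exp(-muhat3 + nu)`, so perceived volatility
flattens decisions. Six single-trial quantities — cue PE `delta_c`,
advice PE `delta1`, outcome PE `delta_b`, advice precision `pi2`,
volatility PE `delta2`, volatility precision `pi3` — serve as EEG
regressors in three two-regressor GLMs.

See `docs/methods.md` for the full model, priors, inference choices, and
known limitations.

## Worked example

```python
import socialhgf as sh

schedule = sh.make_schedule(sh.TaskConfig(seed=7))
print(len(schedule), schedule.phase_counts())
# 170 (34, 102, 34)

params = sh.ModelParams(variant="mean_reverting", zeta=0.45, nu=2.5)
sim = sh.simulate_choices(params, schedule, seed=1)
print(round(sim["y"].mean(), 3))
# 0.606        <- fraction of trials on which advice was taken

fit = sh.fit_map(schedule, sim["y"].to_numpy(), "mean_reverting", seed=0)
print(round(fit.map_estimates.zeta, 3), round(fit.map_estimates.nu, 2),
      round(fit.log_evidence, 1))
# 0.455 2.66 -61.5   <- recovered social weight, decision noise, log evidence
```

The social weight comes back near its generating value (0.45), the
decision-noise parameter near 2.5, and the Laplace log evidence is the
quantity the group-level model selection consumes.

The same pipeline runs from the shell:

```bash
socialhgf all --seed 1 --out runs/demo --n-perm 1000
```

which writes the schedule, simulated choices, per-subject fits, BMS
results, recovery report, the synthetic EEG container, GLM cluster
tables, and a human-readable `summary.txt` (winning model, protected
exceedance probabilities, recovery correlations, latency ordering).

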