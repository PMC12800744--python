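import numpy as np
import pytest

import socialhgf as sh
from socialhgf.hgf import ModelParams, filter_beliefs, sigmoid
from hgf_oracle import filter_oracle

HAND_PARAMS = ModelParams(kappa2=1.0, omega2=-2.0, theta=0.5, mu2_0=0.0,
                          sigma2_0=1.0, mu3_0=1.0, sigma3_0=1.0,
                          variant="standard")


def _random_params(rng, variant="mean_reverting"):
    return ModelParams(
        kappa2=float(np.exp(0.5 * rng.standard_normal())),
        omega2=float(-3.0 + 1.5 * rng.standard_normal()),
        m3=float(1.0 + rng.standard_normal()),
        mu2_0=float(rng.standard_normal()),
        mu3_0=float(1.0 + rng.standard_normal()),
        variant=variant,
    )


def test_sigmoid_values():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(40.0) == pytest.approx(1.0, abs=1e-12)
    assert sigmoid(-40.0) == pytest.approx(0.0, abs=1e-12)
    # direct evaluation of the closed form as oracle
    assert sigmoid(0.509653) == pytest.approx(0.624725, abs=1e-6)
    z = np.linspace(-5, 5, 50)
    assert np.all(np.diff(sigmoid(z)) > 0)


def test_single_trial_hand_arithmetic():
    """One accurate-advice trial from flat beliefs, worked by hand."""
    traj = filter_beliefs(HAND_PARAMS, [1])
    assert traj.muhat1[0] == pytest.approx(0.5, abs=1e-6)
    assert traj.delta1[0] == pytest.approx(0.5, abs=1e-6)
    assert traj.v2[0] == pytest.approx(0.367879, abs=1e-6)
    assert traj.pihat2[0] == pytest.approx(0.731059, abs=1e-6)
    assert traj.pi2[0] == pytest.approx(0.981059, abs=1e-6)
    assert traj.mu2[0] == pytest.approx(0.509653, abs=1e-6)


def test_zero_coupling_freezes_level3(default_schedule):
    """kappa2 = 0 removes the hierarchy: v2 is constant at exp(omega2) and
    mu3 follows its deterministic drift path."""
    p = ModelParams(kappa2=0.0, omega2=-2.0, variant="standard")
    traj = filter_beliefs(p, default_schedule.u)
    np.testing.assert_allclose(traj.v2, np.exp(-2.0), rtol=1e-12)
    np.testing.assert_allclose(traj.mu3, p.mu3_0, rtol=1e-12)
    # mean-reverting: mu3 relaxes along the exact geometric drift path
    pm = ModelParams(kappa2=0.0, omega2=-2.0, m3=2.0, mu3_0=0.0, phi3=0.1,
                     variant="mean_reverting")
    tm = filter_beliefs(pm, default_schedule.u)
    expected = 2.0 * (1.0 - 0.9 ** np.arange(1, 171))
    np.testing.assert_allclose(tm.mu3, expected, rtol=1e-10)


def test_phi3_zero_matches_standard(default_schedule):
    p_std = ModelParams(variant="standard")
    p_mr = ModelParams(variant="mean_reverting", phi3=0.0)
    a = filter_beliefs(p_std, default_schedule.u)
    b = filter_beliefs(p_mr, default_schedule.u)
    for name in ("mu2", "pi2", "mu3", "pi3", "delta1", "delta2"):
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))


def test_mean_reversion_pulls_towards_equilibrium(default_schedule):
    """The level-3 prediction always lies between the previous posterior
    and the equilibrium point."""
    p = ModelParams(variant="mean_reverting", m3=2.0, phi3=0.1, omega2=-4.0)
    traj = filter_beliefs(p, default_schedule.u)
    prev = np.concatenate([[p.mu3_0], traj.mu3[:-1]])
    between = ((traj.muhat3 - prev) * (p.m3 - prev) >= 0) & (
        np.abs(traj.muhat3 - p.m3) <= np.abs(prev - p.m3))
    assert between.all()


@pytest.mark.parametrize("variant", ["standard", "mean_reverting"])
def test_oracle_transliteration_agreement(default_schedule, variant):
    """Production filter agrees with a literal per-trial transliteration of
    the update equations to 1e-10 over random parameter draws."""
    rng = np.random.default_rng(7)
    u = default_schedule.u
    n_ok = 0
    for _ in range(100):
        p = _random_params(rng, variant)
        try:
            expected = filter_oracle(
                u, p.kappa2, p.omega2, p.theta, p.phi3, p.m3, p.mu2_0,
                p.sigma2_0, p.mu3_0, p.sigma3_0, p.mean_reverting)
        except ArithmeticError:
            with pytest.raises(sh.FilterDivergenceError):
                filter_beliefs(p, u)
            continue
        traj = filter_beliefs(p, u)
        for key in expected[0]:
            got = getattr(traj, key)
            want = [row[key] for row in expected]
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12,
                                       err_msg=f"{key} mismatch")
        n_ok += 1
    assert n_ok >= 60  # a minority of draws diverges by design


def test_filter_invariants(default_schedule):
    """Precision positivity, the exact pwPE update identities, and the
    binary-input precision gain, across random draws."""
    rng = np.random.default_rng(11)
    u = default_schedule.u
    for _ in range(50):
        p = _random_params(rng)
        try:
            t = filter_beliefs(p, u)
        except sh.FilterDivergenceError:
            continue
        assert np.all(t.pi2 > 0) and np.all(t.pi3 > 0)
        assert np.all(t.pihat2 > 0) and np.all(t.pihat3 > 0)
        assert np.all(t.pi2 >= t.pihat2)  # binary-input precision gain
        np.testing.assert_allclose(t.delta1, u - t.muhat1, rtol=0, atol=1e-14)
        np.testing.assert_allclose(t.mu2 - t.muhat2, t.delta1 / t.pi2,
                                   rtol=1e-12)
        # level-3 update is the precision-weighted volatility PE
        np.testing.assert_allclose(t.mu3 - t.muhat3,
                                   0.5 * t.gamma2 * t.delta2 / t.pi3,
                                   rtol=1e-9, atol=1e-15)
        assert np.all(t.delta2 >= -1.0)


def test_surprise_monotonicity(default_schedule):
    """Confirming inputs yield small advice PEs, contradicting ones large."""
    t = filter_beliefs(ModelParams(variant="standard"), default_schedule.u)
    confident = t.muhat1 > 0.5
    match = default_schedule.u == 1
    assert np.all(np.abs(t.delta1[confident & match]) < 0.5)
    assert np.all(np.abs(t.delta1[confident & ~match]) > 0.5)


def test_non_binary_inputs_rejected():
    with pytest.raises(ValueError):
        filter_beliefs(ModelParams(), [0, 1, 0.5])


def test_divergence_reports_trial_and_quantity():
    p = ModelParams(kappa2=4.0, omega2=-0.7, mu2_0=5.0, sigma3_0=5.0,
                    mu3_0=0.0, variant="standard")
    with pytest.raises(sh.FilterDivergenceError) as err:
        filter_beliefs(p, [0, 1] * 40)
    assert err.value.trial >= 1
    assert err.value.quantity in ("pi2", "pi3", "mu3")


def test_derived_pes(default_schedule):
    traj = filter_beliefs(ModelParams(), default_schedule.u)
    delta_c, mu_b, delta_b = sh.derived_pes(traj, default_schedule, zeta=0.428)
    u, c = default_schedule.u, default_schedule.c
    np.testing.assert_allclose(delta_c, u - c, atol=1e-14)
    np.testing.assert_allclose(delta_b, u - mu_b, atol=1e-14)
    # worked example: u=1, c=0.75 -> delta_c = 0.25
    assert (1.0 - 0.75) == pytest.approx(0.25)
    # group-mean social weight: zeta=0.428, muhat1=0.6, c=0.7 -> mu_b=0.6572
    assert 0.428 * 0.6 + (1 - 0.428) * 0.7 == pytest.approx(0.6572, abs=1e-12)
    # degenerate weight: zeta=1 reduces the outcome PE to the advice PE
    _, mu_b1, delta_b1 = sh.derived_pes(traj, default_schedule, zeta=1.0)
    np.testing.assert_allclose(mu_b1, traj.muhat1, atol=1e-14)
    np.testing.assert_allclose(delta_b1, traj.delta1, atol=1e-14)


def test_derived_pes_length_mismatch(default_schedule):
    traj = filter_beliefs(ModelParams(), default_schedule.u[:100])
    with pytest.raises(ValueError):
        sh.derived_pes(traj, default_schedule, zeta=0.5)


def test_regressor_table(default_schedule):
    traj = filter_beliefs(ModelParams(), default_schedule.u)
    table, pair_corr = sh.regressor_table(traj, default_schedule, zeta=0.45)
    assert set(table.columns) == {"delta_c", "delta_b", "abs_delta1", "pi2",
                                  "delta2", "pi3"}
    np.testing.assert_allclose(table.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(table.std(ddof=0), 1.0, atol=1e-12)
    assert set(pair_corr) == {"PEs", "lowPE", "highPE"}
    assert all(-1 <= v <= 1 for v in pair_corr.values())
    signed, _ = sh.regressor_table(traj, default_schedule, zeta=0.45,
                                   signed_advice_pe=True)
    assert "delta1" in signed.columns


def test_regressor_table_zero_variance():
    u = np.ones(60)
    traj = filter_beliefs(ModelParams(), u)

    class FakeSchedule:
        c = np.full(60, 0.75)

    with pytest.raises(ValueError, match="zero variance"):
        sh.regressor_table(traj, FakeSchedule(), zeta=1e-9)
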