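import numpy as np
import pytest

from socialhgf.eeg import default_effect_specs, make_layout, synthesize_eeg
from socialhgf.glm import (CollinearityError, DESIGNS, GLMDesign,
                           covariate_correlation, first_level, group_test,
                           latency_order, phase_erps)


@pytest.fixture(scope="module")
def layout():
    return make_layout()


def _pair_specs(design_name, scale=1.0):
    """Noise-free plant containing only one design's regressor pair, so the
    partialled betas are analytically known."""
    return {
        q: type(s)(s.quantity, s.latency_ms, s.width_ms, s.center,
                   s.spatial_width, scale * (s.amp_mean or 0.5), amp_sd=0.0,
                   cov_slope=0.0)
        for q, s in default_effect_specs().items()
        if q in DESIGNS[design_name]
    }


@pytest.mark.parametrize("design_name", list(DESIGNS))
def test_noiseless_first_level_recovers_planted_betas(
        design_name, small_schedule, small_cohort_tables, layout):
    """With zero noise and plants restricted to the design's own pair, the
    partialled OLS betas equal the planted amplitude times the kernel."""
    specs = _pair_specs(design_name)
    ds = synthesize_eeg(small_cohort_tables, specs=specs,
                        phases=small_schedule.phase, noise=(0.0, 0.0, 0.0),
                        seed=0)
    betas, resid_var, _ = first_level(ds, GLMDesign(design_name,
                                                    DESIGNS[design_name]))
    for j, reg in enumerate(DESIGNS[design_name]):
        spec = specs[reg]
        gt = np.exp(-((ds.times - spec.latency_ms) ** 2)
                    / (2 * spec.width_ms ** 2))
        gs = np.exp(-(layout.distances()[layout.index(spec.center)] ** 2)
                    / (2 * spec.spatial_width ** 2))
        planted = spec.amp_mean * gs[:, None] * gt[None, :]
        # baseline correction shifts each kernel by its prestim mean
        planted = planted - planted[:, ds.times < 0].mean(axis=1,
                                                          keepdims=True)
        np.testing.assert_allclose(betas[0, j], planted, atol=2e-3)
    assert np.all(resid_var < 1e-3)


def test_linearity_of_planted_amplitude(small_schedule, small_cohort_tables):
    ds = synthesize_eeg(small_cohort_tables, specs=_pair_specs("highPE"),
                        phases=small_schedule.phase, noise=(0, 0, 0), seed=0)
    ds2 = synthesize_eeg(small_cohort_tables,
                         specs=_pair_specs("highPE", scale=2.0),
                         phases=small_schedule.phase, noise=(0, 0, 0), seed=0)
    b1, _, _ = first_level(ds, GLMDesign("highPE", DESIGNS["highPE"]))
    b2, _, _ = first_level(ds2, GLMDesign("highPE", DESIGNS["highPE"]))
    peak = np.abs(b1).max()
    np.testing.assert_allclose(b2, 2 * b1, atol=0.01 * peak)


def test_duplicated_regressor_raises(small_schedule, small_cohort_tables):
    ds = synthesize_eeg(small_cohort_tables, phases=small_schedule.phase,
                        seed=3)
    tables = [t.assign(dup=t["delta2"]) for t in ds.regressors]
    with pytest.raises(CollinearityError, match="delta2.*dup|dup.*delta2"):
        first_level(ds, GLMDesign("bad", ("delta2", "dup")), regressors=tables)


def test_constant_regressor_raises(small_schedule, small_cohort_tables):
    ds = synthesize_eeg(small_cohort_tables, phases=small_schedule.phase,
                        seed=3)
    tables = [t.assign(flat=0.0) for t in ds.regressors]
    with pytest.raises(CollinearityError, match="flat"):
        first_level(ds, GLMDesign("bad", ("delta2", "flat")),
                    regressors=tables)


def test_f_equals_t_squared(layout):
    rng = np.random.default_rng(0)
    values = rng.normal(size=(12, 64, 192))
    times = np.linspace(-100, 646, 192)
    res = group_test(values, times, layout, n_perm=50, seed=0,
                     cluster_inference=False)
    win = ~np.isnan(res.fmap)
    np.testing.assert_allclose(res.fmap[win], res.tmap[win] ** 2, rtol=1e-10)


def test_group_test_needs_ten_subjects(layout):
    with pytest.raises(ValueError, match="10 subjects"):
        group_test(np.zeros((5, 64, 192)), np.linspace(-100, 646, 192),
                   layout, n_perm=10)


def test_permutation_threshold_deterministic(layout):
    rng = np.random.default_rng(1)
    values = rng.normal(size=(14, 64, 192))
    times = np.linspace(-100, 646, 192)
    a = group_test(values, times, layout, n_perm=100, seed=9,
                   cluster_inference=False)
    b = group_test(values, times, layout, n_perm=100, seed=9,
                   cluster_inference=False)
    assert a.fwe_threshold == b.fwe_threshold


def test_strong_plant_detected_with_clusters(small_schedule,
                                             small_cohort_tables, layout):
    """A strong volatility-precision plant is found at its kernel, and the
    cluster table localises it."""
    specs = {"pi3": default_effect_specs()["pi3"]}
    specs["pi3"] = type(specs["pi3"])("pi3", 326.0, 12.0, specs["pi3"].center,
                                      0.35, 3.0, amp_sd=0.1)
    ds = synthesize_eeg(small_cohort_tables, specs=specs,
                        phases=small_schedule.phase, seed=5)
    betas, _, _ = first_level(ds, GLMDesign("highPE", ("delta2", "pi3")))
    res = group_test(betas[:, 1], ds.times, ds.layout, n_perm=200, seed=2,
                     cluster_inference=True)
    assert res.significant
    assert abs(res.peak_time_ms - 326.0) < 30.0
    layout_dist = np.linalg.norm(
        layout.positions[layout.index(res.peak_channel)]
        - layout.positions[layout.index(specs["pi3"].center)])
    assert layout_dist < 0.35  # peak on or next to the planted channel
    sig = res.clusters[res.clusters.significant]
    assert len(sig) >= 1
    assert (sig.iloc[0].earliest_ms <= 326.0 <= sig.iloc[0].peak_time_ms
            + 40.0)
    assert res.earliest_cluster_ms is not None


def test_latency_order_reporting(layout):
    class Fake:
        def __init__(self, earliest, peak, sig):
            self.earliest_peak_ms = earliest
            self.earliest_cluster_ms = None
            self.peak_time_ms = peak
            self.significant = sig

    results = {"a": Fake(300.0, 320.0, True), "b": Fake(None, 400.0, False),
               "c": Fake(250.0, 260.0, True)}
    ordered, missing = latency_order(results)
    assert ordered == [("c", 250.0), ("a", 300.0)]
    assert missing == ["b"]
    peak_ordered, _ = latency_order(results, criterion="peak")
    assert peak_ordered == [("c", 260.0), ("a", 320.0)]
    single, none_missing = latency_order({"a": Fake(300.0, 320.0, True)})
    assert single == [("a", 300.0)] and none_missing == []


def test_phase_erps_counts_and_contrasts(small_schedule, small_cohort_tables):
    # plant-free data: phases share the same background ERP by construction
    ds = synthesize_eeg(small_cohort_tables, specs={},
                        phases=small_schedule.phase, seed=6)
    erps, contrasts = phase_erps(ds, n_perm=60, seed=0,
                                 cluster_inference=False)
    assert set(erps) == {"S1", "V", "S2"}
    assert erps["S1"].shape == (12, 64, 192)
    assert set(contrasts) == {"S1-V", "S1-S2", "V-S2"}
    # identical planted phase means: no contrast should light up
    assert not any(c.significant for c in contrasts.values())


def test_phase_erps_missing_phase(small_schedule, small_cohort_tables):
    ds = synthesize_eeg(small_cohort_tables, phases=small_schedule.phase,
                        seed=6)
    ds.phases = np.array(["?"] * ds.n_trials)
    with pytest.raises(ValueError):
        phase_erps(ds, n_perm=10)


def test_planted_phase_offset_detected(small_schedule, small_cohort_tables):
    """An amplitude offset added to volatile-phase trials is picked up by
    the S1-V contrast at the planted time and location."""
    ds = synthesize_eeg(small_cohort_tables, specs={},
                        phases=small_schedule.phase, seed=7)
    layout = ds.layout
    ch = layout.index(layout.nearest(0.0, -0.7))
    bump = 10.0 * np.exp(-((ds.times - 300.0) ** 2) / (2 * 25.0 ** 2))
    vol = ds.phases == "V"
    ds.data[:, vol, ch, :] += bump.astype(np.float32)
    _, contrasts = phase_erps(ds, n_perm=150, seed=1,
                              cluster_inference=False)
    res = contrasts["S1-V"]
    assert res.significant
    assert abs(res.peak_time_ms - 300.0) < 40.0
    assert res.peak_channel == layout.names[ch]
    assert not contrasts["S1-S2"].significant


def test_covariate_correlation_validation(layout):
    times = np.linspace(-100, 646, 192)
    values = np.random.default_rng(0).normal(size=(12, 64, 192))
    with pytest.raises(ValueError, match="constant"):
        covariate_correlation(values, np.ones(12), times, layout, n_perm=10)
    with pytest.raises(ValueError):
        covariate_correlation(values, np.arange(5), times, layout, n_perm=10)


def test_planted_covariate_slope_recovered(small_schedule,
                                           small_cohort_tables):
    """A strong covariate-linked advice-precision amplitude is recovered as
    a significant negative t at the planted kernel."""
    specs = dict(default_effect_specs())
    pi2 = specs["pi2"]
    specs["pi2"] = type(pi2)("pi2", pi2.latency_ms, pi2.width_ms, pi2.center,
                             pi2.spatial_width, 0.0, amp_sd=0.1,
                             cov_slope=-3.0, covariate="gf_social")
    ds = synthesize_eeg(small_cohort_tables, specs=specs,
                        phases=small_schedule.phase, seed=8)
    betas, _, _ = first_level(ds, GLMDesign("lowPE", DESIGNS["lowPE"]))
    res = covariate_correlation(betas[:, 1], ds.covariates["gf_social"],
                                ds.times, ds.layout, n_perm=200, seed=3)
    assert res.mask.any()
    assert res.peak_t < 0
    assert abs(res.peak_time_ms - pi2.latency_ms) < 60.0
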