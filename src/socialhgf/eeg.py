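"""Synthetic multi-subject single-trial EEG with planted model-based effects.

The generator emulates clean outcome-locked epochs from a 64-channel
recording (-100 to 650 ms at 256 Hz): a common background ERP, spatially
and temporally smoothed Gaussian noise, and — the point of the exercise —
trial-wise amplitude modulations that are linear in z-scored computational
trajectories, each confined to a Gaussian temporal kernel and a Gaussian
spatial patch:

    amp(s, k, ch, t) = ERP(ch, t)
                       + sum_q a_{s,q} * z_{s,q,k} * G_time(t) * G_space(ch)
                       + noise,
    a_{s,q} = amp_mean_q + cov_slope_q * std. covariate_s + subject noise.

Default plant latencies follow the group peaks of the outcome-locked
effects this pipeline is meant to recover (volatility precision early at
~326 ms; cue and advice PEs at ~441/445 ms; outcome and volatility PEs at
~535 ms), so the temporal-hierarchy analysis has a principled ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SensorLayout",
    "EffectSpec",
    "EEGDataset",
    "make_layout",
    "default_effect_specs",
    "make_covariates",
    "synthesize_eeg",
    "reject_artifacts",
]

SFREQ = 256.0
TMIN_MS, TMAX_MS = -100.0, 650.0


@dataclass(frozen=True)
class SensorLayout:
    """64 channels on a flattened unit-disc scalp."""

    names: tuple[str, ...]
    positions: np.ndarray  # (64, 2) within the unit disc

    def index(self, name: str) -> int:
        return self.names.index(name)

    def nearest(self, x: float, y: float) -> str:
        d = np.linalg.norm(self.positions - np.array([x, y]), axis=1)
        return self.names[int(np.argmin(d))]

    def distances(self) -> np.ndarray:
        p = self.positions
        return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)


def make_layout(seed: int = 0) -> SensorLayout:
    """Deterministic 64-channel disc layout with BioSemi-style A/B labels.

    Channels sit on concentric rings (1 + 7 + 12 + 20 + 24); the y axis
    points to the front of the head (frontal channels have y > 0).
    """
    ring_sizes = (1, 7, 12, 20, 24)
    ring_radii = (0.0, 0.22, 0.45, 0.68, 0.92)
    pos = []
    for size, radius in zip(ring_sizes, ring_radii):
        angles = np.pi / 2 + 2 * np.pi * np.arange(size) / max(size, 1)
        for a in angles:
            pos.append((radius * np.cos(a), radius * np.sin(a)))
    pos = np.round(np.array(pos), 6)
    names = tuple(f"A{i+1}" for i in range(32)) + tuple(f"B{i+1}" for i in range(32))
    return SensorLayout(names=names, positions=pos)


@dataclass(frozen=True)
class EffectSpec:
    """A planted linear effect of one computational quantity."""

    quantity: str        # regressor column name (e.g. "delta_c")
    latency_ms: float    # centre of the Gaussian temporal kernel
    width_ms: float      # temporal SD
    center: str          # channel at the centre of the spatial patch
    spatial_width: float  # spatial SD in layout (disc) units
    amp_mean: float      # microvolt per z-unit, group mean
    amp_sd: float = 0.25  # between-subject SD of the amplitude
    cov_slope: float = 0.0  # microvolt per SD of the linked covariate
    covariate: str = "gf_social"

    def __post_init__(self):
        if self.width_ms <= 0 or self.spatial_width <= 0:
            raise ValueError("kernel widths must be positive")
        if not (TMIN_MS <= self.latency_ms <= TMAX_MS):
            raise ValueError("latency must lie within the epoch")


def default_effect_specs(layout: SensorLayout | None = None) -> dict[str, EffectSpec]:
    """Plants matching the recovered group peaks and topographies.

    Advice precision (pi2) is planted at zero amplitude: it is the one
    quantity for which no sensor-level group effect is expected, but its
    first-level betas still exist and can carry covariate structure.
    """
    layout = layout or make_layout()
    centro_parietal = layout.nearest(0.0, -0.35)
    parietal = layout.nearest(0.0, -0.6)
    frontal = layout.nearest(0.0, 0.55)
    temporal = layout.nearest(-0.85, 0.0)
    # Amplitudes sit on a common ~1 microvolt-per-z scale, targeting high
    # group-level detection power at 43 subjects where the design allows it
    # (the cue/outcome-PE pair is strongly collinear within its design, so
    # its partialled effects are deliberately harder to detect).  Signs
    # follow an FRN-like convention: outcome-related PEs (cue, outcome)
    # deflect negatively, advice PE and the volatility quantities
    # positively, so that correlated quantities reinforce rather than
    # cancel in the summed scalp signal.
    return {
        "delta_c": EffectSpec("delta_c", 441.0, 20.0, centro_parietal, 0.35, -1.2),
        "abs_delta1": EffectSpec("abs_delta1", 445.0, 45.0, centro_parietal, 0.35, 0.9),
        "delta_b": EffectSpec("delta_b", 535.0, 40.0, centro_parietal, 0.35, -1.3),
        "pi2": EffectSpec("pi2", 300.0, 30.0, temporal, 0.35, 0.0,
                          cov_slope=-0.8, covariate="gf_social"),
        "delta2": EffectSpec("delta2", 535.0, 20.0, parietal, 0.35, 0.8),
        "pi3": EffectSpec("pi3", 326.0, 8.0, frontal, 0.35, 0.8),
    }


@dataclass
class EEGDataset:
    """Subjects x trials x channels x time single-trial amplitudes (microvolt)."""

    data: np.ndarray           # (S, T, C, N) float32
    times: np.ndarray          # (N,) ms
    layout: SensorLayout
    phases: np.ndarray         # (T,) phase label per trial
    covariates: pd.DataFrame   # one row per subject
    regressors: list[pd.DataFrame] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        """Portable array container: .npz with a JSON metadata entry."""
        meta = {
            "times": self.times.tolist(),
            "channels": list(self.layout.names),
            "positions": self.layout.positions.tolist(),
            "phases": self.phases.tolist(),
            "seed": self.seed,
        }
        np.savez_compressed(
            path, data=self.data,
            covariates=self.covariates.to_records(index=False),
            meta=json.dumps(meta),
        )

    @classmethod
    def load(cls, path) -> "EEGDataset":
        with np.load(path, allow_pickle=True) as f:
            meta = json.loads(str(f["meta"]))
            return cls(
                data=f["data"],
                times=np.array(meta["times"]),
                layout=SensorLayout(tuple(meta["channels"]),
                                    np.array(meta["positions"])),
                phases=np.array(meta["phases"]),
                covariates=pd.DataFrame(f["covariates"]),
                seed=meta["seed"],
            )


def time_axis() -> np.ndarray:
    """Epoch sample times in ms: -100 to 650 at 256 Hz (192 samples)."""
    n = int(round((TMAX_MS - TMIN_MS) / 1000.0 * SFREQ))
    return TMIN_MS + np.arange(n) * (1000.0 / SFREQ)


# GF score distribution emulating a high-functioning cohort:
# median 9, interquartile range [8, 9] on the 1-10 scale.
_GF_SCORES = np.array([6, 7, 8, 9, 10])
_GF_PROBS = np.array([0.05, 0.10, 0.25, 0.40, 0.20])


def make_covariates(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic psychosocial functioning scores (GF: Social / GF: Role)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "gf_social": rng.choice(_GF_SCORES, size=n_subjects, p=_GF_PROBS),
        "gf_role": rng.choice(_GF_SCORES, size=n_subjects, p=_GF_PROBS),
    })


def _background_erp(layout: SensorLayout, times: np.ndarray) -> np.ndarray:
    """Common outcome-locked waveform: fronto-central negativity ~150 ms,
    parietal positivity ~320 ms."""
    y = layout.positions[:, 1]
    frontal = np.exp(-((y - 0.5) ** 2) / (2 * 0.4**2))
    parietal = np.exp(-((y + 0.5) ** 2) / (2 * 0.4**2))
    n1 = -2.0 * np.exp(-((times - 150.0) ** 2) / (2 * 25.0**2))
    p3 = 3.0 * np.exp(-((times - 320.0) ** 2) / (2 * 60.0**2))
    return frontal[:, None] * n1[None, :] + parietal[:, None] * p3[None, :]


def synthesize_eeg(regressors: list[pd.DataFrame],
                   specs: dict[str, EffectSpec] | None = None,
                   layout: SensorLayout | None = None,
                   phases: np.ndarray | None = None,
                   covariates: pd.DataFrame | None = None,
                   noise: tuple[float, float, float] = (0.2, 20.0, 8.0),
                   artifact_rate: float = 0.0,
                   seed: int = 0) -> EEGDataset:
    """Generate a cohort of single-trial epochs with planted effects.

    ``regressors`` holds one z-scored trajectory table per subject (all the
    same trial count); ``noise`` is (spatial SD in disc units, temporal
    smoothing SD in ms, per-sample trial noise SD in microvolt).  Epochs are
    baseline-corrected over -100..0 ms.  Fully deterministic under ``seed``.
    """
    layout = layout or make_layout()
    specs = specs if specs is not None else default_effect_specs(layout)
    times = time_axis()
    n_sub = len(regressors)
    n_trials = len(regressors[0])
    for r in regressors:
        if len(r) != n_trials:
            raise ValueError("all subjects must have the same trial count")
        missing = [q for q in specs if q not in r.columns]
        if missing:
            raise ValueError(f"regressor table lacks columns {missing}")
    if phases is None:
        phases = np.array(["?"] * n_trials)
    if len(phases) != n_trials:
        raise ValueError("phase labels do not match the trial count")
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = make_covariates(n_sub, seed=int(rng.integers(2**31)))
    cov_std = {
        c: (covariates[c] - covariates[c].mean()).to_numpy()
        / (covariates[c].std(ddof=0) or 1.0)
        for c in covariates.columns
    }

    spatial_sd, temporal_ms, trial_sd = noise
    dt = 1000.0 / SFREQ
    n_time = len(times)
    n_ch = len(layout.names)
    erp = _background_erp(layout, times)

    # per-quantity spatiotemporal kernels
    kernels = {}
    dist = layout.distances()
    for q, spec in specs.items():
        gt = np.exp(-((times - spec.latency_ms) ** 2) / (2 * spec.width_ms**2))
        gs = np.exp(-(dist[layout.index(spec.center)] ** 2)
                    / (2 * spec.spatial_width**2))
        kernels[q] = (gs, gt)

    # spatially correlated noise: unit-variance-preserving channel mixing
    if spatial_sd > 0:
        W = np.exp(-(dist**2) / (2 * spatial_sd**2))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
    else:
        W = np.eye(n_ch)

    W32 = W.astype(np.float32)
    data = np.empty((n_sub, n_trials, n_ch, n_time), dtype=np.float32)
    for s in range(n_sub):
        epochs = np.empty((n_trials, n_ch, n_time), dtype=np.float32)
        epochs[:] = erp.astype(np.float32)
        for q, spec in specs.items():
            a = (spec.amp_mean
                 + spec.cov_slope * cov_std.get(spec.covariate, np.zeros(n_sub))[s]
                 + spec.amp_sd * rng.standard_normal())
            z = regressors[s][q].to_numpy(dtype=np.float64)
            gs, gt = kernels[q]
            epochs += (a * z[:, None, None] * gs[None, :, None]
                       * gt[None, None, :]).astype(np.float32)
        if trial_sd > 0:
            nz = rng.standard_normal((n_trials, n_ch, n_time),
                                     dtype=np.float32)
            if temporal_ms > 0:
                nz = gaussian_filter1d(nz, sigma=temporal_ms / dt, axis=-1)
                # rescale so the per-sample SD stays at trial_sd
                nz /= nz.std()
            epochs += np.float32(trial_sd) * np.einsum("ck,tkn->tcn", W32, nz)
        # baseline correction over the pre-stimulus interval
        base = epochs[:, :, times < 0].mean(axis=-1, keepdims=True,
                                            dtype=np.float64)
        epochs -= base.astype(np.float32)
        if artifact_rate > 0:  # blink-like post-stimulus bursts
            bad = rng.random(n_trials) < artifact_rate
            burst = np.exp(-((times - 250.0) ** 2) / (2 * 60.0**2))
            epochs[bad] += (180.0 * np.sign(rng.standard_normal((int(bad.sum()), 1, 1)))
                            * burst[None, None, :]).astype(np.float32)
        data[s] = epochs

    return EEGDataset(data=data, times=times, layout=layout, phases=phases,
                      covariates=covariates, regressors=regressors, seed=seed)


def reject_artifacts(dataset: EEGDataset, threshold_uv: float = 100.0):
    """Flag trials whose absolute amplitude exceeds the threshold anywhere.

    Returns ``(good, counts)``: a subjects x trials boolean mask and the
    per-subject number of retained trials.
    """
    peak = np.abs(dataset.data).max(axis=(2, 3))
    good = peak <= threshold_uv
    return good, good.sum(axis=1)
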