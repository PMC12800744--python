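"""Mass-univariate single-trial GLMs with permutation-based FWE control.

First level: per subject, channel and time sample, ordinary least squares
of single-trial amplitude on an intercept plus z-scored computational
trajectories.  Second level: one-sample F tests (squared t) across
subjects, with family-wise error control over the channels x time search
space by max-statistic sign-flip permutation, and cluster-mass inference
at a primary cluster-defining threshold of p < 0.001.  Channel adjacency
for clusters comes from the Delaunay triangulation of the sensor layout;
time adjacency links neighbouring samples.

The analysis window is 100-550 ms post-stimulus by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from scipy.stats import t as t_dist

from .eeg import EEGDataset, SensorLayout

__all__ = [
    "GLMDesign",
    "GLMResult",
    "CollinearityError",
    "DESIGNS",
    "first_level",
    "group_test",
    "latency_order",
    "phase_erps",
    "covariate_correlation",
]

ANALYSIS_WINDOW = (100.0, 550.0)

#: the three computational designs: one regressor pair each
DESIGNS = {
    "PEs": ("delta_c", "delta_b"),
    "lowPE": ("abs_delta1", "pi2"),
    "highPE": ("delta2", "pi3"),
}


@dataclass(frozen=True)
class GLMDesign:
    name: str
    regressors: tuple[str, ...]


class CollinearityError(ValueError):
    pass


def _design_matrix(table: pd.DataFrame, regressors: tuple[str, ...],
                   subject: int) -> np.ndarray:
    cols = []
    for name in regressors:
        x = table[name].to_numpy(dtype=np.float64)
        sd = x.std()
        if sd == 0:
            raise CollinearityError(
                f"subject {subject}: regressor {name!r} is constant")
        cols.append((x - x.mean()) / sd)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(np.corrcoef(cols[i], cols[j])[0, 1])
            if abs(r) > 0.999:
                raise CollinearityError(
                    f"subject {subject}: regressors "
                    f"{regressors[i]!r} and {regressors[j]!r} are collinear "
                    f"(r = {r:.4f})")
    return np.column_stack([np.ones(len(table))] + cols)


def first_level(eeg: EEGDataset, design: GLMDesign,
                regressors: list[pd.DataFrame] | None = None):
    """Per-subject OLS betas.

    Returns ``(betas, resid_var, pair_corr)`` where ``betas`` has shape
    (subjects, regressors, channels, time) — the intercept is estimated but
    not returned — ``resid_var`` the residual variance per subject, and
    ``pair_corr`` the within-design regressor correlations per subject.
    """
    tables = regressors if regressors is not None else eeg.regressors
    if len(tables) != eeg.n_subjects:
        raise ValueError("one regressor table per subject required")
    S, T, C, N = eeg.data.shape
    p = len(design.regressors)
    betas = np.empty((S, p, C, N))
    resid_var = np.empty(S)
    pair_corr = []
    for s in range(S):
        if len(tables[s]) != T:
            raise ValueError(f"subject {s}: regressor length != trial count")
        X = _design_matrix(tables[s], design.regressors, s)
        if p == 2:
            pair_corr.append(float(np.corrcoef(X[:, 1], X[:, 2])[0, 1]))
        Y = eeg.data[s].reshape(T, C * N).astype(np.float64)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas[s] = coef[1:].reshape(p, C, N)
        resid = Y - X @ coef
        dof = max(T - X.shape[1], 1)
        resid_var[s] = float((resid**2).sum() / (dof * C * N))
    return betas, resid_var, pair_corr


def channel_adjacency(layout: SensorLayout) -> np.ndarray:
    """Symmetric boolean channel adjacency from Delaunay neighbours."""
    tri = Delaunay(layout.positions)
    n = len(layout.names)
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    adj[i, j] = True
    return adj


def _lattice_adjacency(adj_ch: np.ndarray, n_time: int):
    """Sparse adjacency over the flattened channels x time lattice."""
    n_ch = adj_ch.shape[0]
    rows, cols = [], []
    ch_i, ch_j = np.nonzero(adj_ch)
    for t in range(n_time):
        base = t * n_ch
        rows.append(base + ch_i)
        cols.append(base + ch_j)
    idx = np.arange(n_ch)
    for t in range(n_time - 1):
        rows.append(t * n_ch + idx)
        cols.append((t + 1) * n_ch + idx)
        rows.append((t + 1) * n_ch + idx)
        cols.append(t * n_ch + idx)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = n_ch * n_time
    return coo_matrix((np.ones(len(rows), bool), (rows, cols)),
                      shape=(n, n)).tocsr()


def _clusters(mask_flat: np.ndarray, stat_flat: np.ndarray, adj) -> list[dict]:
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for k in range(n_comp):
        members = idx[labels == k]
        out.append({"members": members,
                    "mass": float(stat_flat[members].sum())})
    return out


@dataclass
class GLMResult:
    """Group-level statistic map with permutation FWE inference."""

    fmap: np.ndarray                 # (C, N) F statistic (NaN outside window)
    tmap: np.ndarray
    fwe_threshold: float             # max-statistic threshold on F
    mask_peak: np.ndarray            # peak-level FWE significance
    mask_cluster: np.ndarray         # union of significant clusters
    clusters: pd.DataFrame           # extent, peak channel/time/F, mass, p
    earliest_peak_ms: float | None
    earliest_cluster_ms: float | None
    peak_channel: str | None
    peak_time_ms: float | None
    peak_f: float
    times: np.ndarray = field(repr=False, default=None)
    window: tuple[float, float] = ANALYSIS_WINDOW
    n_perm: int = 0

    @property
    def significant(self) -> bool:
        return bool(self.mask_peak.any() or self.mask_cluster.any())


def _one_sample_t(values: np.ndarray) -> np.ndarray:
    S = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(S))


def group_test(values: np.ndarray, times: np.ndarray, layout: SensorLayout,
               n_perm: int = 1000, seed: int = 0,
               window: tuple[float, float] = ANALYSIS_WINDOW,
               cluster_p: float = 0.001, alpha: float = 0.05,
               cluster_inference: bool = True) -> GLMResult:
    """One-sample F test across subjects with permutation FWE control.

    ``values`` is (subjects, channels, time) — first-level betas for one
    regressor, or a paired ERP difference.  The null distribution flips the
    sign of whole subject maps (exchangeable under symmetric zero-mean
    errors); peak-level inference uses the maximum F over the analysis
    window, cluster-level inference the maximum suprathreshold cluster
    mass at the primary threshold ``cluster_p``.
    """
    S, C, N = values.shape
    if S < 10:
        raise ValueError(f"need at least 10 subjects, got {S}")
    win = (times >= window[0]) & (times <= window[1])
    n_win = int(win.sum())
    V = values[:, :, win].reshape(S, C * n_win).astype(np.float64)

    t_obs = _one_sample_t(V)
    f_obs = t_obs**2

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    ssq = (V**2).sum(axis=0)
    mean_p = signs @ V / S
    var_p = (ssq[None, :] - S * mean_p**2) / (S - 1)
    var_p[var_p <= 0] = np.inf
    f_perm = mean_p**2 / (var_p / S)
    max_f = f_perm.max(axis=1)
    fwe_threshold = float(np.quantile(max_f, 1.0 - alpha, method="higher"))

    mask_peak_flat = f_obs >= fwe_threshold

    # cluster-mass inference at the primary (cluster-defining) threshold
    f_primary = float(t_dist.isf(cluster_p / 2.0, S - 1) ** 2)
    clusters_rows = []
    mask_cluster_flat = np.zeros_like(mask_peak_flat)
    if cluster_inference:
        adj = _lattice_adjacency(channel_adjacency(layout), n_win)
        # lattice index is time-major: node = t * C + ch
        f_obs_lattice = f_obs.reshape(C, n_win).T.ravel()
        obs_clusters = _clusters(f_obs_lattice >= f_primary, f_obs_lattice, adj)
        null_mass = np.zeros(n_perm)
        for i in range(n_perm):
            fp = f_perm[i].reshape(C, n_win).T.ravel()
            cl = _clusters(fp >= f_primary, fp, adj)
            if cl:
                null_mass[i] = max(c["mass"] for c in cl)
        mass_threshold = float(np.quantile(null_mass, 1.0 - alpha,
                                           method="higher"))
        for c in sorted(obs_clusters, key=lambda c: -c["mass"]):
            members = c["members"]
            t_idx, ch_idx = np.divmod(members, C)
            peak = members[np.argmax(f_obs_lattice[members])]
            p_val = float((1 + (null_mass >= c["mass"]).sum()) / (1 + n_perm))
            significant = c["mass"] >= mass_threshold
            clusters_rows.append({
                "extent": len(members),
                "mass": c["mass"],
                "peak_channel": layout.names[peak % C],
                "peak_time_ms": float(times[win][peak // C]),
                "peak_f": float(f_obs_lattice[peak]),
                "earliest_ms": float(times[win][t_idx.min()]),
                "p_fwe": p_val,
                "significant": bool(significant),
            })
            if significant:
                lattice_mask = np.zeros(C * n_win, dtype=bool)
                lattice_mask[members] = True
                mask_cluster_flat |= lattice_mask.reshape(n_win, C).T.ravel()

    def expand(flat, fill=np.nan):
        full = np.full((C, N), fill)
        full[:, win] = flat.reshape(C, n_win)
        return full

    fmap = expand(f_obs)
    tmap = expand(t_obs)
    mask_peak = expand(mask_peak_flat, fill=False).astype(bool)
    mask_cluster = expand(mask_cluster_flat, fill=False).astype(bool)

    peak_flat = int(np.argmax(f_obs))
    peak_ch, peak_t = divmod(peak_flat, n_win)
    earliest_peak = (float(times[win][np.flatnonzero(mask_peak_flat.reshape(C, n_win).any(axis=0))[0]])
                     if mask_peak_flat.any() else None)
    sig_rows = [r for r in clusters_rows if r["significant"]]
    earliest_cluster = min((r["earliest_ms"] for r in sig_rows), default=None)

    return GLMResult(
        fmap=fmap, tmap=tmap, fwe_threshold=fwe_threshold,
        mask_peak=mask_peak, mask_cluster=mask_cluster,
        clusters=pd.DataFrame(clusters_rows),
        earliest_peak_ms=earliest_peak,
        earliest_cluster_ms=earliest_cluster,
        peak_channel=layout.names[peak_ch],
        peak_time_ms=float(times[win][peak_t]),
        peak_f=float(f_obs[peak_flat]),
        times=times, window=window, n_perm=n_perm,
    )


def latency_order(results: dict[str, GLMResult], criterion: str = "earliest"):
    """Order regressors by the onset of their significant expression.

    ``criterion`` 'earliest' uses the first significant peak-level time
    point (falling back to the earliest significant cluster onset);
    'peak' uses the time of the maximum F.  Returns ``(ordered,
    not_detected)`` where ``ordered`` is a list of (name, ms) sorted
    ascending.
    """
    ordered, missing = [], []
    for name, res in results.items():
        if criterion == "peak":
            t = res.peak_time_ms if res.significant else None
        else:
            t = res.earliest_peak_ms
            if t is None:
                t = res.earliest_cluster_ms
        if t is None:
            missing.append(name)
        else:
            ordered.append((name, float(t)))
    ordered.sort(key=lambda kv: kv[1])
    return ordered, missing


def phase_erps(eeg: EEGDataset, n_perm: int = 1000, seed: int = 0,
               window: tuple[float, float] = ANALYSIS_WINDOW,
               cluster_inference: bool = True):
    """Per-phase ERPs and pairwise phase contrasts.

    Returns ``(erps, contrasts)``: per-phase subject ERPs (S, C, N) and a
    dict of paired-contrast GLMResults for S1-V, S1-S2 and V-S2.
    """
    labels = [p for p in ("S1", "V", "S2") if p in set(eeg.phases)]
    if not labels:
        raise ValueError("no recognised phase labels present")
    erps = {}
    for p in labels:
        sel = eeg.phases == p
        if not sel.any():
            raise ValueError(f"phase {p} has no trials")
        erps[p] = eeg.data[:, sel].mean(axis=1, dtype=np.float64)
    contrasts = {}
    rng = np.random.default_rng(seed)
    for a, b in (("S1", "V"), ("S1", "S2"), ("V", "S2")):
        if a in erps and b in erps:
            contrasts[f"{a}-{b}"] = group_test(
                erps[a] - erps[b], eeg.times, eeg.layout, n_perm=n_perm,
                seed=int(rng.integers(2**31)), window=window,
                cluster_inference=cluster_inference)
    return erps, contrasts


@dataclass
class CovariateResult:
    tmap: np.ndarray
    fwe_threshold: float
    mask: np.ndarray
    peak_channel: str | None
    peak_time_ms: float | None
    peak_t: float
    n_perm: int


def covariate_correlation(values: np.ndarray, covariate, times: np.ndarray,
                          layout: SensorLayout, n_perm: int = 1000,
                          seed: int = 0,
                          window: tuple[float, float] = ANALYSIS_WINDOW,
                          alpha: float = 0.05) -> CovariateResult:
    """Regress subject-level maps on a standardized covariate.

    FWE control by max-|t| permutation over random reassignments of the
    covariate to subjects (exchangeable under the null of no association).
    """
    cov = np.asarray(covariate, dtype=np.float64)
    S, C, N = values.shape
    if len(cov) != S:
        raise ValueError("covariate length must equal the subject count")
    if cov.std() == 0:
        raise ValueError("constant covariate")
    win = (times >= window[0]) & (times <= window[1])
    n_win = int(win.sum())
    V = values[:, :, win].reshape(S, C * n_win).astype(np.float64)
    Vc = V - V.mean(axis=0)
    Vsd = V.std(axis=0)
    Vsd[Vsd == 0] = np.inf
    z = (cov - cov.mean()) / cov.std()

    def tmap_for(zvec):
        r = zvec @ Vc / (S * Vsd)
        r = np.clip(r, -0.999999, 0.999999)
        return r * np.sqrt((S - 2) / (1.0 - r**2))

    t_obs = tmap_for(z)
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for i in range(n_perm):
        max_t[i] = np.abs(tmap_for(rng.permutation(z))).max()
    thr = float(np.quantile(max_t, 1.0 - alpha, method="higher"))
    mask_flat = np.abs(t_obs) >= thr

    tmap = np.full((C, N), np.nan)
    tmap[:, win] = t_obs.reshape(C, n_win)
    mask = np.zeros((C, N), dtype=bool)
    mask[:, win] = mask_flat.reshape(C, n_win)
    peak_flat = int(np.argmax(np.abs(t_obs)))
    peak_ch, peak_t = divmod(peak_flat, n_win)
    return CovariateResult(
        tmap=tmap, fwe_threshold=thr, mask=mask,
        peak_channel=layout.names[peak_ch],
        peak_time_ms=float(times[win][peak_t]),
        peak_t=float(t_obs[peak_flat]), n_perm=n_perm,
    )
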