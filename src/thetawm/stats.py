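"""Inference machinery.

Cluster-based permutation tests over channel x frequency (x time) grids,
paired t-tests with Cohen's d, the (uncapped) Holm step-down correction,
two-way repeated-measures ANOVA, paired-t power from the noncentral t
distribution, and the 1.5-IQR outlier rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.power import TTestPower


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def paired_t(x, y):
    """Two-tailed paired t-test with Cohen's d for paired designs.

    Returns ``(t, df, p, d)`` where ``d = mean(x - y) / sd(x - y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    diff = x - y
    sd = diff.std(ddof=1)
    d = 0.0 if sd == 0 else float(diff.mean() / sd)
    if sd == 0:
        return 0.0, n - 1, 1.0, 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), n - 1, float(p), d


def holm(p_values, cap: bool = False) -> np.ndarray:
    """Step-down Holm adjustment.

    Sorted ascending, ``p_(i)`` is multiplied by ``m - i`` (0-based), a
    running maximum enforces monotonicity, and values are mapped back to the
    input order.  Adjusted values are *not* capped at 1 unless ``cap`` is
    set, so an adjusted value slightly above 1 is reported as such.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    if cap:
        out = np.minimum(out, 1.0)
    return out


def power_paired_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Two-tailed power of a paired t-test from the noncentral t distribution
    (df = n - 1, noncentrality d * sqrt(n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(TTestPower().power(effect_size=d, nobs=n, alpha=alpha,
                                    alternative="two-sided"))


def iqr_outliers(values) -> np.ndarray:
    """Flag values beyond 1.5 inter-quartile ranges from the quartiles.

    Quartiles use the linear-interpolation convention.  Returns a boolean
    mask with True at outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for the IQR rule")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova2(data: np.ndarray, correction: str = "none") -> pd.DataFrame:
    """Two-way fully-within-subject ANOVA on ``units x levelsA x levelsB``.

    Returns one row per effect (A, B, A*B) with F, numerator/denominator
    degrees of freedom, p, and partial eta squared.  No sphericity
    correction by default; ``correction='gg'`` applies Greenhouse-Geisser.
    """
    import pingouin as pg

    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be units x levelsA x levelsB")
    if np.isnan(data).any():
        raise ValueError("design must be complete (no missing cells)")
    n, a, b = data.shape
    units, la, lb = np.meshgrid(np.arange(n), np.arange(a), np.arange(b),
                                indexing="ij")
    df = pd.DataFrame({"unit": units.ravel(), "A": la.ravel(),
                       "B": lb.ravel(), "y": data.ravel()})
    res = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="unit",
                      detailed=True, effsize="np2")
    pcol = "p_GG_corr" if (correction == "gg" and "p_GG_corr" in res) else "p_unc"
    out = res.rename(columns={"Source": "effect", "ddof1": "df_num",
                              "ddof2": "df_den", pcol: "p",
                              "np2": "partial_eta_sq"})
    return out[["effect", "F", "df_num", "df_den", "p", "partial_eta_sq"]]


# ---------------------------------------------------------------------------
# cluster-based permutation testing
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    bins: np.ndarray          # flat bin indices into the channel x freq (x time) grid
    channels: list[int]       # distinct channel indices spanned
    mass: float               # sum of member t-values
    p: float
    sign: int
    significant: bool


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray         # observed t per bin, grid shape
    mask: np.ndarray          # True at bins of significant clusters
    n_permutations: int
    alpha: float
    seed: int | None = None
    dims: tuple = field(default_factory=tuple)

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def significant_channels(self, ch_names=None) -> list:
        chans = sorted({c for cl in self.significant_clusters
                        for c in cl.channels})
        if ch_names is not None:
            return [ch_names[i] for i in chans]
        return chans

    def to_json(self, path=None):
        payload = dict(
            n_permutations=self.n_permutations, alpha=self.alpha,
            seed=self.seed, dims=list(self.dims),
            clusters=[dict(bins=c.bins.tolist(), channels=list(c.channels),
                           mass=c.mass, p=c.p, sign=c.sign,
                           significant=bool(c.significant))
                      for c in self.clusters])
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def _grid_adjacency(adjacency: np.ndarray, grid_shape: tuple) -> sparse.csr_matrix:
    """Bin adjacency over the channel x grid lattice.

    Bins are adjacent when they share a channel and are lattice neighbours in
    frequency or time, or when they sit at the same lattice point on
    neighbouring channels.
    """
    n_ch = adjacency.shape[0]
    n_grid = int(np.prod(grid_shape)) if grid_shape else 1
    chain = [sparse.diags([np.ones(m - 1), np.ones(m - 1)], [1, -1],
                          format="csr") if m > 1 else sparse.csr_matrix((m, m))
             for m in grid_shape]
    if len(chain) == 0:
        lattice = sparse.csr_matrix((1, 1))
    elif len(chain) == 1:
        lattice = chain[0]
    else:
        i0 = sparse.identity(grid_shape[0], format="csr")
        i1 = sparse.identity(grid_shape[1], format="csr")
        lattice = sparse.kron(chain[0], i1) + sparse.kron(i0, chain[1])
    ch_adj = sparse.csr_matrix(np.asarray(adjacency, dtype=bool))
    i_grid = sparse.identity(n_grid, format="csr")
    i_ch = sparse.identity(n_ch, format="csr")
    return (sparse.kron(ch_adj, i_grid) + sparse.kron(i_ch, lattice)).tocsr()


def _find_clusters(t_vals: np.ndarray, threshold: float,
                   bin_adj: sparse.csr_matrix, n_grid: int,
                   min_channel_extent: int, mode: str):
    """Sign-separated suprathreshold clusters with their masses.

    Returns a list of ``(mass, member_bins, channels, sign)``; clusters whose
    channel span is below ``min_channel_extent`` are dropped.  In
    ``'neighbour'`` mode a bin is only eligible if its channel neighbourhood
    (itself included) holds at least ``min_channel_extent`` suprathreshold
    bins of the same sign.
    """
    out = []
    for sign in (1, -1):
        mask = (t_vals > threshold) if sign == 1 else (t_vals < -threshold)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        if mode == "neighbour" and min_channel_extent > 1:
            sub = bin_adj[idx][:, idx]
            support = np.asarray(sub.sum(axis=1)).ravel() + 1
            idx = idx[support >= min_channel_extent]
            if idx.size == 0:
                continue
        sub = bin_adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            channels = np.unique(members // n_grid)
            if mode == "extent" and channels.size < min_channel_extent:
                continue
            out.append((float(t_vals[members].sum()), members,
                        channels.tolist(), sign))
    return out


def cluster_permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                             adjacency: np.ndarray, n_perm: int = 500,
                             alpha: float = 0.05,
                             cluster_alpha: float = 0.05,
                             min_channel_extent: int = 3,
                             mode: str = "extent",
                             seed: int | None = None) -> ClusterTestResult:
    """Paired cluster-based permutation test over channels x freqs (x times).

    Per-bin paired t-values are thresholded at the two-tailed critical value
    of ``cluster_alpha``; suprathreshold bins of equal sign are clustered by
    channel-graph / lattice adjacency; clusters spanning fewer than
    ``min_channel_extent`` distinct channels are discarded.  The null
    distribution is the per-tail maximum cluster mass over random per-unit
    condition flips; cluster p-values use the add-one estimator and each tail
    is tested at ``alpha / 2``.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have identical unit/grid shape")
    if a.ndim < 2:
        raise ValueError("need units x channels (x freq x time)")
    n_units = a.shape[0]
    grid_shape = a.shape[2:]
    n_ch = a.shape[1]
    n_grid = int(np.prod(grid_shape)) if grid_shape else 1
    diffs = (a - b).reshape(n_units, -1)
    n_bins = diffs.shape[1]

    df = n_units - 1
    t_crit = sps.t.ppf(1.0 - cluster_alpha / 2.0, df)
    sum_sq = (diffs ** 2).sum(axis=0)

    def t_stat(signed_mean):
        var = (sum_sq / n_units - signed_mean ** 2) * n_units / df
        var = np.maximum(var, 1e-300)
        return signed_mean / np.sqrt(var / n_units)

    t_obs = t_stat(diffs.mean(axis=0))
    bin_adj = _grid_adjacency(adjacency, grid_shape)
    observed = _find_clusters(t_obs, t_crit, bin_adj, n_grid,
                              min_channel_extent, mode)

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, n_units)) * 2 - 1
    perm_means = flips @ diffs / n_units
    null_pos = np.zeros(n_perm)
    null_neg = np.zeros(n_perm)
    for i in range(n_perm):
        t_perm = t_stat(perm_means[i])
        for mass, _, _, sign in _find_clusters(t_perm, t_crit, bin_adj,
                                               n_grid, min_channel_extent,
                                               mode):
            if sign == 1:
                null_pos[i] = max(null_pos[i], mass)
            else:
                null_neg[i] = max(null_neg[i], -mass)

    clusters = []
    mask = np.zeros(n_bins, dtype=bool)
    for mass, members, channels, sign in observed:
        null = null_pos if sign == 1 else null_neg
        p = (1.0 + (null >= abs(mass)).sum()) / (1.0 + n_perm)
        significant = p <= alpha / 2.0
        if significant:
            mask[members] = True
        clusters.append(Cluster(bins=members, channels=channels,
                                mass=mass, p=float(p), sign=sign,
                                significant=significant))
    clusters.sort(key=lambda c: -abs(c.mass))
    shape = (n_ch,) + grid_shape
    return ClusterTestResult(clusters=clusters, t_map=t_obs.reshape(shape),
                             mask=mask.reshape(shape), n_permutations=n_perm,
                             alpha=alpha, seed=seed, dims=shape)


def one_sample_cluster_test(x: np.ndarray, popmean: float = 0.0,
                            n_perm: int = 500, alpha: float = 0.05,
                            cluster_alpha: float = 0.05,
                            seed: int | None = None) -> ClusterTestResult:
    """Sign-flip cluster test of ``units x bins`` series against ``popmean``.

    Bins are 1-D lattice-adjacent (e.g. consecutive time points); no channel
    extent rule applies.  Equivalent to the paired test of ``x`` against the
    constant, so it reuses the same machinery.
    """
    x = np.asarray(x, dtype=float)
    const = np.full_like(x, popmean)
    # single pseudo-channel, bins on the lattice
    adjacency = np.zeros((1, 1), dtype=bool)
    return cluster_permutation_test(x[:, None, :], const[:, None, :],
                                    adjacency, n_perm=n_perm, alpha=alpha,
                                    cluster_alpha=cluster_alpha,
                                    min_channel_extent=1, seed=seed)
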