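"""Cross-validated linear-discriminant decoding of stimulus category.

Per time point, channel voltages are the feature vector of a two-class LDA
with Ledoit-Wolf shrinkage of the class covariances, evaluated with
stratified 5-fold cross-validation repeated 5 times.  Variants: temporal
generalization (train at one time, test at all others), channel searchlight
over a fixed window, and exemplar pair-averaging before classification.

The LDA is fitted in batch across time points (class means, per-class
shrunk covariances and the discriminant solve are vectorised over the time
axis), which keeps per-timepoint cross-validation tractable; it reproduces
the standard lsqr/shrinkage discriminant (see the test suite for the
cross-check against scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet
from .stats import one_sample_cluster_test


@dataclass
class DecodingResult:
    """Accuracy with its evaluation geometry.

    ``accuracy`` is a per-test-time vector, a train-time x test-time matrix,
    or a per-channel searchlight map; all values are fractions correct.
    Chance for the two balanced classes is 0.5.
    """

    accuracy: np.ndarray
    times: np.ndarray | None = None
    train_times: np.ndarray | None = None
    test_times: np.ndarray | None = None
    ch_names: list[str] | None = None
    folds: int = 5
    repeats: int = 5
    seed: int | None = None
    window: tuple | None = None
    meta: dict = field(default_factory=dict)

    @property
    def chance(self) -> float:
        return 0.5

    def to_frame(self) -> pd.DataFrame:
        if self.accuracy.ndim == 1 and self.ch_names is not None:
            return pd.DataFrame({"channel": self.ch_names,
                                 "accuracy": self.accuracy})
        if self.accuracy.ndim == 1:
            return pd.DataFrame({"time": self.times,
                                 "accuracy": self.accuracy})
        return pd.DataFrame(self.accuracy,
                            index=pd.Index(self.train_times, name="train_time"),
                            columns=self.test_times)


# ---------------------------------------------------------------------------
# pair averaging
# ---------------------------------------------------------------------------

def pair_average(epochs: EpochSet, group_col: str = "exemplar",
                 seed: int | None = None, return_pairs: bool = False):
    """Average randomly assigned trial pairs within each exemplar.

    Within every level of ``group_col`` trials are randomly paired and each
    pair is replaced by its mean; an odd leftover trial passes through
    unaveraged.  Metadata of the first member is inherited.
    """
    if group_col not in epochs.metadata.columns:
        raise ValueError(f"metadata lacks a {group_col!r} column")
    rng = np.random.default_rng(seed)
    groups = epochs.metadata.groupby(group_col, sort=True).indices
    new_rows, new_data, pairs = [], [], []
    for key in sorted(groups):
        perm = rng.permutation(np.array(groups[key]))
        for k in range(0, len(perm) - 1, 2):
            i, j = int(perm[k]), int(perm[k + 1])
            new_data.append(epochs.data[[i, j]].mean(axis=0))
            new_rows.append(epochs.metadata.iloc[i])
            pairs.append((i, j))
        if len(perm) % 2:
            i = int(perm[-1])
            new_data.append(epochs.data[i])
            new_rows.append(epochs.metadata.iloc[i])
            pairs.append((i,))
    out = EpochSet(data=np.stack(new_data), rate=epochs.rate,
                   tmin=epochs.tmin, ch_names=list(epochs.ch_names),
                   metadata=pd.DataFrame(new_rows))
    if return_pairs:
        return out, pairs
    return out


# ---------------------------------------------------------------------------
# batched shrinkage LDA
# ---------------------------------------------------------------------------

def ledoit_wolf_shrinkage(x: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage coefficient per time slice.

    ``x``: (n_samples, n_features, n_times), already class-centered.
    Returns the optimal coefficient toward the scaled identity, one per time
    slice, following the standard plug-in formula.
    """
    n, p, _ = x.shape
    s = np.einsum("npt,nqt->tpq", x, x) / n          # empirical covariance
    trace = np.einsum("tpp->t", s)
    mu = trace / p
    s_sq = np.einsum("tpq,tpq->t", s, s)
    norms4 = (np.einsum("npt,npt->nt", x, x) ** 2).sum(axis=0)
    beta = (norms4 / n - s_sq) / (p * n)
    delta = s_sq / p - 2.0 * mu * trace / p + mu ** 2
    beta = np.minimum(beta, delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(delta > 0, beta / delta, 0.0)
    return np.clip(np.nan_to_num(lam), 0.0, 1.0)


def _fit_lda_dual(x: np.ndarray, y: np.ndarray, shrinkage="auto"):
    """High-dimensional path of :func:`_fit_lda` (features > trials).

    The shrunk covariance is ``diag(d) + U^T U`` with rank <= n_trials, so
    the discriminant solve goes through the Woodbury identity in sample
    space; numerically equivalent to the direct path.
    """
    n, p, n_times = x.shape
    d = np.zeros((n_times, p))
    blocks = []
    means, priors = [], []
    for k in (0, 1):
        xk = x[y == k]
        nk = xk.shape[0]
        mk = xk.mean(axis=0)
        means.append(mk)
        priors.append(nk / n)
        xc = xk - mk[None]
        if shrinkage == "auto":
            scale = xc.std(axis=0)
            scale[scale == 0] = 1.0
            xs = xc / scale[None]
            lam = ledoit_wolf_shrinkage(xs)
            mu = np.einsum("npt,npt->t", xs, xs) / (nk * p)
            d += (nk / n) * lam[:, None] * mu[:, None] * (scale ** 2).T
        else:
            lam = np.full(n_times, float(shrinkage))
            mu = np.einsum("npt,npt->t", xc, xc) / (nk * p)
            d += (nk / n) * lam[:, None] * mu[:, None]
        coef = (nk / n) * (1.0 - lam) / nk
        blocks.append(np.sqrt(coef)[:, None, None]
                      * xc.transpose(2, 0, 1))          # (T, nk, p)
    u = np.concatenate(blocks, axis=1)                   # (T, n, p)
    d = np.maximum(d, 1e-12 * d.max())
    m0, m1 = means
    b_vec = (m1 - m0).T[:, :, None]                      # (T, p, 1)
    d_inv_b = b_vec / d[:, :, None]
    ud = u / d[:, None, :]                               # U D^-1
    eye = np.eye(u.shape[1])[None]
    gram = eye + ud @ u.transpose(0, 2, 1)
    z = np.linalg.solve(gram, ud @ b_vec)                # (T, n, 1)
    w = (d_inv_b - ud.transpose(0, 2, 1) @ z)[:, :, 0]   # (T, p)
    mid = ((m1 + m0) / 2.0).T
    b = -np.einsum("tp,tp->t", mid, w) + np.log(priors[1] / priors[0])
    return w, b


def _fit_lda(x: np.ndarray, y: np.ndarray, shrinkage="auto"):
    """Fit two-class shrinkage LDA at every time slice.

    ``x``: (n_trials, n_features, n_times); ``y``: 0/1 labels.
    Returns ``(w, b)`` with ``w``: (n_times, n_features), ``b``: (n_times,);
    the decision is class 1 where ``x_t . w_t + b_t > 0``.
    """
    n, p, n_times = x.shape
    if p > n:
        return _fit_lda_dual(x, y, shrinkage)
    cov = np.zeros((n_times, p, p))
    means = []
    priors = []
    for k in (0, 1):
        xk = x[y == k]
        nk = xk.shape[0]
        mk = xk.mean(axis=0)                          # (p, T)
        means.append(mk)
        priors.append(nk / n)
        xc = xk - mk[None]
        if shrinkage == "auto":
            # shrink in standardised feature space (target: scaled identity
            # of the correlation matrix), then rescale
            scale = xc.std(axis=0)
            scale[scale == 0] = 1.0
            xs = xc / scale[None]
            lam = ledoit_wolf_shrinkage(xs)
            s = np.einsum("npt,nqt->tpq", xs, xs) / nk
            mu = np.einsum("tpp->t", s) / p
            s *= (1.0 - lam)[:, None, None]
            s[:, np.arange(p), np.arange(p)] += (lam * mu)[:, None]
            s *= scale.T[:, :, None] * scale.T[:, None, :]
        else:
            lam = np.full(n_times, float(shrinkage))
            s = np.einsum("npt,nqt->tpq", xc, xc) / nk
            mu = np.einsum("tpp->t", s) / p
            s *= (1.0 - lam)[:, None, None]
            s[:, np.arange(p), np.arange(p)] += (lam * mu)[:, None]
        cov += (nk / n) * s
    m0, m1 = means
    dm = (m1 - m0).T[:, :, None]                      # (T, p, 1)
    w = np.linalg.solve(cov, dm)[:, :, 0]             # (T, p)
    mid = ((m1 + m0) / 2.0).T                         # (T, p)
    b = -np.einsum("tp,tp->t", mid, w) + np.log(priors[1] / priors[0])
    return w, b


def _encode_labels(epochs: EpochSet, labels):
    if labels is None:
        labels = epochs.metadata["category"].astype(str).to_numpy()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("decoding requires exactly two classes")
    return (labels == classes[1]).astype(int)


def _splits(y: np.ndarray, folds: int, repeats: int, seed):
    """Stratified fold assignments, reshuffled per repeat, seeds derived."""
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` trials")
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.generate_state(repeats) % (2 ** 31):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rep_seed))
        yield from skf.split(np.zeros_like(y), y)


def crossval_decode(epochs: EpochSet, labels=None, folds: int = 5,
                    repeats: int = 5, shrinkage="auto",
                    seed: int | None = None) -> DecodingResult:
    """Per-timepoint LDA accuracy, mean over folds and repeats."""
    y = _encode_labels(epochs, labels)
    acc = np.zeros(epochs.n_samples)
    n_eval = 0
    for train, test in _splits(y, folds, repeats, seed):
        w, b = _fit_lda(epochs.data[train], y[train], shrinkage)
        scores = np.einsum("npt,tp->nt", epochs.data[test], w) + b
        acc += ((scores > 0).astype(int) == y[test, None]).mean(axis=0)
        n_eval += 1
    return DecodingResult(accuracy=acc / n_eval, times=epochs.times,
                          folds=folds, repeats=repeats, seed=seed)


def temporal_generalization(epochs: EpochSet, labels=None,
                            train_times=None, test_times=None,
                            folds: int = 5, repeats: int = 5,
                            shrinkage="auto",
                            seed: int | None = None) -> DecodingResult:
    """Train at each train time, test at every test time.

    Under the same fold seed the matrix diagonal equals the
    :func:`crossval_decode` time course.
    """
    y = _encode_labels(epochs, labels)
    t = epochs.times
    train_idx = (np.arange(epochs.n_samples) if train_times is None
                 else np.array([int(np.argmin(np.abs(t - tt)))
                                for tt in train_times]))
    test_idx = (np.arange(epochs.n_samples) if test_times is None
                else np.array([int(np.argmin(np.abs(t - tt)))
                               for tt in test_times]))
    acc = np.zeros((train_idx.size, test_idx.size))
    n_eval = 0
    for train, test in _splits(y, folds, repeats, seed):
        w, b = _fit_lda(epochs.data[train][:, :, train_idx], y[train],
                        shrinkage)
        # score every (train time k, test time t) pair in one contraction
        scores = np.einsum("npt,kp->nkt",
                           epochs.data[test][:, :, test_idx], w) + b[:, None]
        acc += ((scores > 0).astype(int)
                == y[test, None, None]).mean(axis=0)
        n_eval += 1
    return DecodingResult(accuracy=acc / n_eval, train_times=t[train_idx],
                          test_times=t[test_idx], folds=folds,
                          repeats=repeats, seed=seed)


def stimulus_delay_generalization(matrix: DecodingResult,
                                  stimulus_window=(0.0, 0.75)) -> np.ndarray:
    """Average the generalization matrix over training times within the
    stimulus-on window, yielding a test-time accuracy series."""
    tt = matrix.train_times
    rows = (tt >= stimulus_window[0]) & (tt < stimulus_window[1])
    if not rows.any():
        raise ValueError("no training times fall in the stimulus window")
    return matrix.accuracy[rows].mean(axis=0)


def searchlight_decode(epochs: EpochSet, neighbours: dict, labels=None,
                       window: tuple[float, float] | None = None,
                       folds: int = 5, repeats: int = 5, shrinkage="auto",
                       seed: int | None = None) -> DecodingResult:
    """Per-channel decoding map: features are the centre channel plus its
    graph neighbours, at all time points within ``window``."""
    y = _encode_labels(epochs, labels)
    if window is None:
        window = (epochs.times[0], epochs.times[-1] + 1.0 / epochs.rate)
    smask = epochs.time_mask(*window)
    acc = np.zeros(epochs.n_channels)
    for ci, center in enumerate(epochs.ch_names):
        group = [center] + sorted(neighbours.get(center, ()))
        idx = epochs.channel_indices(group)
        feats = epochs.data[:, idx][:, :, smask]
        feats = feats.reshape(epochs.n_trials, -1)[:, :, None]
        total, n_eval = 0.0, 0
        for train, test in _splits(y, folds, repeats, seed):
            w, b = _fit_lda(feats[train], y[train], shrinkage)
            scores = np.einsum("npt,tp->nt", feats[test], w) + b
            total += ((scores[:, 0] > 0).astype(int) == y[test]).mean()
            n_eval += 1
        acc[ci] = total / n_eval
    return DecodingResult(accuracy=acc, ch_names=list(epochs.ch_names),
                          folds=folds, repeats=repeats, seed=seed,
                          window=window)


# ---------------------------------------------------------------------------
# group-level significance
# ---------------------------------------------------------------------------

def decode_significance(accuracies: np.ndarray, times: np.ndarray,
                        chance: float = 0.5, n_perm: int = 500,
                        alpha: float = 0.05, seed: int | None = None):
    """Cluster-corrected above-chance windows across participants.

    ``accuracies``: participants x times.  Per-timepoint t against chance,
    temporal clustering of adjacent suprathreshold points, max-sum sign-flip
    permutation null.  Returns ``(windows, result)`` with windows as
    ``(start_s, end_s)`` tuples (end exclusive).
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.ndim != 2 or accuracies.shape[0] < 2:
        raise ValueError("need >= 2 participants x times accuracies")
    result = one_sample_cluster_test(accuracies, popmean=chance,
                                     n_perm=n_perm, alpha=alpha, seed=seed)
    # keep only above-chance (positive) clusters as decoding windows
    mask = np.zeros(accuracies.shape[1], dtype=bool)
    for cl in result.significant_clusters:
        if cl.sign == 1:
            mask[cl.bins] = True
    windows = []
    in_run = False
    dt = times[1] - times[0] if times.size > 1 else 0.0
    start = times[0]
    for i, flag in enumerate(mask):
        if flag and not in_run:
            start = times[i]
            in_run = True
        elif not flag and in_run:
            windows.append((float(start), float(times[i - 1] + dt)))
            in_run = False
    if in_run:
        windows.append((float(start), float(times[-1] + dt)))
    return windows, result
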