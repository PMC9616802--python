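import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from thetawm import decoding

from conftest import make_epochs


def gaussian_classes(rng, n_per_class, n_ch, n_times, delta, scale=1.0):
    """Two Gaussian classes with identity covariance and mean shift delta."""
    x0 = rng.standard_normal((n_per_class, n_ch, n_times)) * scale
    x1 = rng.standard_normal((n_per_class, n_ch, n_times)) * scale
    x1 += np.asarray(delta)[None, :, None]
    data = np.concatenate([x0, x1])
    cats = ["object"] * n_per_class + ["scene"] * n_per_class
    return make_epochs(data, rate=100.0, categories=cats)


# ---------------------------------------------------------------------------
# pair averaging
# ---------------------------------------------------------------------------

def test_pair_average_trial_counts(rng):
    # 11 trials of one exemplar -> 5 pairs + 1 remainder = 6 output trials
    data = rng.standard_normal((11, 2, 8))
    md = pd.DataFrame({"category": "object", "exemplar": "obj1",
                       "trial_index": np.arange(11)})
    es = make_epochs(data, metadata=md)
    out = decoding.pair_average(es, seed=0)
    assert out.n_trials == 6


def test_pair_average_identical_trials(rng):
    row = rng.standard_normal((1, 2, 8))
    data = np.concatenate([row, row])
    md = pd.DataFrame({"category": "object", "exemplar": "obj1",
                       "trial_index": [0, 1]})
    es = make_epochs(data, metadata=md)
    out = decoding.pair_average(es, seed=0)
    assert out.n_trials == 1
    assert np.allclose(out.data[0], row[0])


def test_pair_average_means_match_recorded_members(rng):
    data = rng.standard_normal((8, 3, 10))
    md = pd.DataFrame({"category": ["object"] * 4 + ["scene"] * 4,
                       "exemplar": ["o1", "o1", "o2", "o2",
                                    "s1", "s1", "s1", "s2"],
                       "trial_index": np.arange(8)})
    es = make_epochs(data, metadata=md)
    out, pairs = decoding.pair_average(es, seed=1, return_pairs=True)
    assert len(pairs) == out.n_trials
    for k, members in enumerate(pairs):
        assert np.allclose(out.data[k], data[list(members)].mean(axis=0))
    with pytest.raises(ValueError):
        decoding.pair_average(es, group_col="missing")


# ---------------------------------------------------------------------------
# LDA core vs scikit-learn
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("shrinkage", ["auto", 0.2])
def test_batched_lda_matches_sklearn(rng, shrinkage):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    n, p, T = 50, 8, 4
    x = rng.standard_normal((n, p, T)) * rng.uniform(0.5, 2.0, size=(1, p, 1))
    y = (rng.random(n) < 0.5).astype(int)
    x[y == 1, :3] += 0.7
    w, b = decoding._fit_lda(x, y, shrinkage)
    for t in range(T):
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        clf.fit(x[:, :, t], y)
        assert np.allclose(clf.coef_[0], w[t], atol=1e-10)
        assert clf.intercept_[0] == pytest.approx(b[t], abs=1e-10)


def test_lda_dual_path_equals_direct(rng):
    n, p, T = 24, 40, 3
    x = rng.standard_normal((n, p, T))
    y = np.arange(n) % 2
    x[y == 1, :4] += 1.0
    w_dual, b_dual = decoding._fit_lda(x, y, "auto")        # p > n path
    w_dir, b_dir = decoding._fit_lda_dual(x, y, "auto")
    assert np.allclose(w_dual, w_dir)
    # and against the explicit direct solve on a p <= n problem
    x2 = rng.standard_normal((60, 10, 2))
    y2 = np.arange(60) % 2
    x2[y2 == 1, :3] += 0.5
    assert np.allclose(np.stack(decoding._fit_lda(x2, y2, "auto")[0]),
                       np.stack(decoding._fit_lda_dual(x2, y2, "auto")[0]))


# ---------------------------------------------------------------------------
# cross-validated decoding
# ---------------------------------------------------------------------------

def test_decode_chance_on_permuted_labels():
    accs = []
    for s in range(20):
        rng = np.random.default_rng(1000 + s)
        es = gaussian_classes(rng, 20, 8, 10, np.zeros(8))
        labels = rng.permutation(es.metadata["category"].to_numpy())
        res = decoding.crossval_decode(es, labels=labels, seed=s)
        accs.append(res.accuracy.mean())
    assert np.mean(accs) == pytest.approx(0.5, abs=0.02)


def test_decode_perfect_on_separable_patterns(rng):
    es = gaussian_classes(rng, 20, 6, 5, np.full(6, 50.0), scale=0.01)
    res = decoding.crossval_decode(es, seed=0)
    assert np.allclose(res.accuracy, 1.0)


def test_decode_approaches_bayes_optimal(rng):
    delta = np.array([0.5, 0.4, 0.3, 0.2])
    es = gaussian_classes(rng, 200, 4, 3, delta)
    res = decoding.crossval_decode(es, seed=0)
    bayes = norm.cdf(np.linalg.norm(delta) / 2.0)
    assert res.accuracy.mean() == pytest.approx(bayes, abs=0.03)


def test_decode_requires_enough_trials_per_class(rng):
    es = gaussian_classes(rng, 4, 4, 3, np.zeros(4))
    with pytest.raises(ValueError):
        decoding.crossval_decode(es, folds=5)


def test_decode_invariant_to_channel_order_and_scaling(rng):
    es = gaussian_classes(rng, 30, 6, 4, np.array([0.8, 0.6, 0.4, 0, 0, 0]))
    base = decoding.crossval_decode(es, shrinkage=0.1, seed=5)
    perm = [5, 2, 0, 1, 4, 3]
    es2 = make_epochs(es.data[:, perm] * 3.0, rate=100.0,
                      metadata=es.metadata,
                      ch_names=[es.ch_names[i] for i in perm])
    flipped = decoding.crossval_decode(es2, shrinkage=0.1, seed=5)
    assert np.abs(base.accuracy - flipped.accuracy).max() <= 0.01 + 1e-9


def test_splits_partition_trials(rng):
    y = np.array([0, 1] * 20)
    for train, test in decoding._splits(y, 5, 2, seed=0):
        assert set(train) | set(test) == set(range(40))
        assert set(train) & set(test) == set()


# ---------------------------------------------------------------------------
# temporal generalization
# ---------------------------------------------------------------------------

def test_generalization_diagonal_equals_timecourse(rng):
    es = gaussian_classes(rng, 15, 5, 6, np.array([1.0, 0.5, 0, 0, 0]))
    tc = decoding.crossval_decode(es, seed=7)
    tg = decoding.temporal_generalization(es, seed=7)
    assert np.allclose(np.diag(tg.accuracy), tc.accuracy)


def test_generalization_windowed_pattern(rng):
    n_times = 12
    es = gaussian_classes(rng, 30, 6, n_times, np.zeros(6))
    y = (es.metadata["category"] == "scene").to_numpy()
    es.data[np.ix_(y, [0, 1, 2], np.arange(4, 8))] += 3.0
    tg = decoding.temporal_generalization(es, seed=2)
    inside = tg.accuracy[4:8, 4:8].mean()
    outside = tg.accuracy[:4, :4].mean()
    assert inside > 0.9
    assert outside == pytest.approx(0.5, abs=0.1)


def test_generalization_persistent_pattern_uniform_square(rng):
    es = gaussian_classes(rng, 30, 6, 8, np.array([2.0, 1.5, 1.0, 0, 0, 0]))
    tg = decoding.temporal_generalization(es, seed=3)
    assert tg.accuracy.min() > 0.75


def test_stimulus_delay_generalization_averages_rows(rng):
    es = gaussian_classes(rng, 15, 4, 6, np.array([1.0, 0, 0, 0]))
    tg = decoding.temporal_generalization(es, seed=1)
    series = decoding.stimulus_delay_generalization(tg, (0.0, 0.03))
    rows = (tg.train_times >= 0.0) & (tg.train_times < 0.03)
    assert np.allclose(series, tg.accuracy[rows].mean(axis=0))


# ---------------------------------------------------------------------------
# searchlight
# ---------------------------------------------------------------------------

def test_searchlight_localises_injected_pattern(layout16, radius16, rng):
    from thetawm import synth
    nbrs = layout16.neighbours(radius16)
    target = "Pz"
    group = [target] + sorted(nbrs[target])
    cats = ["object", "scene"] * 20
    data = rng.standard_normal((40, 16, 30))
    es = make_epochs(data, rate=100.0, ch_names=layout16.labels,
                     categories=cats)
    y = (es.metadata["category"] == "scene").to_numpy()
    idx = es.channel_indices(group)
    es.data[np.ix_(y, idx, np.arange(30))] += 2.0
    res = decoding.searchlight_decode(es, nbrs, seed=0)
    assert res.ch_names[int(np.argmax(res.accuracy))] in group
    far = [c for c in layout16.labels
           if c not in group and not (set(nbrs[c]) & set(group))]
    far_idx = [res.ch_names.index(c) for c in far]
    assert np.abs(res.accuracy[far_idx] - 0.5).max() < 0.2


def test_searchlight_chance_on_noise(layout16, radius16):
    nbrs = layout16.neighbours(radius16)
    maps = []
    for s in range(10):
        rng = np.random.default_rng(300 + s)
        es = make_epochs(rng.standard_normal((40, 16, 10)), rate=100.0,
                         ch_names=layout16.labels,
                         categories=["object", "scene"] * 20)
        res = decoding.searchlight_decode(es, nbrs, seed=s)
        maps.append(res.accuracy)
    assert np.abs(np.mean(maps) - 0.5) < 0.03


# ---------------------------------------------------------------------------
# group significance
# ---------------------------------------------------------------------------

def test_decode_significance_no_window_at_chance():
    acc = np.full((10, 50), 0.5)
    windows, _ = decoding.decode_significance(acc, np.arange(50) * 0.01,
                                              n_perm=200, seed=0)
    assert windows == []


def test_decode_significance_recovers_injected_window(rng):
    times = np.arange(100) * 0.01
    acc = 0.5 + rng.standard_normal((28, 100)) * 0.03
    acc[:, 30:70] += 0.15          # 400 ms elevation to ~0.65
    windows, res = decoding.decode_significance(acc, times, n_perm=200,
                                                seed=1)
    assert windows
    start, end = max(windows, key=lambda w: w[1] - w[0])
    inj = (0.30, 0.70)
    overlap = (min(end, inj[1]) - max(start, inj[0])) / (inj[1] - inj[0])
    assert overlap >= 0.8
    # deterministic under a fixed permutation seed
    windows2, _ = decoding.decode_significance(acc, times, n_perm=200, seed=1)
    assert windows == windows2


def test_pair_averaging_improves_gaussian_decodability():
    gains = []
    for s in range(20):
        rng = np.random.default_rng(500 + s)
        es = gaussian_classes(rng, 24, 6, 2, np.array([0.7, 0.5, 0.3, 0, 0, 0]))
        plain = decoding.crossval_decode(es, seed=s).accuracy.mean()
        paired = decoding.crossval_decode(
            decoding.pair_average(es, seed=s), seed=s).accuracy.mean()
        gains.append(paired - plain)
    assert np.mean(gains) >= 0.0
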