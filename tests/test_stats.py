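import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thetawm import stats, synth


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def test_paired_t_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t, df, p, d = stats.paired_t(x, x)
    assert t == 0.0 and d == 0.0 and p == 1.0 and df == 3


def test_paired_t_hand_example():
    # differences {1, 2, 3}: t = 2 / (1 / sqrt(3)) = 3.4641
    y = np.zeros(3)
    x = np.array([1.0, 2.0, 3.0])
    t, df, p, d = stats.paired_t(x, y)
    assert t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-4)
    assert df == 2
    assert d == pytest.approx(2.0)


def test_paired_t_matches_textbook_formula(rng):
    x = rng.standard_normal(20)
    y = rng.standard_normal(20) + 0.3
    t, df, p, d = stats.paired_t(x, y)
    diff = x - y
    t_ref = diff.mean() / (diff.std(ddof=1) / np.sqrt(20))
    p_ref = 2.0 * sps.t.sf(abs(t_ref), 19)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)
    assert d == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-12)
    with pytest.raises(ValueError):
        stats.paired_t([1.0], [2.0])


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

def test_holm_single_p_unchanged():
    assert stats.holm([0.03]) == pytest.approx([0.03])


def test_holm_hand_stepped():
    out = stats.holm([0.01, 0.04, 0.03])
    assert out == pytest.approx([0.03, 0.06, 0.06])


def test_holm_uncapped_and_monotone():
    # the running-max rule can push adjusted values above 1
    out = stats.holm([0.5, 0.6])
    assert out == pytest.approx([1.0, 1.0])
    out = stats.holm([0.55, 0.9])
    assert out == pytest.approx([1.1, 1.1])
    capped = stats.holm([0.55, 0.9], cap=True)
    assert capped == pytest.approx([1.0, 1.0])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=12))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_holm_properties_hold_for_arbitrary_p_sets(p):
    out = stats.holm(p)
    p = np.asarray(p)
    # adjusted values never fall below the raw ones
    assert (out >= p - 1e-12).all()
    # monotone in the raw ordering
    order = np.argsort(p, kind="stable")
    assert (np.diff(out[order]) >= -1e-12).all()
    # a single p is returned unchanged; capping bounds at 1
    assert (stats.holm(p, cap=True) <= 1.0 + 1e-12).all()


def test_holm_ge_raw_and_order_preserving(rng):
    p = rng.random(15)
    out = stats.holm(p)
    assert (out >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(out[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        stats.holm([0.5, 1.2])


# ---------------------------------------------------------------------------
# power of the paired t
# ---------------------------------------------------------------------------

def test_power_null_effect_equals_alpha():
    assert stats.power_paired_t(30, 0.0, 0.05) == pytest.approx(0.05, abs=1e-6)


def test_power_sample_size_statement():
    # n = 28 participants gives 80% power for d = 0.55 at alpha = .05
    assert stats.power_paired_t(28, 0.55, 0.05) == pytest.approx(0.80,
                                                                 abs=0.005)


def test_power_asymptotic():
    assert stats.power_paired_t(10000, 0.5, 0.05) > 0.9999
    with pytest.raises(ValueError):
        stats.power_paired_t(1, 0.5)
    with pytest.raises(ValueError):
        stats.power_paired_t(10, 0.5, alpha=0.0)


# ---------------------------------------------------------------------------
# IQR outliers
# ---------------------------------------------------------------------------

def test_iqr_outliers_cases():
    assert not stats.iqr_outliers([3.0, 3.0, 3.0, 3.0]).any()
    mask = stats.iqr_outliers([1, 2, 3, 4, 100])
    assert mask.tolist() == [False, False, False, False, True]
    mask = stats.iqr_outliers([-100, 1, 2, 3, 4])
    assert mask.tolist() == [True, False, False, False, False]
    with pytest.raises(ValueError):
        stats.iqr_outliers([1, 2, 3])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova2_oracle(data):
    """Hand-coded sums-of-squares decomposition for a two-way
    fully-within-subject design (units x a x b)."""
    n, a, b = data.shape
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb
    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in (
            ("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
            ("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
            ("A * B", ss_ab, (a - 1) * (b - 1), ss_sab,
             (a - 1) * (b - 1) * (n - 1))):
        f = (ss_eff / df_eff) / (ss_err / df_err)
        out[name] = (f, df_eff, df_err, ss_eff / (ss_eff + ss_err))
    return out


def test_rm_anova2_interaction_df_28x2x9(rng):
    res = stats.rm_anova2(rng.standard_normal((28, 2, 9)))
    inter = res[res["effect"] == "A * B"].iloc[0]
    assert (inter["df_num"], inter["df_den"]) == (8, 216)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_rm_anova2_constant_data_f_zero():
    # constant data make every mean square 0; the 0/0 inside the ANOVA is
    # the degenerate case under test
    res = stats.rm_anova2(np.full((6, 2, 4), 3.0))
    assert (res["F"].fillna(0.0).abs() < 1e-9).all()


def test_rm_anova2_matches_ss_oracle(rng):
    data = rng.standard_normal((6, 2, 4))
    res = stats.rm_anova2(data).set_index("effect")
    oracle = rm_anova2_oracle(data)
    for eff, (f, df1, df2, np2) in oracle.items():
        row = res.loc[eff]
        assert row["F"] == pytest.approx(f, abs=1e-8)
        assert (row["df_num"], row["df_den"]) == (df1, df2)
        assert row["partial_eta_sq"] == pytest.approx(np2, abs=1e-8)
    with pytest.raises(ValueError):
        bad = data.copy()
        bad[0, 0, 0] = np.nan
        stats.rm_anova2(bad)


# ---------------------------------------------------------------------------
# cluster permutation test
# ---------------------------------------------------------------------------

def test_cluster_identical_conditions_no_clusters(adjacency16, rng):
    a = rng.standard_normal((10, 16, 9))
    res = stats.cluster_permutation_test(a, a.copy(), adjacency16,
                                         n_perm=100, seed=0)
    assert res.clusters == []
    assert not res.mask.any()


def bruteforce_components(bins, adjacency, grid_shape):
    """Connected components of suprathreshold bins via breadth-first search."""
    nf = grid_shape[0] if grid_shape else 1
    bins = set(map(tuple, bins))
    comps = []
    while bins:
        frontier = [bins.pop()]
        comp = set(frontier)
        while frontier:
            ch, fi = frontier.pop()
            for ch2, fi2 in list(bins):
                lattice = ch2 == ch and abs(fi2 - fi) == 1
                spatial = fi2 == fi and adjacency[ch, ch2]
                if lattice or spatial:
                    bins.remove((ch2, fi2))
                    comp.add((ch2, fi2))
                    frontier.append((ch2, fi2))
        comps.append(comp)
    return comps


def test_cluster_recovers_injected_offset(adjacency16, rng):
    n_units, nf = 12, 9
    a = rng.standard_normal((n_units, 16, nf))
    b = rng.standard_normal((n_units, 16, nf))
    center = 2
    chs = [center] + sorted(np.flatnonzero(adjacency16[center])[:3])
    a[:, chs, 3:6] += 5.0
    res = stats.cluster_permutation_test(a, b, adjacency16, n_perm=200,
                                         seed=3)
    sig = res.significant_clusters
    assert len(sig) >= 1
    top = sig[0]
    assert top.sign == 1
    assert top.p <= 0.05 / 2
    assert top.p >= 1.0 / 201.0            # add-one rule: never exactly 0
    injected = {(c, f) for c in chs for f in range(3, 6)}
    members = {(bin_ // nf, bin_ % nf) for bin_ in top.bins}
    assert injected <= members
    # membership agrees with an independent brute-force component search
    t_crit = sps.t.ppf(0.975, n_units - 1)
    diffs = a - b
    t_map = diffs.mean(0) / (diffs.std(0, ddof=1) / np.sqrt(n_units))
    supra = np.argwhere(t_map > t_crit)
    comps = bruteforce_components(supra, adjacency16, (nf,))
    comps = [c for c in comps if len({ch for ch, _ in c}) >= 3]
    best = max(comps, key=lambda c: sum(t_map[ch, fi] for ch, fi in c))
    assert members == best


def test_cluster_exchangeable_under_unit_permutation(adjacency16, rng):
    a = rng.standard_normal((8, 16, 5))
    b = rng.standard_normal((8, 16, 5))
    a[:, :4, :] += 1.2
    res1 = stats.cluster_permutation_test(a, b, adjacency16, n_perm=100,
                                          seed=9)
    perm = rng.permutation(8)
    res2 = stats.cluster_permutation_test(a[perm], b[perm], adjacency16,
                                          n_perm=100, seed=9)
    assert np.allclose(res1.t_map, res2.t_map)
    assert [c.p for c in res1.clusters] == [c.p for c in res2.clusters]


def test_cluster_null_reproducible_under_seed(adjacency16, rng):
    a = rng.standard_normal((8, 16, 5))
    b = rng.standard_normal((8, 16, 5))
    a[:, :5, :] += 0.8
    r1 = stats.cluster_permutation_test(a, b, adjacency16, n_perm=100, seed=4)
    r2 = stats.cluster_permutation_test(a, b, adjacency16, n_perm=100, seed=4)
    assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]


def test_cluster_min_extent_discards_small_clusters(rng):
    # two channels far apart: no cluster can span three channels
    adjacency = np.zeros((4, 4), dtype=bool)
    a = rng.standard_normal((10, 4, 3))
    b = rng.standard_normal((10, 4, 3))
    a[:, 0, :] += 5.0
    res = stats.cluster_permutation_test(a, b, adjacency, n_perm=100,
                                         min_channel_extent=3, seed=1)
    assert res.clusters == []
    res = stats.cluster_permutation_test(a, b, adjacency, n_perm=100,
                                         min_channel_extent=1, seed=1)
    sig = res.significant_clusters
    assert sig and sig[0].channels == [0]


def test_cluster_result_json_roundtrip(adjacency16, rng, tmp_path):
    a = rng.standard_normal((8, 16, 5))
    b = rng.standard_normal((8, 16, 5))
    a[:, :5, :] += 1.0
    res = stats.cluster_permutation_test(a, b, adjacency16, n_perm=50, seed=2)
    path = tmp_path / "clusters.json"
    res.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert payload["n_permutations"] == 50
    assert len(payload["clusters"]) == len(res.clusters)
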