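import numpy as np
import pandas as pd
import pytest

from connatlas.errors import InputError
from connatlas.stats import (
    GroupMatrix,
    anova_tukey,
    bootstrap_support,
    correlation_matrix,
    hcluster,
)


def _matrix(X, groups=None, samples=None):
    X = np.asarray(X, dtype=float)
    samples = samples or [f"s{i}" for i in range(len(X))]
    groups = groups or ["g"] * len(X)
    return GroupMatrix(
        pd.DataFrame(X, index=samples), pd.Series(groups, index=samples)
    )


# ---------------------------------------------------------------------------
# Correlation matrix


def test_duplicate_rows_fully_correlated():
    row = np.random.default_rng(0).dirichlet(np.ones(8))
    R = correlation_matrix(_matrix([row, row]))
    assert R.iloc[0, 1] == pytest.approx(1.0)


def test_orthogonal_centered_rows_uncorrelated():
    a = np.array([1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0])
    R = correlation_matrix(_matrix([a, b]))
    assert R.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_matches_direct_formula_on_random_matrix():
    rng = np.random.default_rng(1)
    X = rng.dirichlet(np.ones(71), size=8)
    R = correlation_matrix(_matrix(X)).to_numpy()
    for i in range(8):
        for j in range(8):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            assert R[i, j] == pytest.approx(expected, abs=1e-12)
    assert np.allclose(R, R.T)
    assert np.all(np.abs(R) <= 1 + 1e-12)


def test_zero_variance_row_reported_undefined():
    X = [[0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4]]
    R = correlation_matrix(_matrix(X))
    assert np.isnan(R.iloc[0, 1])
    assert R.iloc[0, 0] == 1.0


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def _design(rng, means, n=4, sd=1.0):
    X, groups = [], []
    for gi, m in enumerate(means):
        for _ in range(n):
            X.append(rng.normal(m, sd, size=6))
            groups.append(f"g{gi}")
    return _matrix(X, groups=groups)


def test_identical_groups_give_f_zero_p_one():
    row = [0.1, 0.2, 0.3, 0.4]
    M = _matrix([row] * 8, groups=["a"] * 4 + ["b"] * 4)
    res = anova_tukey(M, 0)
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0
    assert not res.tukey["significant"].any()


def test_separated_group_flagged_in_all_its_pairs():
    rng = np.random.default_rng(2)
    X, groups = [], []
    for gi, m in enumerate([0.0, 0.0, 0.0, 10.0]):
        for _ in range(4):
            X.append([m + rng.normal(0, 0.01)])
            groups.append(f"g{gi}")
    res = anova_tukey(_matrix(X, groups=groups), 0)
    tuk = res.tukey
    involving_g3 = tuk[(tuk["group1"] == "g3") | (tuk["group2"] == "g3")]
    others = tuk[(tuk["group1"] != "g3") & (tuk["group2"] != "g3")]
    assert involving_g3["significant"].all()
    assert not others["significant"].any()


def test_matches_reference_statistics_engine():
    """F and every Tukey-adjusted p agree with scipy/statsmodels to 1e-6."""
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(3)
    M = _design(rng, [0.0, 0.3, 0.5, 1.0], n=4)
    res = anova_tukey(M, 2)
    y = M.data[2].to_numpy()
    labels = M.groups.to_numpy()
    groups = [y[labels == g] for g in pd.unique(labels)]
    f_ref = f_oneway(*groups)
    assert res.f_statistic == pytest.approx(f_ref.statistic, abs=1e-6)
    assert res.p_value == pytest.approx(f_ref.pvalue, abs=1e-6)
    ref = pairwise_tukeyhsd(y, labels, alpha=0.05)
    from itertools import combinations

    ref_df = pd.DataFrame(
        [
            {"group1": a, "group2": b, "ref_p": p, "ref_diff": d}
            for (a, b), p, d in zip(
                combinations(ref.groupsunique, 2), ref.pvalues, ref.meandiffs
            )
        ]
    )
    merged = res.tukey.merge(ref_df, on=["group1", "group2"])
    assert len(merged) == len(res.tukey)
    for _, row in merged.iterrows():
        assert row["p_adj"] == pytest.approx(float(row["ref_p"]), abs=1e-6)
        assert row["mean_diff"] == pytest.approx(float(row["ref_diff"]), abs=1e-6)


def test_p_values_invariant_to_shift_and_relabeling():
    rng = np.random.default_rng(4)
    M = _design(rng, [0.0, 0.2, 0.4, 0.9], n=4)
    base = anova_tukey(M, 0)
    shifted = GroupMatrix(M.data + 100.0, M.groups)
    res_shift = anova_tukey(shifted, 0)
    assert res_shift.p_value == pytest.approx(base.p_value, abs=1e-12)
    relabel = {"g0": "z", "g1": "y", "g2": "x", "g3": "w"}
    res_rel = anova_tukey(GroupMatrix(M.data, M.groups.map(relabel)), 0)
    assert res_rel.p_value == pytest.approx(base.p_value, abs=1e-12)
    assert sorted(res_rel.tukey["p_adj"]) == pytest.approx(
        sorted(base.tukey["p_adj"]), abs=1e-12
    )


def test_too_few_samples_rejected():
    M = _matrix([[1.0], [2.0]], groups=["a", "b"])
    with pytest.raises(InputError):
        anova_tukey(M, 0)


# ---------------------------------------------------------------------------
# Hierarchical clustering


def test_duplicate_pairs_merge_first_at_zero_height():
    rng = np.random.default_rng(5)
    a = rng.dirichlet(np.ones(12))
    b = rng.dirichlet(np.ones(12))
    tree = hcluster(_matrix([a, a, b, b]))
    assert tree.heights[0] == pytest.approx(0.0, abs=1e-12)
    assert tree.heights[1] == pytest.approx(0.0, abs=1e-12)
    first_two = {frozenset(s) for s in tree.node_sets[:2]}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}


def test_three_item_tree_matches_hand_computed_average_linkage():
    # construct rows with known pairwise correlation-distance structure
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    rows = [x, x[::-1], np.array([1.0, 2.2, 2.9, 4.1, 5.2, 5.8])]
    M = _matrix(rows)
    D = 1.0 - np.corrcoef(np.array(rows))
    # expected: items 0 and 2 merge first (most correlated), then join 1 at
    # the average of d(0,1) and d(2,1)
    tree = hcluster(M)
    assert tree.node_sets[0] == frozenset({0, 2})
    assert tree.heights[0] == pytest.approx(D[0, 2])
    assert tree.heights[1] == pytest.approx((D[0, 1] + D[2, 1]) / 2)


def test_topology_invariant_to_item_order():
    rng = np.random.default_rng(6)
    X = rng.dirichlet(np.ones(30), size=6)
    tree = hcluster(_matrix(X))
    perm = [3, 1, 5, 0, 4, 2]
    tree_p = hcluster(_matrix(X[perm]))
    remap = {new: old for new, old in enumerate(perm)}
    sets = {frozenset(s) for s in tree.node_sets}
    sets_p = {frozenset(remap[i] for i in s) for s in tree_p.node_sets}
    assert sets == sets_p


def test_invariant_to_positive_affine_rescaling():
    rng = np.random.default_rng(7)
    X = rng.dirichlet(np.ones(30), size=6)
    tree = hcluster(_matrix(X))
    X2 = X * rng.uniform(0.5, 3.0, size=(6, 1)) + rng.uniform(0, 1, size=(6, 1))
    tree2 = hcluster(_matrix(X2))
    assert [set(s) for s in tree.node_sets] == [set(s) for s in tree2.node_sets]


def test_zero_variance_item_rejected():
    X = [[0.25] * 4, [0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1]]
    with pytest.raises(InputError):
        hcluster(_matrix(X))


# ---------------------------------------------------------------------------
# Multiscale bootstrap


def _two_cluster_matrix(rng, n_items=8, n_cols=200):
    """Two blocks of highly correlated rows, uncorrelated across blocks."""
    base1 = rng.normal(0, 1, n_cols)
    base2 = rng.normal(0, 1, n_cols)
    rows = []
    for i in range(n_items // 2):
        rows.append(base1 + rng.normal(0, 0.3, n_cols))
    for i in range(n_items // 2):
        rows.append(base2 + rng.normal(0, 0.3, n_cols))
    return _matrix(rows)


def test_well_separated_clusters_have_high_bp():
    rng = np.random.default_rng(8)
    M = _two_cluster_matrix(rng)
    tree = bootstrap_support(M, n_boot=200, seed=1)
    left = frozenset(range(4))
    right = frozenset(range(4, 8))
    assert tree.bp[left] >= 0.95
    assert tree.bp[right] >= 0.95
    assert tree.au[left] >= 0.9


def test_iid_noise_has_no_strongly_supported_nodes():
    maxima = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        M = _matrix(rng.normal(0, 1, size=(8, 60)))
        tree = bootstrap_support(M, n_boot=150, seed=seed)
        nontrivial = [
            bp
            for s, bp in tree.bp.items()
            if 1 < len(s) < len(tree.items)
        ]
        maxima.append(max(nontrivial))
    assert np.median(maxima) < 0.8


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(9)
    M = _two_cluster_matrix(rng, n_items=6, n_cols=80)
    t1 = bootstrap_support(M, n_boot=150, seed=42)
    t2 = bootstrap_support(M, n_boot=150, seed=42)
    assert t1.bp == t2.bp
    assert t1.au == t2.au


def test_bootstrap_requires_enough_replicates():
    rng = np.random.default_rng(10)
    M = _two_cluster_matrix(rng, n_items=6, n_cols=40)
    with pytest.raises(InputError):
        bootstrap_support(M, n_boot=10, seed=0)


def test_support_table_and_json_round_trip(tmp_path):
    import json

    rng = np.random.default_rng(11)
    M = _two_cluster_matrix(rng, n_items=6, n_cols=60)
    tree = bootstrap_support(M, n_boot=150, seed=3)
    df = tree.support_table()
    assert {"members", "height", "bp", "au"} <= set(df.columns)
    tree.to_json(tmp_path / "tree.json")
    loaded = json.loads((tmp_path / "tree.json").read_text())
    assert len(loaded["nodes"]) == len(tree.node_sets)
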