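import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nichemap as nm
from nichemap.errors import ParameterError
from nichemap.stats import _soft_threshold_keep, holm_adjust
from _oracles import brute_pseudo_f


# ---------------------------------------------------------------- PERMANOVA

def test_degenerate_identical_rows_give_finite_f_and_p_one():
    X = pd.DataFrame(np.ones((8, 3)))
    labels = ["a"] * 4 + ["b"] * 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = nm.permanova(X, labels, n_permutations=99, seed=0)
    assert np.isfinite(res.pseudo_F)
    assert res.p_value == 1.0


def test_strong_separation_attains_minimum_p():
    rng = np.random.default_rng(0)
    n_per = 8
    X = np.vstack([rng.normal(0, 0.1, (n_per, 4)),
                   rng.normal(50, 0.1, (n_per, 4)),
                   rng.normal(-50, 0.1, (n_per, 4))])
    labels = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
    strata = list(range(n_per)) * 3
    res = nm.permanova(X, labels, strata=strata, n_permutations=999, seed=1)
    assert res.p_value == pytest.approx(1.0 / 1000.0)
    assert res.R2 > 0.99


def test_pseudo_f_matches_brute_force_definition():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 5))
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    res = nm.permanova(pd.DataFrame(X), labels, n_permutations=9, seed=0, scale=False)
    assert res.pseudo_F == pytest.approx(brute_pseudo_f(X, labels), rel=1e-10)


def test_pseudo_f_matches_scikit_bio():
    """Independent cross-check of the statistic against skbio's PERMANOVA."""
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova
    rng = np.random.default_rng(5)
    X = rng.normal(size=(15, 6))
    labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
    res = nm.permanova(pd.DataFrame(X), labels, n_permutations=9, seed=0, scale=False)
    from scipy.spatial.distance import pdist, squareform
    dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(15)])
    sk = sk_permanova(dm, grouping=labels, permutations=9)
    assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-10)


def test_permanova_invariances():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 4))
    X[:6] += 1.5
    labels = ["a"] * 6 + ["b"] * 6
    base = nm.permanova(pd.DataFrame(X), labels, n_permutations=199, seed=9)
    scaled = nm.permanova(pd.DataFrame(X * 37.0), labels, n_permutations=199, seed=9)
    assert base.p_value == scaled.p_value  # z-scoring absorbs positive scaling
    assert base.pseudo_F == pytest.approx(scaled.pseudo_F, rel=1e-10)
    perm = np.random.default_rng(0).permutation(12)
    reord = nm.permanova(pd.DataFrame(X[perm]), list(np.array(labels)[perm]),
                         n_permutations=199, seed=9)
    assert base.pseudo_F == pytest.approx(reord.pseudo_F, rel=1e-10)


def test_single_label_stratum_warns():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(8, 3)))
    labels = ["a", "b"] * 4
    strata = ["s1", "s1", "s2", "s2", "s3", "s3", "odd", "odd"]
    labels[6] = labels[7] = "a"  # stratum 'odd' carries one label only
    with pytest.warns(UserWarning, match="stratum"):
        nm.permanova(X, labels, strata=strata, n_permutations=19, seed=0)


# --------------------------------------------------------------------- Holm

def test_holm_arithmetic_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.20]), [0.03, 0.04, 0.20])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8))
def test_holm_dominates_raw(ps):
    holm = holm_adjust(ps)
    assert np.all(holm >= np.asarray(ps) - 1e-15)
    assert np.all(holm <= 1.0)


def test_pairwise_permanova_identical_groups_all_one():
    X = pd.DataFrame(np.ones((12, 3)))
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        contrasts = nm.pairwise_permanova(X, labels, n_permutations=49, seed=0)
    assert len(contrasts) == 3
    assert all(c.holm_p == 1.0 and c.holm_p >= c.raw_p for c in contrasts)


# ---------------------------------------------------------------------- PCA

def test_pca_equal_variance_features_contribute_equally():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["f1", "f2"])
    res = nm.pca_contributions(X)
    assert res.reference == 50.0
    np.testing.assert_allclose(res.contributions["PC1"], [50, 50], atol=7.0)
    assert res.contributions["PC1"].sum() == pytest.approx(100.0)


def test_pca_reference_line_formula():
    assert 100.0 / 4559 == pytest.approx(0.021935, abs=1e-5)
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(10, 40)))
    res = nm.pca_contributions(X)
    assert res.reference == pytest.approx(100.0 / 40)


def test_pca_dominant_feature_tops_component_one():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(scale=0.05, size=(60, 6)),
                     columns=[f"f{j}" for j in range(6)])
    X["f3"] += np.repeat([0.0, 4.0], 30)  # all between-group variance on f3
    res = nm.pca_contributions(X, scale=False)  # unscaled: f3 carries the spectrum
    assert res.top(1, 1).index[0] == "f3"
    assert res.contributions.loc["f3", "PC1"] > 99.0


def test_pca_drops_constant_feature_with_warning():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 1.0, 1.0, 1.0],
                      "c": [0.0, 1.0, 0.0, 1.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        res = nm.pca_contributions(X)
    assert res.dropped == ["b"]


# ------------------------------------------------------------------ sPLS-DA

def _two_class_data(seed=0, n=40, p=12):
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2), dtype=object)
    X = rng.normal(size=(n, p))
    X[y == "b", :3] += 2.0
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y


def test_dense_limit_matches_independent_pls(recwarn):
    """keepX = p: scores equal a tightly-converged NIPALS PLS2 (sklearn).

    Three classes keep the one-hot response full-rank on two components.
    """
    from sklearn.cross_decomposition import PLSRegression
    rng = np.random.default_rng(7)
    n, p = 40, 12
    y = np.array(["a"] * 14 + ["b"] * 13 + ["c"] * 13, dtype=object)
    X = rng.normal(size=(n, p))
    X[y == "b", :3] += 2.0
    X[y == "c", 5:8] -= 1.5
    X = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
    Xz, _ = nm.stats.zscore_columns(X)
    res = nm.SparsePLSDA(Xz, y, n_components=2, keep_x=X.shape[1],
                         scale=False, tol=1e-14, max_iter=5000).fit()
    Y = pd.get_dummies(pd.Categorical(y)).to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk = PLSRegression(n_components=2, scale=False, tol=1e-20,
                           max_iter=20000).fit(Xz.to_numpy(), Y - Y.mean(0))
    T, Tsk = res.scores.to_numpy(), sk.x_scores_
    for c in range(2):
        s = np.sign(T[:, c] @ Tsk[:, c])
        np.testing.assert_allclose(T[:, c], s * Tsk[:, c], atol=1e-8)


def test_single_informative_feature_selected_with_keepx_one():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
    y = np.array(["u"] * 15 + ["v"] * 15, dtype=object)
    X.loc[y == "v", "d"] += 5.0
    res = nm.splsda_fit(X, y, n_components=1, keep_x=1)
    assert res.selected[0] == ["d"]


def test_loadings_unit_norm_and_sparsity_contract():
    X, y = _two_class_data(4)
    res = nm.splsda_fit(X, y, n_components=2, keep_x=5)
    for c in range(2):
        w = res.x_weights.iloc[:, c].to_numpy()
        assert np.linalg.norm(w) == pytest.approx(1.0)
        assert np.count_nonzero(w) <= 5
    with pytest.raises(ParameterError):
        nm.splsda_fit(X, y, keep_x=0)


def test_selected_set_invariant_to_column_order():
    X, y = _two_class_data(5)
    res = nm.splsda_fit(X, y, n_components=1, keep_x=4)
    shuffled = X[list(X.columns[::-1])]
    res2 = nm.splsda_fit(shuffled, y, n_components=1, keep_x=4)
    assert set(res.selected[0]) == set(res2.selected[0])


def test_soft_threshold_keeps_largest_magnitudes():
    a = np.array([0.1, -3.0, 2.0, 0.5, -0.2])
    out = _soft_threshold_keep(a, 2)
    assert np.count_nonzero(out) == 2
    assert set(np.flatnonzero(out)) == {1, 2}
    np.testing.assert_allclose(_soft_threshold_keep(a, 5), a)


# -------------------------------------------------------- paired permutation

def test_all_zero_differences_give_p_one():
    res = nm.paired_permutation_test(np.zeros(16), np.zeros(16))
    assert res.p_value == 1.0 and res.statistic == 0.0


def test_exact_enumeration_same_sign_differences():
    """n=10 all-positive differences: only identity and full flip reach |t|,
    so the exact two-sided p is 2/1024."""
    d = np.array([1.0, 2.0, 1.5, 0.7, 1.2, 0.9, 1.8, 1.1, 0.8, 1.3])
    res = nm.paired_permutation_test(d, np.zeros(10), n_permutations=9999)
    assert res.exact and res.n_permutations == 1024
    assert res.p_value == pytest.approx(2.0 / 1024.0)


def test_too_few_pairs_rejected():
    with pytest.raises(ParameterError):
        nm.paired_permutation_test([1.0, 2.0], [0.0, 0.0])


def test_paired_test_null_calibration():
    """Sign-flip null on exchangeable pairs rejects ~5% at alpha 0.05."""
    rng = np.random.default_rng(0)
    rejections = 0
    reps = 500
    for _ in range(reps):
        d = rng.normal(size=8)
        res = nm.paired_permutation_test(d, np.zeros(8))
        rejections += res.p_value <= 0.05
    assert 0.02 <= rejections / reps <= 0.08


# --------------------------------------------------------------- imputation

def test_impute_policy_and_no_op():
    idx = pd.MultiIndex.from_tuples(
        [("P01", "tumor"), ("P01", "nontumor"), ("P02", "tumor"), ("P02", "nontumor")],
        names=["patient_id", "region_class"],
    )
    complete = pd.DataFrame({"density_A": [1.0, 2.0, 3.0, 4.0]}, index=idx)
    fm = nm.FeatureMatrix(data=complete, clusters=["A"])
    pd.testing.assert_frame_equal(nm.impute_missing(fm).data, complete)

    df = pd.DataFrame(
        {"dist_A_B": [5.0, np.nan, 7.0, np.nan],
         "neigh_A_B": [0.5, np.nan, 0.2, np.nan],
         "count_B": [3.0, np.nan, 1.0, np.nan]},
        index=idx,
    )
    out = nm.impute_missing(nm.FeatureMatrix(data=df, clusters=["A", "B"])).data
    assert out.loc[("P01", "nontumor"), "dist_A_B"] == 1000.0
    assert out.loc[("P01", "nontumor"), "neigh_A_B"] == 0.0
    assert out.loc[("P01", "nontumor"), "count_B"] == 0.0


def test_impute_then_zscore_matches_hand_computation():
    idx = pd.MultiIndex.from_tuples(
        [("P01", "tumor"), ("P02", "tumor"), ("P03", "tumor")],
        names=["patient_id", "region_class"],
    )
    df = pd.DataFrame({"dist_A_B": [800.0, np.nan, 600.0]}, index=idx)
    out = nm.impute_missing(nm.FeatureMatrix(data=df, clusters=["A", "B"])).data
    z, _ = nm.stats.zscore_columns(out)
    filled = np.array([800.0, 1000.0, 600.0])
    expected = (filled - filled.mean()) / filled.std(ddof=1)
    np.testing.assert_allclose(z["dist_A_B"], expected)
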