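"""PCA on standardized metrics, Ward clustering on scores, cluster comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from repmap import ValidationError, compare_clusters, hcpc, run_pca
from repmap.metrics import METRIC_COLUMNS


def _table(X, index=None, group=None):
    cols = list(METRIC_COLUMNS)[: X.shape[1]]
    df = pd.DataFrame(X, columns=cols)
    df.index = index if index is not None else [f"r{i}" for i in range(len(df))]
    if group is not None:
        df["respondent_group"] = group
    return df, cols


# -- PCA ---------------------------------------------------------------------


def test_pca_eigenvalues_match_correlation_eigendecomposition():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 9))
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    expected = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    np.testing.assert_allclose(pca.eigenvalues, expected, atol=1e-8)
    # correlation PCA: total inertia = number of active variables
    assert pca.eigenvalues.sum() == pytest.approx(9.0)
    assert pca.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)


def test_pca_scores_covariance_diagonal_eigenvalues():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 5))
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    S = pca.scores.to_numpy()
    cov = (S - S.mean(0)).T @ (S - S.mean(0)) / len(S)
    np.testing.assert_allclose(cov, np.diag(pca.eigenvalues), atol=1e-10)


def test_pca_single_varying_variable():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(10, 1))
    # three perfectly correlated columns: one underlying dimension
    X = np.hstack([base, 2 * base, -base])
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    assert pca.percent_variance[0] == pytest.approx(100.0)


def test_pca_sign_convention_and_supplementary_centroids():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 4))
    groups = ["a"] * 6 + ["b"] * 6
    df, cols = _table(X, group=groups)
    pca = run_pca(df, active_columns=cols)
    for j, axis in enumerate(pca.loadings.columns):
        lead = pca.loadings[axis].abs().idxmax()
        assert pca.loadings.loc[lead, axis] > 0
    centroid_a = pca.scores.iloc[:6].mean()
    pd.testing.assert_series_equal(
        pca.supplementary_coords.loc["a"], centroid_a, check_names=False
    )


def test_pca_constant_column_error():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 3))
    X[:, 1] = 7.0
    df, cols = _table(X)
    with pytest.raises(ValidationError, match="n_links"):
        run_pca(df, supplementary=None, active_columns=cols)


# -- hierarchical clustering -------------------------------------------------


def _separated_clouds(rng, n=10, gap=50.0):
    a = rng.normal(size=(n, 3))
    b = rng.normal(size=(n, 3)) + gap
    X = np.vstack([a, b])
    labels = np.array([0] * n + [1] * n)
    return X, labels


def test_hcpc_recovers_separated_clouds():
    rng = np.random.default_rng(5)
    X, planted = _separated_clouds(rng)
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    result = hcpc(pca, k="auto")
    assert result.k == 2
    assert adjusted_rand_score(planted, result.labels) == 1.0
    assert result.within_inertia + result.between_inertia == pytest.approx(
        result.total_inertia, abs=1e-9
    )


def test_hcpc_singletons_and_duplicates():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(6, 3))
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    singles = hcpc(pca, k=6)
    assert singles.within_inertia == pytest.approx(0.0, abs=1e-12)
    assert singles.labels.nunique() == 6
    # duplicate every row: duplicates must share a cluster at k = n
    X2 = np.repeat(X, 2, axis=0)
    df2, _ = _table(X2)
    pca2 = run_pca(df2, supplementary=None, active_columns=cols)
    res = hcpc(pca2, k=6)
    labs = res.labels.to_numpy()
    assert all(labs[2 * i] == labs[2 * i + 1] for i in range(6))


def test_hcpc_ward_heights_nondecreasing():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 4))
    df, cols = _table(X)
    result = hcpc(run_pca(df, supplementary=None, active_columns=cols), k=3)
    heights = result.linkage_matrix[:, 2]
    assert (np.diff(heights) >= -1e-12).all()


def test_hcpc_k_bounds():
    rng = np.random.default_rng(8)
    df, cols = _table(rng.normal(size=(5, 3)))
    pca = run_pca(df, supplementary=None, active_columns=cols)
    with pytest.raises(ValidationError, match="outside"):
        hcpc(pca, k=9)


def test_hcpc_consolidation_deterministic():
    rng = np.random.default_rng(9)
    X, _ = _separated_clouds(rng, n=8)
    df, cols = _table(X)
    pca = run_pca(df, supplementary=None, active_columns=cols)
    a = hcpc(pca, k=2, consolidate=True, seed=5)
    b = hcpc(pca, k=2, consolidate=True, seed=5)
    pd.testing.assert_series_equal(a.labels, b.labels)


# -- comparison --------------------------------------------------------------


def test_compare_identical_clusters_t_zero_p_one():
    rows = np.array([[1.0, 2.0], [3.0, 5.0], [5.0, 9.0]])
    X = np.vstack([rows, rows])
    df, cols = _table(X, group=["researcher"] * 6)
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=df.index)
    comp = compare_clusters(df, labels, active_columns=cols)
    assert (comp.stats["t"].abs() < 1e-12).all()
    assert np.allclose(comp.stats["p_value"], 1.0)
    assert comp.composition.to_numpy().sum() == 6


def test_compare_clusters_textbook_pooled_t():
    """Groups {1..5} vs {2..6}: pooled-variance t = -1, p = 2 P(T_8 < -1)."""
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    df, cols = _table(X)
    labels = pd.Series([1] * 5 + [2] * 5, index=df.index)
    comp = compare_clusters(df, labels, active_columns=cols)
    row = comp.stats.loc[cols[0]]
    assert row["mean_1"] == pytest.approx(3.0)
    assert row["mean_2"] == pytest.approx(4.0)
    assert row["sd_1"] == pytest.approx(np.sqrt(2.5))
    assert row["t"] == pytest.approx(-1.0)
    assert row["p_value"] == pytest.approx(0.3465935, abs=1e-6)


def test_compare_clusters_requires_size_two():
    rng = np.random.default_rng(10)
    df, cols = _table(rng.normal(size=(4, 2)))
    labels = pd.Series([1, 2, 2, 2], index=df.index)
    with pytest.raises(ValidationError, match="size >= 2"):
        compare_clusters(df, labels, active_columns=cols)


def test_compare_clusters_holm_adjusts_upward():
    rng = np.random.default_rng(11)
    df, cols = _table(rng.normal(size=(12, 4)))
    labels = pd.Series([1] * 6 + [2] * 6, index=df.index)
    comp = compare_clusters(df, labels, active_columns=cols, holm=True)
    assert (comp.stats["p_holm"] >= comp.stats["p_value"] - 1e-12).all()
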