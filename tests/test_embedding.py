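"""Sparse-PCA embedding, BIC formula, model selection and cluster utilities."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from habclust.embedding import (
    BICGaussianMixture,
    FeatureTable,
    HistogramSparsePCA,
    build_feature_table,
    compute_bic,
    embed_tsne,
    feature_importance,
    order_clusters,
    select_k,
)


def _scalars(n, rng=None, rates=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "neuron_id": [f"n{i}" for i in range(n)],
            "rate": rates if rates is not None else rng.uniform(1, 20, n),
            "cv": rng.uniform(0.5, 1.5, n),
            "burst_index": rng.uniform(0, 0.3, n),
        }
    )


# ---------------------------------------------------------------------------
# Sparse PCA
# ---------------------------------------------------------------------------


def test_rank_one_bank_concentrates_in_first_component():
    rng = np.random.default_rng(0)
    loading = rng.standard_normal(50)
    weights = rng.standard_normal(40)[:, None]
    bank = weights * loading[None, :] + 1e-9 * rng.standard_normal((40, 50))
    est = HistogramSparsePCA(n_components=4, penalty=0.0).fit(bank)
    scores = est.transform(bank)
    var = scores.var(axis=0)
    assert var[0] / var.sum() > 0.999
    assert np.all(var[1:] < 1e-6 * var[0])


def test_zero_penalty_matches_dense_pca_exactly():
    rng = np.random.default_rng(1)
    bank = rng.standard_normal((60, 30)) @ rng.standard_normal((30, 30))
    est = HistogramSparsePCA(n_components=5, penalty=0.0).fit(bank)
    Z = (bank - bank.mean(0)) / bank.std(0)
    ref = PCA(n_components=5).fit(Z)
    np.testing.assert_allclose(
        est.transform(bank).var(axis=0, ddof=1),
        ref.explained_variance_,
        rtol=1e-6,
    )


def test_positive_penalty_sparsifies_loadings():
    rng = np.random.default_rng(2)
    bank = rng.standard_normal((80, 40))
    dense = HistogramSparsePCA(n_components=4, penalty=0.0).fit(bank)
    sparse = HistogramSparsePCA(n_components=4, penalty=2.0).fit(bank)
    assert dense.sparsity_ == 0.0
    assert sparse.sparsity_ > 0.2


def test_duplicated_rows_get_identical_scores():
    rng = np.random.default_rng(3)
    bank = rng.standard_normal((30, 25))
    doubled = np.vstack([bank, bank])
    est = HistogramSparsePCA(n_components=3, penalty=0.5).fit(doubled)
    scores = est.transform(doubled)
    np.testing.assert_allclose(scores[:30], scores[30:], atol=1e-10)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


def test_feature_table_is_exactly_19_columns():
    rng = np.random.default_rng(4)
    for n in (270, 295):
        table = build_feature_table(
            _scalars(n, rng), rng.standard_normal((n, 8)), rng.standard_normal((n, 8))
        )
        assert table.matrix.shape == (n, 19)
        z = table.standardized
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-10)


def test_feature_table_rejects_degenerate_inputs():
    rng = np.random.default_rng(5)
    with pytest.raises(ValueError, match="fewer than two"):
        build_feature_table(_scalars(1), np.zeros((1, 8)), np.zeros((1, 8)))
    with pytest.raises(ValueError, match="[Mm]ismatch"):
        build_feature_table(
            _scalars(5), rng.standard_normal((4, 8)), rng.standard_normal((5, 8))
        )
    with pytest.raises(ValueError, match="19"):
        FeatureTable(
            neuron_ids=["a"], matrix=np.zeros((1, 7)),
            col_mean=np.zeros(7), col_sd=np.ones(7),
        )


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------


def test_bic_formula_natural_log():
    assert compute_bic(-100.0, 10, 50) == pytest.approx(200 + 10 * np.log(50))
    assert compute_bic(-100.0, 0, 50) == pytest.approx(200.0)
    assert compute_bic(-100.0, 10, 1) == pytest.approx(200.0)
    with pytest.raises(ValueError):
        compute_bic(-1.0, 1, 0)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def _blobs(rng, centers, n_each, d=19, scale=1.0):
    X = np.vstack(
        [c + scale * rng.standard_normal((n_each, d)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_each)
    return X, labels


def test_two_separated_blobs_select_k2():
    """Blobs 10 within-SD apart in every dimension are split, not merged."""
    rng = np.random.default_rng(6)
    X, _ = _blobs(rng, [np.zeros(19), np.full(19, 10.0)], n_each=100)
    est = BICGaussianMixture(k_grid=tuple(range(1, 6)), n_restarts=15, random_state=0)
    assert est.fit(X).selected_k_ == 2


def test_single_blob_selects_k1():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((200, 19))
    est = BICGaussianMixture(k_grid=tuple(range(1, 5)), n_restarts=15, random_state=0)
    assert est.fit(X).selected_k_ == 1


def test_selection_is_deterministic_given_seed():
    rng = np.random.default_rng(8)
    X, _ = _blobs(rng, [np.zeros(19), np.full(19, 3.0)], n_each=60)
    a = BICGaussianMixture(k_grid=(1, 2, 3), n_restarts=10, random_state=1).fit(X)
    b = BICGaussianMixture(k_grid=(1, 2, 3), n_restarts=10, random_state=1).fit(X)
    np.testing.assert_array_equal(a.labels_, b.labels_)
    np.testing.assert_allclose(
        a.bic_table_["bic_mean"], b.bic_table_["bic_mean"]
    )


# ---------------------------------------------------------------------------
# Importance / ordering / t-SNE
# ---------------------------------------------------------------------------


def _fitted_model(X, ids, k, seed=0):
    table = FeatureTable(
        neuron_ids=ids,
        matrix=X,
        col_mean=X.mean(0),
        col_sd=np.where(X.std(0) > 0, X.std(0), 1.0),
    )
    model = select_k(table, k_grid=(k,), n_restarts=10, seed=seed)
    return table, model


def test_importance_concentrates_on_the_splitting_feature():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((400, 19))
    X[:200, 5] += 12.0  # clusters differ only in feature index 5
    table, model = _fitted_model(X, [f"n{i}" for i in range(400)], k=2)
    imp = feature_importance(model, table)
    assert imp.shape == (2, 19)
    assert np.all(imp >= 0)
    for row in imp:
        assert np.argmax(row) == 5
        assert row[5] > 2 * np.max(np.delete(row, 5))


def test_importance_invariant_to_relabeling_up_to_row_permutation():
    rng = np.random.default_rng(10)
    X = np.vstack([rng.standard_normal((30, 19)), rng.standard_normal((30, 19)) + 4])
    table, model = _fitted_model(X, [f"n{i}" for i in range(60)], k=2, seed=0)
    imp = feature_importance(model, table)
    swapped = order_clusters(model, table)
    imp2 = feature_importance(swapped, table)
    assert sorted(map(tuple, np.round(imp, 10))) == sorted(map(tuple, np.round(imp2, 10)))


def test_order_clusters_sorts_by_rate_with_burst_tiebreak():
    rng = np.random.default_rng(11)
    # three clusters split on feature 5; rates 10, 2, 2 with bursts 0.3, 0.2, 0.05
    X = rng.standard_normal((90, 19)) * 0.01
    X[:30, 5] += 6
    X[30:60, 5] -= 6
    X[:30, 0] = 10.0
    X[30:60, 0] = 2.0
    X[60:, 0] = 2.0
    X[:30, 2] = 0.30
    X[30:60, 2] = 0.20
    X[60:, 2] = 0.05
    table, model = _fitted_model(X, [f"n{i}" for i in range(90)], k=3)
    ordered = order_clusters(model, table)
    rates = [
        table.matrix[ordered.labels == k, 0].mean() for k in (1, 2, 3)
    ]
    bursts = [
        table.matrix[ordered.labels == k, 2].mean() for k in (1, 2, 3)
    ]
    assert rates[0] == pytest.approx(rates[1])  # the tied pair comes first
    assert rates[2] == pytest.approx(10.0, abs=0.1)
    assert bursts[0] < bursts[1]  # tie broken by ascending burst index
    # applying the ordering twice is the identity
    again = order_clusters(ordered, table)
    np.testing.assert_array_equal(again.labels, ordered.labels)


def test_tsne_shape_determinism_and_neighborhoods():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.standard_normal((30, 19)), rng.standard_normal((30, 19)) + 12])
    table = FeatureTable(
        neuron_ids=[f"n{i}" for i in range(60)],
        matrix=X,
        col_mean=X.mean(0),
        col_sd=X.std(0),
    )
    a = embed_tsne(table, seed=3)
    b = embed_tsne(table, seed=3)
    assert a.shape == (60, 2)
    np.testing.assert_array_equal(a, b)
    # points from the same well-separated blob stay closer on average
    within = np.linalg.norm(a[:30] - a[:30].mean(0), axis=1).mean()
    between = np.linalg.norm(a[:30].mean(0) - a[30:].mean(0))
    assert between > within
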