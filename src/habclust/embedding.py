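"""Feature embedding and mixture-model clustering.

The clustering operates on 19 features per neuron: mean firing rate,
ISI coefficient of variation, burst index, the first eight sparse
principal components of the ISI distribution and the first eight of the
autocorrelogram.  A Gaussian mixture is fitted for every candidate
cluster number with 100 random restarts, the Bayesian information
criterion ``BIC = -2 log L + M log N`` (natural log) is averaged over
restarts, and the cluster number is chosen at the smallest mean BIC or
at the point where its gradient saturates.

Estimators follow scikit-learn conventions (``fit`` / ``transform`` /
``predict``, fitted attributes with trailing underscores) and compose
with scikit-learn pipelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA, MiniBatchSparsePCA
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .features import compute_scalar_features, histogram_bank
from .io_formats import RunConfig, SpikeTrain

logger = logging.getLogger("habclust")

SCALAR_NAMES = ("rate", "cv", "burst_index")
FEATURE_NAMES: tuple[str, ...] = SCALAR_NAMES + tuple(
    f"isi_pc{i+1}" for i in range(8)
) + tuple(f"acg_pc{i+1}" for i in range(8))


# ---------------------------------------------------------------------------
# Sparse PCA over histogram banks
# ---------------------------------------------------------------------------


class HistogramSparsePCA(TransformerMixin, BaseEstimator):
    """Sparse PCA over a per-neuron histogram bank.

    Each bin column is z-scored across neurons before fitting (constant
    columns are dropped with a warning).  With ``penalty == 0`` the
    transform is ordinary PCA, which the sparse solution approaches as
    the penalty vanishes; with ``penalty > 0`` loadings are sparsified
    by an L1 term, solved with scikit-learn's mini-batch dictionary
    learner for speed.

    Parameters
    ----------
    n_components : int, default 8
    penalty : float, default 1.0
        L1 sparsity penalty on the loadings; 0 means dense PCA.  The
        default zeroes roughly half of the loading entries on the
        synthetic presets.
    random_state : int or None
        Seeds the sparse solver (the penalty-0 path is deterministic).
    """

    def __init__(self, n_components: int = 8, penalty: float = 1.0,
                 random_state: int | None = 0, max_iter: int = 500):
        self.n_components = n_components
        self.penalty = penalty
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= self.n_components:
            raise ValueError("need more neurons than components")
        self.col_mean_ = X.mean(axis=0)
        col_sd = X.std(axis=0, ddof=0)
        self.keep_ = col_sd > 0
        if not self.keep_.all():
            warnings.warn(
                f"dropping {int((~self.keep_).sum())} constant histogram columns"
            )
        self.col_sd_ = np.where(self.keep_, col_sd, 1.0)
        Z = self._zscore(X)
        if self.penalty == 0:
            self._model_ = PCA(n_components=self.n_components)
        else:
            self._model_ = MiniBatchSparsePCA(
                n_components=self.n_components,
                alpha=self.penalty,
                ridge_alpha=0.01,
                max_iter=self.max_iter,
                random_state=self.random_state,
            )
        self._model_.fit(Z)
        self.loadings_ = self._model_.components_
        return self

    def _zscore(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.col_mean_) / self.col_sd_
        return Z[:, self.keep_]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        return self._model_.transform(self._zscore(X))

    @property
    def sparsity_(self) -> float:
        """Fraction of exactly-zero loading entries."""
        check_is_fitted(self, "loadings_")
        return float(np.mean(self.loadings_ == 0))


def fit_sparse_pca(
    bank: np.ndarray,
    n_components: int = 8,
    penalty: float = 1.0,
    random_state: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit sparse PCA on a histogram bank; returns (loadings, scores)."""
    est = HistogramSparsePCA(n_components=n_components, penalty=penalty,
                             random_state=random_state)
    scores = est.fit(bank).transform(bank)
    return est.loadings_, scores


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Per-neuron 19-dimensional feature matrix with its scaling.

    ``matrix`` holds raw (unstandardized) features; ``col_mean`` and
    ``col_sd`` are the standardization parameters actually used by the
    mixture fit, which may come from a pooled dataset when two
    conditions share a feature space.
    """

    neuron_ids: list[str]
    matrix: np.ndarray  # n x 19, raw scale
    col_mean: np.ndarray
    col_sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    isi_loadings: np.ndarray | None = None
    acg_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix must have {len(self.feature_names)} columns"
            )
        if len(self.neuron_ids) != self.matrix.shape[0]:
            raise ValueError("neuron_ids length does not match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains undefined entries")

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def standardized(self) -> np.ndarray:
        return (self.matrix - self.col_mean) / self.col_sd

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "neuron_id", self.neuron_ids)
        return df


def build_feature_table(
    scalars: pd.DataFrame,
    isi_scores: np.ndarray,
    acg_scores: np.ndarray,
    isi_loadings: np.ndarray | None = None,
    acg_loadings: np.ndarray | None = None,
    scaling_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureTable:
    """Assemble the 19-feature table from scalars and component scores.

    ``scalars`` must have columns ``neuron_id, rate, cv, burst_index``
    in the same neuron order as the score matrices.  ``scaling_stats``
    overrides the per-column standardization (mean, sd), e.g. with
    pooled statistics shared between two datasets.
    """
    n = len(scalars)
    if isi_scores.shape[0] != n or acg_scores.shape[0] != n:
        raise ValueError("mismatched neuron sets between scalars and scores")
    if n < 2:
        raise ValueError("cannot standardize features of fewer than two neurons")
    matrix = np.column_stack(
        [scalars[list(SCALAR_NAMES)].to_numpy(dtype=float), isi_scores, acg_scores]
    )
    if scaling_stats is None:
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=0)
    else:
        mean, sd = scaling_stats
    sd = np.where(sd > 0, sd, 1.0)
    return FeatureTable(
        neuron_ids=[str(x) for x in scalars["neuron_id"]],
        matrix=matrix,
        col_mean=np.asarray(mean, dtype=float),
        col_sd=np.asarray(sd, dtype=float),
        isi_loadings=isi_loadings,
        acg_loadings=acg_loadings,
    )


def extract_feature_tables(
    groups: list[list[SpikeTrain]],
    config: RunConfig | None = None,
) -> list[FeatureTable]:
    """Extract feature tables for one or more datasets in a shared space.

    The sparse-PCA banks and the per-column standardization are fitted
    on the pooled neurons of all groups, so centroids from different
    groups live on common axes — a prerequisite for cross-condition
    cluster matching.  Neurons with fewer than ``config.min_spikes``
    spikes are excluded (with a log message).
    """
    cfg = config or RunConfig()
    kept_groups: list[list[SpikeTrain]] = []
    for trains in groups:
        kept = [t for t in trains if t.n_spikes >= cfg.min_spikes]
        if len(kept) < len(trains):
            logger.info(
                "excluding %d neurons with < %d spikes", len(trains) - len(kept),
                cfg.min_spikes,
            )
        kept_groups.append(kept)
    pooled = [t for g in kept_groups for t in g]
    if len(pooled) < 2:
        raise ValueError("need at least two neurons with enough spikes")
    isi_bank = histogram_bank(pooled, "isi", cfg.isi_bin_width, cfg.isi_max)
    acg_bank = histogram_bank(pooled, "acg", cfg.acg_bin_width, cfg.acg_max)
    isi_pca = HistogramSparsePCA(cfg.n_components, cfg.spca_penalty, cfg.seed)
    acg_pca = HistogramSparsePCA(cfg.n_components, cfg.spca_penalty, cfg.seed)
    isi_scores = isi_pca.fit(isi_bank).transform(isi_bank)
    acg_scores = acg_pca.fit(acg_bank).transform(acg_bank)
    scalars = pd.DataFrame(
        [compute_scalar_features(t, cfg.burst_threshold).__dict__ for t in pooled]
    )
    pooled_matrix = np.column_stack(
        [scalars[list(SCALAR_NAMES)].to_numpy(dtype=float), isi_scores, acg_scores]
    )
    mean = pooled_matrix.mean(axis=0)
    sd = pooled_matrix.std(axis=0, ddof=0)
    tables = []
    start = 0
    for kept in kept_groups:
        stop = start + len(kept)
        tables.append(
            build_feature_table(
                scalars.iloc[start:stop],
                isi_scores[start:stop],
                acg_scores[start:stop],
                isi_loadings=isi_pca.loadings_,
                acg_loadings=acg_pca.loadings_,
                scaling_stats=(mean, sd),
            )
        )
        start = stop
    return tables


# ---------------------------------------------------------------------------
# BIC and mixture-model selection
# ---------------------------------------------------------------------------


def compute_bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``-2 log L + M ln N``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_obs)


def _gmm_n_params(k: int, d: int, covariance_type: str) -> int:
    """Free parameters of a k-component mixture in d dimensions."""
    cov = {
        "full": k * d * (d + 1) // 2,
        "diag": k * d,
        "tied": d * (d + 1) // 2,
        "spherical": k,
    }[covariance_type]
    return (k - 1) + k * d + cov


class BICGaussianMixture(ClusterMixin, BaseEstimator):
    """Gaussian mixture with restart-averaged BIC model selection.

    For each candidate cluster number ``k`` the mixture is fitted from
    ``n_restarts`` randomly seeded initializations (k-means based by
    default, so restarts explore distinct local optima without
    degenerate starts) and the per-restart BIC is recorded.  The selected ``k`` is the smallest whose mean BIC is at
    the grid minimum or whose mean-BIC gradient has saturated, i.e.
    ``|dBIC(k -> k+1)| < saturation_frac * |dBIC(k_min -> k_min+1)|``.
    Final labels come from the best-BIC restart at the selected ``k``.

    Attributes (after ``fit``)
    --------------------------
    selected_k_ : int
    labels_ : ndarray of int, 1-based cluster labels
    bic_table_ : DataFrame with columns k, bic_mean, bic_ci_low, bic_ci_high
    weights_, means_, covariances_ : mixture parameters (input scale)
    responsibilities_ : n x k posterior membership
    feature_importance_ : k x d, |cluster mean - global mean| per feature
    """

    def __init__(
        self,
        k_grid: tuple[int, ...] = tuple(range(1, 9)),
        n_restarts: int = 100,
        covariance_type: str = "full",
        reg_covar: float = 1e-6,
        saturation_frac: float = 0.1,
        max_iter: int = 200,
        init_params: str = "kmeans",
        random_state: int | None = 0,
    ):
        self.k_grid = k_grid
        self.n_restarts = n_restarts
        self.covariance_type = covariance_type
        self.reg_covar = reg_covar
        self.saturation_frac = saturation_frac
        self.max_iter = max_iter
        self.init_params = init_params
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, d = X.shape
        k_grid = [k for k in sorted(set(self.k_grid)) if 1 <= k <= n]
        if not k_grid:
            raise ValueError("empty k grid")
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(len(k_grid) * self.n_restarts).reshape(
            len(k_grid), self.n_restarts
        )
        bic = np.full((len(k_grid), self.n_restarts), np.nan)
        for i, k in enumerate(k_grid):
            m_params = _gmm_n_params(k, d, self.covariance_type)
            for r in range(self.n_restarts):
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=self.covariance_type,
                    reg_covar=self.reg_covar,
                    max_iter=self.max_iter,
                    n_init=1,
                    init_params=self.init_params,
                    random_state=int(seeds[i, r] % (2**31 - 1)),
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        gm.fit(X)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                loglik = float(gm.score(X)) * n
                bic[i, r] = compute_bic(loglik, m_params, n)
            if np.isnan(bic[i]).all():
                warnings.warn(f"no restart converged at k={k}; skipping")
        # drop k values where everything failed
        ok = ~np.isnan(bic).all(axis=1)
        k_arr = np.asarray(k_grid)[ok]
        bic = bic[ok]
        seeds = seeds[ok]
        mean_bic = np.nanmean(bic, axis=1)
        sem = stats.sem(bic, axis=1, nan_policy="omit")
        ci = 1.96 * np.asarray(sem)
        self.bic_table_ = pd.DataFrame(
            {
                "k": k_arr,
                "bic_mean": mean_bic,
                "bic_ci_low": mean_bic - ci,
                "bic_ci_high": mean_bic + ci,
            }
        )
        self.selected_k_ = self._select_k(k_arr, mean_bic)
        sel = int(np.flatnonzero(k_arr == self.selected_k_)[0])
        best_r = int(np.nanargmin(bic[sel]))
        gm = GaussianMixture(
            n_components=self.selected_k_,
            covariance_type=self.covariance_type,
            reg_covar=self.reg_covar,
            max_iter=self.max_iter,
            n_init=1,
            init_params=self.init_params,
            random_state=int(seeds[sel, best_r] % (2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        self._gmm_ = gm
        self.weights_ = gm.weights_
        self.means_ = gm.means_
        self.covariances_ = gm.covariances_
        self.responsibilities_ = gm.predict_proba(X)
        self.labels_ = gm.predict(X) + 1
        self.feature_importance_ = np.abs(self.means_ - X.mean(axis=0))
        empty = np.setdiff1d(np.arange(1, self.selected_k_ + 1), self.labels_)
        if empty.size:
            warnings.warn(f"empty clusters {empty.tolist()} in the best fit")
            self.feature_importance_[empty - 1] = 0.0
        return self

    def _select_k(self, k_arr: np.ndarray, mean_bic: np.ndarray) -> int:
        """Smallest k at the BIC minimum or where its gradient saturates.

        The gradient is considered saturated when the improvement gained
        by the step into k falls below ``saturation_frac`` times the
        improvement of the preceding step; the scan stops at the grid
        minimum, so regions where BIC rises again cannot trigger it.
        """
        if len(k_arr) == 1:
            return int(k_arr[0])
        k_min_idx = int(np.argmin(mean_bic))
        imp = -np.diff(mean_bic)  # imp[i] > 0: step k_arr[i] -> k_arr[i+1] improves
        for i in range(k_min_idx + 1):
            if i == k_min_idx:
                return int(k_arr[i])
            if i >= 1 and imp[i] < self.saturation_frac * max(imp[i - 1], 0.0):
                return int(k_arr[i])
        return int(k_arr[k_min_idx])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_gmm_")
        return self._gmm_.predict(np.asarray(X, dtype=float)) + 1

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def bic_curve(self) -> pd.DataFrame:
        check_is_fitted(self, "bic_table_")
        return self.bic_table_.copy()


def select_k(
    features: FeatureTable,
    k_grid: tuple[int, ...] = tuple(range(1, 9)),
    n_restarts: int = 100,
    seed: int | None = 0,
    **kwargs,
) -> "ClusterModel":
    """Fit the restart-averaged mixture on standardized features and
    package the result as a :class:`ClusterModel`."""
    est = BICGaussianMixture(
        k_grid=k_grid, n_restarts=n_restarts, random_state=seed, **kwargs
    )
    est.fit(features.standardized)
    return ClusterModel.from_estimator(est, features)


# ---------------------------------------------------------------------------
# Fitted-model container, ordering, importance
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """A fitted and selected mixture over a feature table."""

    neuron_ids: list[str]
    feature_names: tuple[str, ...]
    k_grid: np.ndarray
    bic_mean: np.ndarray
    bic_ci: np.ndarray  # (len(k_grid), 2)
    selected_k: int
    weights: np.ndarray
    means: np.ndarray  # standardized feature space
    covariances: np.ndarray
    labels: np.ndarray  # 1-based
    responsibilities: np.ndarray
    feature_importance: np.ndarray  # k x d
    col_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_sd: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_estimator(cls, est: BICGaussianMixture, features: FeatureTable) -> "ClusterModel":
        tab = est.bic_table_
        return cls(
            neuron_ids=list(features.neuron_ids),
            feature_names=features.feature_names,
            k_grid=tab["k"].to_numpy(),
            bic_mean=tab["bic_mean"].to_numpy(),
            bic_ci=tab[["bic_ci_low", "bic_ci_high"]].to_numpy(),
            selected_k=est.selected_k_,
            weights=est.weights_,
            means=est.means_,
            covariances=est.covariances_,
            labels=est.labels_,
            responsibilities=est.responsibilities_,
            feature_importance=est.feature_importance_,
            col_mean=features.col_mean,
            col_sd=features.col_sd,
        )

    @property
    def centroids_raw(self) -> np.ndarray:
        """Cluster means de-standardized back to feature units."""
        return self.means * self.col_sd + self.col_mean

    def to_dict(self) -> dict:
        return {
            "neuron_ids": self.neuron_ids,
            "feature_names": list(self.feature_names),
            "k_grid": self.k_grid,
            "bic_mean": self.bic_mean,
            "bic_ci": self.bic_ci,
            "selected_k": self.selected_k,
            "weights": self.weights,
            "means": self.means,
            "covariances": self.covariances,
            "labels": self.labels,
            "responsibilities": self.responsibilities,
            "feature_importance": self.feature_importance,
            "col_mean": self.col_mean,
            "col_sd": self.col_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            neuron_ids=[str(x) for x in d["neuron_ids"]],
            feature_names=tuple(d["feature_names"]),
            k_grid=np.asarray(d["k_grid"]),
            bic_mean=np.asarray(d["bic_mean"], dtype=float),
            bic_ci=np.asarray(d["bic_ci"], dtype=float),
            selected_k=int(d["selected_k"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            labels=np.asarray(d["labels"], dtype=int),
            responsibilities=np.asarray(d["responsibilities"], dtype=float),
            feature_importance=np.asarray(d["feature_importance"], dtype=float),
            col_mean=np.asarray(d["col_mean"], dtype=float),
            col_sd=np.asarray(d["col_sd"], dtype=float),
        )


def feature_importance(model: ClusterModel, features: FeatureTable) -> np.ndarray:
    """Per-cluster feature importance: |cluster mean - global mean|.

    Computed in standardized units from the hard labels; clusters that
    own no neurons get a zero row (with a warning).
    """
    Z = features.standardized
    global_mean = Z.mean(axis=0)
    out = np.zeros((model.selected_k, Z.shape[1]))
    for k in range(1, model.selected_k + 1):
        members = model.labels == k
        if not members.any():
            warnings.warn(f"cluster {k} is empty; importance set to zero")
            continue
        out[k - 1] = np.abs(Z[members].mean(axis=0) - global_mean)
    return out


def order_clusters(model: ClusterModel, features: FeatureTable) -> ClusterModel:
    """Relabel clusters so mean firing rate ascends with the label.

    Ties in mean rate are broken by ascending burst index.  Returns a
    new model; the input is untouched.
    """
    rate_col = features.feature_names.index("rate")
    burst_col = features.feature_names.index("burst_index")
    keys = []
    for k in range(1, model.selected_k + 1):
        members = model.labels == k
        if members.any():
            sub = features.matrix[members]
            keys.append((sub[:, rate_col].mean(), sub[:, burst_col].mean()))
        else:
            keys.append((np.inf, np.inf))
    order = sorted(range(model.selected_k), key=lambda i: keys[i])
    # order[j] = old index of the cluster that becomes label j+1
    relabel = np.empty(model.selected_k, dtype=int)
    for new_idx, old_idx in enumerate(order):
        relabel[old_idx] = new_idx + 1
    perm = np.asarray(order)
    return ClusterModel(
        neuron_ids=model.neuron_ids,
        feature_names=model.feature_names,
        k_grid=model.k_grid,
        bic_mean=model.bic_mean,
        bic_ci=model.bic_ci,
        selected_k=model.selected_k,
        weights=model.weights[perm],
        means=model.means[perm],
        covariances=model.covariances[perm],
        labels=relabel[model.labels - 1],
        responsibilities=model.responsibilities[:, perm],
        feature_importance=model.feature_importance[perm],
        col_mean=model.col_mean,
        col_sd=model.col_sd,
    )


def embed_tsne(features: FeatureTable, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of the standardized features, for visualisation only."""
    Z = features.standardized
    if Z.shape[0] < 10:
        raise ValueError("need at least 10 neurons for a t-SNE embedding")
    perplexity = min(perplexity, (Z.shape[0] - 1) / 3)
    ts = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    )
    return ts.fit_transform(Z)
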