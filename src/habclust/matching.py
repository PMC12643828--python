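"""Cross-dataset cluster correspondence.

Clusters fitted separately on two datasets (e.g. anesthetized and awake
recordings) are matched by the cosine similarity of their centroids.
The optimal one-to-one assignment minimises the total dissimilarity
``sum(1 - SC)`` (Hungarian algorithm); pairs below a similarity
threshold (default 0.6, inclusive) are dropped from the accepted set.

Centroids must live in a shared feature space: the same sparse-PCA
loadings and the same per-column standardization for both datasets
(see :func:`habclust.embedding.extract_feature_tables`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .embedding import ClusterModel


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two centroid vectors.

    Raises on zero vectors, for which the similarity is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(a @ b / (na * nb))


def similarity_matrix(centroids_a: np.ndarray, centroids_b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities, ``k_a x k_b``."""
    return np.array(
        [[cosine_similarity(a, b) for b in centroids_b] for a in centroids_a]
    )


@dataclass(frozen=True)
class MatchResult:
    """Optimal cluster correspondence between two fitted models."""

    similarity: np.ndarray  # k_a x k_b
    assignment: tuple[tuple[int, int], ...]  # (cluster_a, cluster_b), 1-based
    accepted: tuple[tuple[int, int], ...]  # assignment pairs with SC >= threshold
    threshold: float

    @property
    def assignment_cost(self) -> float:
        """Total dissimilarity of the assignment, ``sum(1 - SC)``."""
        return float(
            sum(1.0 - self.similarity[a - 1, b - 1] for a, b in self.assignment)
        )

    def pair_similarity(self, a: int, b: int) -> float:
        return float(self.similarity[a - 1, b - 1])


def match_clusters(
    model_a: ClusterModel | np.ndarray,
    model_b: ClusterModel | np.ndarray,
    threshold: float = 0.6,
    space: str = "standardized",
) -> MatchResult:
    """Match clusters of two models by optimal centroid assignment.

    Parameters
    ----------
    model_a, model_b : ClusterModel or ndarray
        Fitted models (or raw centroid matrices, one row per cluster).
    threshold : float, default 0.6
        Minimum cosine similarity for an assigned pair to be accepted.
        The comparison is inclusive: a pair at exactly the threshold is
        kept.
    space : {"standardized", "raw"}
        Whether centroids are compared in the standardized feature
        space (default) or after de-standardizing to feature units.

    Unequal cluster counts are allowed; the rectangular assignment
    leaves the extra clusters of the larger model unmatched.
    """
    ca = _centroids(model_a, space)
    cb = _centroids(model_b, space)
    sim = similarity_matrix(ca, cb)
    rows, cols = linear_sum_assignment(1.0 - sim)
    assignment = tuple(
        (int(r) + 1, int(c) + 1) for r, c in sorted(zip(rows, cols))
    )
    accepted = tuple(p for p in assignment if sim[p[0] - 1, p[1] - 1] >= threshold)
    return MatchResult(
        similarity=sim, assignment=assignment, accepted=accepted, threshold=threshold
    )


def _centroids(model: ClusterModel | np.ndarray, space: str) -> np.ndarray:
    if isinstance(model, np.ndarray):
        return model
    if space == "standardized":
        return model.means
    if space == "raw":
        return model.centroids_raw
    raise ValueError(f"unknown centroid space {space!r}")


def brute_force_match(similarity: np.ndarray) -> tuple[tuple[tuple[int, int], ...], float]:
    """Exhaustive minimum-dissimilarity assignment (test oracle).

    Enumerates all permutations (square case) or partial injections
    (rectangular case) of min(k_a, k_b) pairs and returns the 1-based
    assignment with minimal ``sum(1 - SC)``.  Ties break towards the
    lexicographically smallest pair list.  Only practical for k <= 8.
    """
    sim = np.asarray(similarity, dtype=float)
    ka, kb = sim.shape
    if max(ka, kb) > 8:
        raise ValueError("brute force limited to k <= 8")
    best: tuple[tuple[int, int], ...] | None = None
    best_cost = np.inf
    rows = range(ka)
    if ka <= kb:
        for perm in permutations(range(kb), ka):
            cost = sum(1.0 - sim[r, c] for r, c in zip(rows, perm))
            pairs = tuple((r + 1, c + 1) for r, c in zip(rows, perm))
            if cost < best_cost - 1e-12 or (
                abs(cost - best_cost) <= 1e-12 and (best is None or pairs < best)
            ):
                best, best_cost = pairs, min(cost, best_cost)
    else:
        for perm in permutations(range(ka), kb):
            cost = sum(1.0 - sim[r, c] for c, r in enumerate(perm))
            pairs = tuple(sorted((r + 1, c + 1) for c, r in enumerate(perm)))
            if cost < best_cost - 1e-12 or (
                abs(cost - best_cost) <= 1e-12 and (best is None or pairs < best)
            ):
                best, best_cost = pairs, min(cost, best_cost)
    assert best is not None
    return best, float(best_cost)
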