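"""Patient-similarity graphs: exponential-kernel k-nn affinities per omics,
average graph fusion, and the symmetric normalised convolution matrix.

The affinity between patients i and j is ``exp(-rho^2(x_i, x_j) / (mu *
delta^2))`` when j is among the k nearest neighbours of i and 0 otherwise,
where ``rho`` is the Euclidean distance and ``delta^2`` is the median of all
pairwise squared distances (a scale-free bandwidth). Per-omics graphs are
fused by elementwise averaging, and graph convolution uses
``A_hat = D~^{-1/2} (A + I) D~^{-1/2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AffinityGraph",
    "ConvolutionMatrix",
    "pairwise_sq_distances",
    "knn_affinity",
    "fuse_graphs",
    "normalize_adjacency",
]


@dataclass
class AffinityGraph:
    """Nonnegative symmetric n x n patient-affinity matrix with provenance."""

    weights: np.ndarray
    omics_label: str = "fused"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(self.weights < 0):
            raise ValueError("affinity weights must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]


@dataclass
class ConvolutionMatrix:
    """Symmetric normalised adjacency with self-loops, plus its degree vector."""

    a_hat: np.ndarray
    degrees: np.ndarray


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between all sample pairs (zero diagonal)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("input contains NaN; impute before building graphs")
    D = squareform(pdist(X, metric="sqeuclidean"))
    return D


def knn_affinity(
    X: np.ndarray,
    k: int,
    mu: float,
    omics_label: str = "gene",
    symmetrize: str = "average",
) -> AffinityGraph:
    """Exponential-kernel k-nn affinity graph over samples.

    The directed k-nn support (self excluded, distance ties broken by
    ascending sample index) is weighted by ``exp(-d2 / (mu * delta2))`` with
    ``delta2`` the median off-diagonal squared distance, then symmetrised:
    ``"average"`` -> (A + A.T)/2, ``"max"`` -> elementwise max, ``"mutual"``
    -> keep only edges present in both directions.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if mu <= 0:
        raise ValueError("mu must be positive")
    D2 = pairwise_sq_distances(X)
    delta2 = float(np.median(D2[np.triu_indices(n, k=1)]))
    if delta2 == 0.0:
        raise ValueError(
            "median pairwise squared distance is zero (all points identical); "
            "add jitter or remove duplicate samples"
        )
    kernel = np.exp(-D2 / (mu * delta2))
    A = np.zeros((n, n))
    for i in range(n):
        d = D2[i].copy()
        d[i] = np.inf  # self excluded from the neighbourhood
        nbrs = np.argsort(d, kind="stable")[:k]  # stable: index breaks ties
        A[i, nbrs] = kernel[i, nbrs]
    if symmetrize == "average":
        A = 0.5 * (A + A.T)
    elif symmetrize == "max":
        A = np.maximum(A, A.T)
    elif symmetrize == "mutual":
        A = np.where((A > 0) & (A.T > 0), A, 0.0)
    else:
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    np.fill_diagonal(A, 0.0)
    return AffinityGraph(
        A, omics_label, params={"k": k, "mu": mu, "delta_sq": delta2, "symmetrize": symmetrize}
    )


def fuse_graphs(graphs: list[AffinityGraph]) -> AffinityGraph:
    """Elementwise arithmetic mean of the affinity matrices."""
    if not graphs:
        raise ValueError("need at least one graph")
    n = graphs[0].n_samples
    if any(g.n_samples != n for g in graphs):
        raise ValueError("all graphs must have the same number of samples")
    W = np.mean([g.weights for g in graphs], axis=0)
    return AffinityGraph(W, "fused", params={"sources": [g.omics_label for g in graphs]})


def normalize_adjacency(A: AffinityGraph | np.ndarray) -> ConvolutionMatrix:
    """Symmetric normalisation with self-loops: D~^{-1/2} (A + I) D~^{-1/2}.

    All eigenvalues of the result lie in [-1, 1]; the empty graph maps to the
    identity.
    """
    W = A.weights if isinstance(A, AffinityGraph) else np.asarray(A, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric; symmetrize the graph first")
    A_tilde = W + np.eye(W.shape[0])
    d = A_tilde.sum(axis=1)
    assert np.all(d > 0)  # guaranteed by the self-loops
    inv_sqrt = 1.0 / np.sqrt(d)
    a_hat = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return ConvolutionMatrix(a_hat=a_hat, degrees=d)
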