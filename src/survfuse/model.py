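"""Scikit-learn-style estimator wrapping the graph-fusion survival network.

:class:`GraphFusionSurvival` is a Cox-type risk model for paired omics views:
``fit`` takes the two sample-aligned matrices and a right-censored outcome,
trains the dually fused network (feature fusion by highway encoders + FBM,
graph fusion of per-omics k-nn affinity graphs, one graph-convolution layer,
Cox partial-likelihood loss) and exposes risk scores; ``predict`` returns the
linear predictor beta^T z_h (higher = shorter expected survival) and
``score`` the concordance index. The estimator is clonable and usable with
sklearn model selection through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import MultiOmicsSurvivalDataset, SurvivalOutcome
from .graph import fuse_graphs, knn_affinity, normalize_adjacency
from .metrics import concordance_index
from .network import (
    Network,
    TrainConfig,
    breslow_baseline,
    get_variant,
    train_network,
)

__all__ = ["GraphFusionSurvival", "unpack_views", "unpack_outcome"]


def unpack_views(X) -> tuple[np.ndarray, np.ndarray]:
    """Accept (X_gene, X_mirna) pairs or a MultiOmicsSurvivalDataset."""
    if isinstance(X, MultiOmicsSurvivalDataset):
        return X.gene.values, X.mirna.values
    if isinstance(X, (tuple, list)) and len(X) == 2:
        X1 = np.asarray(X[0], dtype=float)
        X2 = np.asarray(X[1], dtype=float)
        if X1.shape[0] != X2.shape[0]:
            raise ValueError("the two omics views must have the same number of samples")
        return X1, X2
    raise TypeError(
        "X must be a (gene, microRNA) pair of arrays or a MultiOmicsSurvivalDataset"
    )


def unpack_outcome(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept SurvivalOutcome, (time, event) pairs, 2-col arrays or sksurv-style
    structured arrays (event field first, time second)."""
    if isinstance(y, SurvivalOutcome):
        return y.time, y.event
    if isinstance(y, np.ndarray) and y.dtype.names:
        ev, tm = y.dtype.names[0], y.dtype.names[1]
        return np.asarray(y[tm], dtype=float), np.asarray(y[ev]).astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1]).astype(int)
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    raise TypeError("y must provide an observed time and an event indicator per sample")


class GraphFusionSurvival(BaseEstimator):
    """Dually fused graph-convolutional Cox model for two omics views.

    Parameters
    ----------
    variant : str
        Wiring: "FULL" (everything), "NO_FBM" (fused graph, additive features
        only), "NO_GRAPH"/"HIGH_FF" (fused features, identity graph),
        "LOW_FF", "FBM_FF" (one feature block, identity graph), or
        "GCN_SINGLE" (one omics' encoder and graph).
    l, m, d : int
        Encoder width, number of cross-omics features, FBM factor rank.
    h1, h2 : int
        Hidden widths of the graph-convolution layer and the dense layer.
    k : int
        Neighbourhood size of the k-nn affinity graphs.
    mu_gene, mu_mirna : float
        Kernel bandwidth multipliers of the per-omics graphs.
    graph_mode : str
        "transductive" (default): samples passed to fit participate in
        message passing even when excluded from the loss by ``train_mask``;
        "test_only_graph": training uses a graph over training samples only.
    learning_rate, max_epochs, tol, patience : training schedule (full-batch
        Adam; stop when the loss improves by less than ``tol`` for
        ``patience`` consecutive epochs).
    random_state : int
        Seeds parameter initialisation; fits are deterministic.

    Attributes
    ----------
    net_ : trained :class:`~survfuse.network.Network`
    risk_scores_ : risk for every sample passed to fit
    loss_curve_ : per-epoch training loss
    baseline_hazard_ : Breslow cumulative baseline hazard on the training part
    """

    def __init__(
        self,
        variant: str = "FULL",
        l: int = 50,
        m: int = 10,
        d: int = 16,
        h1: int = 30,
        h2: int = 15,
        k: int = 5,
        mu_gene: float = 0.3,
        mu_mirna: float = 0.2,
        symmetrize: str = "average",
        graph_mode: str = "transductive",
        two_hop: bool = False,
        single_omics: str = "gene",
        learning_rate: float = 2e-4,
        max_epochs: int = 500,
        tol: float = 1e-6,
        patience: int = 20,
        random_state: int = 0,
    ) -> None:
        self.variant = variant
        self.l = l
        self.m = m
        self.d = d
        self.h1 = h1
        self.h2 = h2
        self.k = k
        self.mu_gene = mu_gene
        self.mu_mirna = mu_mirna
        self.symmetrize = symmetrize
        self.graph_mode = graph_mode
        self.two_hop = two_hop
        self.single_omics = single_omics
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build_a_hat(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray | None:
        v = get_variant(self.variant)
        if v.graph_source == "identity":
            return None
        if v.graph_source == "fused":
            g1 = knn_affinity(X1, self.k, self.mu_gene, "gene", self.symmetrize)
            g2 = knn_affinity(X2, self.k, self.mu_mirna, "microRNA", self.symmetrize)
            fused = fuse_graphs([g1, g2])
            return normalize_adjacency(fused).a_hat
        # single-omics graph
        if self.single_omics == "gene":
            g = knn_affinity(X1, self.k, self.mu_gene, "gene", self.symmetrize)
        else:
            g = knn_affinity(X2, self.k, self.mu_mirna, "microRNA", self.symmetrize)
        return normalize_adjacency(g).a_hat

    def fit(self, X, y=None, train_mask: np.ndarray | None = None) -> "GraphFusionSurvival":
        """Train on the given cohort.

        ``train_mask`` (boolean, optional) restricts the partial-likelihood
        loss to a subset while — in transductive mode — keeping every sample
        in the graph; held-out risks are then available in ``risk_scores_``.
        """
        X1, X2 = unpack_views(X)
        if y is None and isinstance(X, MultiOmicsSurvivalDataset):
            y = X.outcome
        time, event = unpack_outcome(y)
        n = X1.shape[0]
        if len(time) != n:
            raise ValueError("outcome length does not match the number of samples")
        if train_mask is None:
            train_mask = np.ones(n, dtype=bool)
        train_mask = np.asarray(train_mask, dtype=bool)
        train_idx = np.flatnonzero(train_mask)

        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            tol=self.tol,
            patience=self.patience,
            seed=self.random_state,
            graph_mode=self.graph_mode,
            h1=self.h1,
            h2=self.h2,
            two_hop=self.two_hop,
        )
        net = Network(
            self.variant,
            p1=X1.shape[1],
            p2=X2.shape[1],
            l=self.l,
            d=self.d,
            m=self.m,
            h1=self.h1,
            h2=self.h2,
            seed=self.random_state,
            single_omics=self.single_omics,
            two_hop=self.two_hop,
        )
        if self.graph_mode == "test_only_graph" and not train_mask.all():
            # strict mode: held-out samples never enter the training graph
            a_tr = self._build_a_hat(X1[train_idx], X2[train_idx])
            _, losses = train_network(
                net,
                X1[train_idx],
                X2[train_idx],
                a_tr,
                time[train_idx],
                event[train_idx],
                np.arange(train_idx.size),
                cfg,
            )
            a_all = self._build_a_hat(X1, X2)
            risk, _ = net.forward(X1, X2, a_all)
        else:
            a_all = self._build_a_hat(X1, X2)
            risk, losses = train_network(
                net, X1, X2, a_all, time, event, train_idx, cfg
            )
        self.net_ = net
        self.params_ = net.params
        self.risk_scores_ = risk
        self.loss_curve_ = losses
        self.train_mask_ = train_mask
        self.baseline_hazard_ = breslow_baseline(
            risk[train_idx], time[train_idx], event[train_idx]
        )
        self.X1_, self.X2_ = X1, X2
        self.n_features_in_ = X1.shape[1] + X2.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Risk scores; for new samples the graph is rebuilt over fit+new."""
        if not hasattr(self, "net_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        if X is None:
            return self.risk_scores_
        X1, X2 = unpack_views(X)
        n_fit = self.X1_.shape[0]
        X1c = np.vstack([self.X1_, X1])
        X2c = np.vstack([self.X2_, X2])
        a_hat = self._build_a_hat(X1c, X2c)
        risk, _ = self.net_.forward(X1c, X2c, a_hat)
        return risk[n_fit:]

    def predict_cumulative_hazard(self, X=None, times: np.ndarray | None = None):
        """H(t | x) = H0(t) * exp(risk) on a grid of times."""
        risk = self.predict(X)
        if times is None:
            times = self.baseline_hazard_.event_times
        H0 = self.baseline_hazard_.cumulative_at(times)
        return np.outer(np.exp(risk), H0), np.asarray(times)

    def predict_survival_function(self, X=None, times: np.ndarray | None = None):
        """S(t | x) = exp(-H0(t) exp(risk))."""
        H, times = self.predict_cumulative_hazard(X, times)
        return np.exp(-H), times

    def score(self, X, y) -> float:
        """Concordance index of the predicted risks on (X, y)."""
        time, event = unpack_outcome(
            y if y is not None or not isinstance(X, MultiOmicsSurvivalDataset) else X.outcome
        )
        return concordance_index(self.predict(X), (time, event))
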