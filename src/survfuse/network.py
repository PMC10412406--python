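"""Graph-convolutional Cox network: forward/backward passes, the negative
partial-likelihood loss, Breslow baseline estimation, ablation variants and
full-batch Adam training.

The full model chains: highway encoders per omics -> FBM cross-omics features
-> fused features Z = (Z1+Z2) (+) Z_cross -> one graph-convolution layer
``tanh(A_hat Z W1)`` -> dense layer ``sigmoid(. W2)`` -> linear Cox head
``risk = Z_h beta``. The convolution matrix multiplies only the first layer
(the second is dense); a ``two_hop`` flag enables the conventional variant
with graph mixing in both layers.

The loss is the negative Cox partial log-likelihood
``sum_{i: event} [log sum_{j in R(i)} exp(risk_j) - risk_i]`` with risk set
``R(i) = {j : O_j >= O_i}`` (Breslow handling of ties), stabilised by
max-subtraction. Training is deterministic full-batch Adam from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fusion import (
    fbm_backward,
    fbm_forward,
    fuse_features,
    highway_backward,
    highway_forward,
    init_fbm_params,
    init_highway_params,
)

__all__ = [
    "cox_neg_log_partial_likelihood",
    "cox_loss_and_risk_gradient",
    "risk_score",
    "BaselineHazard",
    "breslow_baseline",
    "ModelVariant",
    "VARIANTS",
    "TrainConfig",
    "Network",
    "AdamOptimizer",
    "train_network",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _sorted_risk_sets(risk: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and return per-sample risk-set log-sums.

    Returns (order, r, t, e, denom, m) where denom[i] = sum_{j: t_j >= t_i}
    exp(r_j - m) evaluated at the start of i's tie group.
    """
    order = np.argsort(time, kind="stable")
    r, t, e = risk[order], time[order], event[order]
    m = float(r.max())
    exp_r = np.exp(r - m)
    suffix = np.cumsum(exp_r[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")  # start of each tie group
    denom = suffix[first]
    return order, r, t, e, exp_r, denom, m


def cox_neg_log_partial_likelihood(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Negative Cox partial log-likelihood of a risk vector.

    Uses the risk set R(i) = {j : O_j >= O_i} (patient i included; ties enter
    every tied patient's denominator) and a max-subtracted log-sum-exp.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    if event.sum() == 0:
        raise ValueError("partial likelihood requires at least one observed event")
    _, r, _, e, _, denom, m = _sorted_risk_sets(risk, time, event)
    return float(np.sum(e * (np.log(denom) + m - r)))


def cox_loss_and_risk_gradient(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient w.r.t. the risk vector.

    d/d r_k = sum_{events i with k in R(i)} exp(r_k)/sum_{j in R(i)} exp(r_j)
    - event_k.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order, r, t, e, exp_r, denom, m = _sorted_risk_sets(risk, time, event)
    loss = float(np.sum(e * (np.log(denom) + m - r)))
    # event i contributes softmax weight to every k with t_k >= t_i, i.e. all
    # positions at or after i's tie-group start; accumulate via prefix sums
    g = e / denom
    prefix = np.cumsum(g)
    last = np.searchsorted(t, t, side="right") - 1  # end of each tie group
    grad_sorted = exp_r * prefix[last] - e
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad


def risk_score(z_h: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Linear Cox scores beta^T z_h (no intercept)."""
    z_h = np.asarray(z_h, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if z_h.shape[1] != beta.shape[0]:
        raise ValueError(f"feature width {z_h.shape[1]} != beta length {beta.shape[0]}")
    return z_h @ beta


@dataclass
class BaselineHazard:
    """Breslow step estimate of the cumulative baseline hazard."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def cumulative_at(self, t: np.ndarray | float) -> np.ndarray:
        """H0(t): zero before the first event time, step-constant after."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(t), side="right")
        H = np.concatenate([[0.0], self.cumulative_hazard])
        return H[idx]


def breslow_baseline(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray
) -> BaselineHazard:
    """Breslow estimator H0(t) = sum_{t_k <= t} d_k / sum_{j: O_j >= t_k} exp(r_j)."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if event.sum() == 0:
        raise ValueError("Breslow estimator requires at least one observed event")
    order = np.argsort(time, kind="stable")
    r, t, e = risk[order], time[order], event[order]
    exp_r = np.exp(r - r.max())
    suffix = np.cumsum(exp_r[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    scale = math.exp(r.max())
    times, jumps = [], []
    for tk in np.unique(t[e == 1]):
        lo = np.searchsorted(t, tk, side="left")
        hi = np.searchsorted(t, tk, side="right")
        d_k = int(e[lo:hi].sum())
        times.append(tk)
        jumps.append(d_k / (suffix[first[lo]] * scale))
    return BaselineHazard(
        event_times=np.asarray(times), cumulative_hazard=np.cumsum(jumps)
    )


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    """Wiring of one ablation configuration.

    feature_source: "concat" (Z_low (+) Z_cross), "low", "cross", or "single"
    (one omics' highway encoding). graph_source: "fused", "gene", "mirna", or
    "identity" (no neighbour mixing). All configurations share the same
    two-layer head so that wiring, not capacity, is what differs.
    """

    name: str
    use_graph: bool
    use_fbm: bool
    feature_source: str
    graph_source: str


VARIANTS: dict[str, ModelVariant] = {
    "FULL": ModelVariant("FULL", True, True, "concat", "fused"),
    "GCN_SINGLE": ModelVariant("GCN_SINGLE", True, False, "single", "single"),
    "LOW_FF": ModelVariant("LOW_FF", False, False, "low", "identity"),
    "FBM_FF": ModelVariant("FBM_FF", False, True, "cross", "identity"),
    "HIGH_FF": ModelVariant("HIGH_FF", False, True, "concat", "identity"),
    "NO_GRAPH": ModelVariant("NO_GRAPH", False, True, "concat", "identity"),
    "NO_FBM": ModelVariant("NO_FBM", True, False, "low", "fused"),
}


def get_variant(variant: str | ModelVariant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant.upper()]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}"
        ) from None


@dataclass
class TrainConfig:
    """Training hyperparameters (full-batch Adam)."""

    learning_rate: float = 2e-4
    max_epochs: int = 500
    tol: float = 1e-6
    patience: int = 20
    seed: int = 0
    graph_mode: str = "transductive"  # or "test_only_graph"
    h1: int = 30
    h2: int = 15
    two_hop: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.graph_mode not in ("transductive", "test_only_graph"):
            raise ValueError(f"unknown graph_mode {self.graph_mode!r}")


# ---------------------------------------------------------------------------
# Assembled network
# ---------------------------------------------------------------------------

class Network:
    """Parameter container + forward/backward for one variant's wiring."""

    def __init__(
        self,
        variant: str | ModelVariant,
        p1: int,
        p2: int,
        l: int = 50,
        d: int = 16,
        m: int = 10,
        h1: int = 30,
        h2: int = 15,
        seed: int = 0,
        single_omics: str = "gene",
        two_hop: bool = False,
    ) -> None:
        self.variant = get_variant(variant)
        self.l, self.d, self.m, self.h1, self.h2 = l, d, m, h1, h2
        self.single_omics = single_omics
        self.two_hop = two_hop
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        src = self.variant.feature_source
        need_enc1 = src in ("concat", "low", "cross") or (
            src == "single" and single_omics == "gene"
        )
        need_enc2 = src in ("concat", "low", "cross") or (
            src == "single" and single_omics == "mirna"
        )
        if need_enc1:
            for k, v in init_highway_params(p1, l, rng).items():
                self.params[f"enc1.{k}"] = v
        if need_enc2:
            for k, v in init_highway_params(p2, l, rng).items():
                self.params[f"enc2.{k}"] = v
        if self.variant.use_fbm:
            for k, v in init_fbm_params(l, d, m, rng).items():
                self.params[f"fbm.{k}"] = v
        width = {"concat": l + m, "low": l, "cross": m, "single": l}[src]
        self.feature_width = width
        self.params["W1"] = _glorot(rng, width, h1)
        self.params["W2"] = _glorot(rng, h1, h2)
        self.params["beta"] = _glorot(rng, h2, 1)[:, 0]

    def forward(
        self, X1: np.ndarray, X2: np.ndarray, a_hat: np.ndarray | None
    ) -> tuple[np.ndarray, dict]:
        """Risk scores for all samples, with the caches backward needs."""
        p = self.params
        src = self.variant.feature_source
        cache: dict = {}
        z1 = z2 = None
        if any(k.startswith("enc1.") for k in p):
            z1, cache["enc1"] = highway_forward(
                X1, {k[5:]: v for k, v in p.items() if k.startswith("enc1.")}
            )
        if any(k.startswith("enc2.") for k in p):
            z2, cache["enc2"] = highway_forward(
                X2, {k[5:]: v for k, v in p.items() if k.startswith("enc2.")}
            )
        if self.variant.use_fbm:
            z_cross, cache["fbm"] = fbm_forward(z1, z2, p["fbm.U"], p["fbm.V"])
        else:
            z_cross = None
        if src == "concat":
            Z = fuse_features(z1, z2, z_cross).z
        elif src == "low":
            Z = z1 + z2
        elif src == "cross":
            Z = z_cross
        else:  # single
            Z = z1 if z1 is not None else z2
        cache["Z"] = Z
        AZ = Z if a_hat is None else a_hat @ Z
        cache["AZ"] = AZ
        S1 = AZ @ p["W1"]
        H1 = np.tanh(S1)
        cache["H1"] = H1
        AH1 = H1 if (a_hat is None or not self.two_hop) else a_hat @ H1
        cache["AH1"] = AH1
        S2 = AH1 @ p["W2"]
        Zh = 1.0 / (1.0 + np.exp(-S2))
        cache["Zh"] = Zh
        cache["a_hat"] = a_hat
        risk = Zh @ p["beta"]
        return risk, cache

    def backward(self, d_risk: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Analytic gradient of the loss w.r.t. every parameter."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        Zh, AH1, H1, AZ, Z, a_hat = (
            cache["Zh"],
            cache["AH1"],
            cache["H1"],
            cache["AZ"],
            cache["Z"],
            cache["a_hat"],
        )
        grads["beta"] = Zh.T @ d_risk
        dZh = d_risk[:, None] * p["beta"][None, :]
        dS2 = dZh * Zh * (1.0 - Zh)
        grads["W2"] = AH1.T @ dS2
        dAH1 = dS2 @ p["W2"].T
        dH1 = dAH1 if (a_hat is None or not self.two_hop) else a_hat @ dAH1
        dS1 = dH1 * (1.0 - H1 * H1)
        grads["W1"] = AZ.T @ dS1
        dAZ = dS1 @ p["W1"].T
        dZ = dAZ if a_hat is None else a_hat @ dAZ  # a_hat is symmetric
        src = self.variant.feature_source
        l = self.l
        dz1 = dz2 = None
        if src == "concat":
            d_low, d_cross = dZ[:, :l], dZ[:, l:]
            dz1f, dz2f, dU, dV = fbm_backward(d_cross, p["fbm.U"], p["fbm.V"], cache["fbm"])
            grads["fbm.U"], grads["fbm.V"] = dU, dV
            dz1, dz2 = d_low + dz1f, d_low + dz2f
        elif src == "low":
            dz1, dz2 = dZ, dZ
        elif src == "cross":
            dz1, dz2, dU, dV = fbm_backward(dZ, p["fbm.U"], p["fbm.V"], cache["fbm"])
            grads["fbm.U"], grads["fbm.V"] = dU, dV
        else:  # single
            if "enc1" in cache:
                dz1 = dZ
            else:
                dz2 = dZ
        if "enc1" in cache and dz1 is not None:
            enc1_params = {k[5:]: v for k, v in p.items() if k.startswith("enc1.")}
            for k, v in highway_backward(dz1, enc1_params, cache["enc1"]).items():
                grads[f"enc1.{k}"] = v
        if "enc2" in cache and dz2 is not None:
            enc2_params = {k[5:]: v for k, v in p.items() if k.startswith("enc2.")}
            for k, v in highway_backward(dz2, enc2_params, cache["enc2"]).items():
                grads[f"enc2.{k}"] = v
        return grads


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class AdamOptimizer:
    """Standard Adam with bias correction; operates on a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_network(
    net: Network,
    X1: np.ndarray,
    X2: np.ndarray,
    a_hat: np.ndarray | None,
    time: np.ndarray,
    event: np.ndarray,
    train_idx: np.ndarray,
    cfg: TrainConfig,
) -> tuple[np.ndarray, list[float]]:
    """Full-batch Adam on the partial-likelihood loss of the training samples.

    The forward pass runs over every sample handed in (transductive: held-out
    patients participate in graph message passing) but the loss and its
    gradient touch only ``train_idx``. Returns the final risk scores for all
    samples and the per-epoch loss curve.
    """
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0 or event[train_idx].sum() == 0:
        raise ValueError("training set must be nonempty and contain >= 1 event")
    t_tr, e_tr = time[train_idx], event[train_idx]
    opt = AdamOptimizer(net.params, cfg.learning_rate)
    losses: list[float] = []
    best = np.inf
    stall = 0
    risk = None
    for epoch in range(cfg.max_epochs):
        risk, cache = net.forward(X1, X2, a_hat)
        loss, g_tr = cox_loss_and_risk_gradient(risk[train_idx], t_tr, e_tr)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged: non-finite loss at epoch {epoch}")
        losses.append(loss)
        d_risk = np.zeros_like(risk)
        d_risk[train_idx] = g_tr
        grads = net.backward(d_risk, cache)
        opt.step(net.params, grads)
        if best - loss > cfg.tol:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    risk, _ = net.forward(X1, X2, a_hat)
    return risk, losses
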