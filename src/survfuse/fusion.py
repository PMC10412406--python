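"""Per-omics highway encoders, the factorized bilinear model (FBM) for
cross-omics features, and the fused feature block.

A highway encoder projects the raw omics profile to width ``l`` and applies
three gated blocks ``x_out = H(x) * T(x) + x * (1 - T(x))`` where H is an
affine+ReLU transform and T a sigmoid gate; the gate bias starts at -1 so the
encoder begins close to the identity carry.

The FBM builds ``m`` cross-omics scalars per patient, the j-th being the
rank-``d`` bilinear form ``z1^T U_j V_j^T z2`` evaluated as an inner product
of the two d-dimensional projections (the l x l matrix U_j V_j^T is never
materialised). Fused features concatenate the additive fusion
``Z_low = Z1 + Z2`` with the cross-omics block.

Forward passes return the caches needed by the matching ``*_backward``
functions, which implement the analytic gradients used by training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "init_highway_params",
    "highway_forward",
    "highway_backward",
    "init_fbm_params",
    "fbm_forward",
    "fbm_backward",
    "FusedFeatures",
    "fuse_features",
]

N_HIGHWAY_LAYERS = 3


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_highway_params(
    p: int, l: int, rng: np.random.Generator, n_layers: int = N_HIGHWAY_LAYERS
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights; gate biases start at -1 (carry-biased)."""
    params = {"Wp": _glorot(rng, p, l), "bp": np.zeros(l)}
    for layer in range(n_layers):
        params[f"Wh{layer}"] = _glorot(rng, l, l)
        params[f"bh{layer}"] = np.zeros(l)
        params[f"Wt{layer}"] = _glorot(rng, l, l)
        params[f"bt{layer}"] = np.full(l, -1.0)
    return params


def highway_forward(
    X: np.ndarray, params: dict[str, np.ndarray], n_layers: int = N_HIGHWAY_LAYERS
) -> tuple[np.ndarray, dict]:
    """Linear projection p -> l followed by the gated highway blocks."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params["Wp"].shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match projection input "
            f"{params['Wp'].shape[0]}"
        )
    x = X @ params["Wp"] + params["bp"]
    cache: dict = {"X": X, "inputs": [], "H": [], "T": [], "ah": [], "n_layers": n_layers}
    for layer in range(n_layers):
        ah = x @ params[f"Wh{layer}"] + params[f"bh{layer}"]
        H = np.maximum(ah, 0.0)  # ReLU transform
        T = _sigmoid(x @ params[f"Wt{layer}"] + params[f"bt{layer}"])
        cache["inputs"].append(x)
        cache["ah"].append(ah)
        cache["H"].append(H)
        cache["T"].append(T)
        x = H * T + x * (1.0 - T)
    return x, cache


def highway_backward(
    d_out: np.ndarray, params: dict[str, np.ndarray], cache: dict
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all encoder parameters."""
    grads = {}
    dx = d_out
    for layer in reversed(range(cache["n_layers"])):
        x, ah, H, T = (
            cache["inputs"][layer],
            cache["ah"][layer],
            cache["H"][layer],
            cache["T"][layer],
        )
        dH = dx * T
        dT = dx * (H - x)
        dx_in = dx * (1.0 - T)
        dah = dH * (ah > 0)
        dat = dT * T * (1.0 - T)
        grads[f"Wh{layer}"] = x.T @ dah
        grads[f"bh{layer}"] = dah.sum(axis=0)
        grads[f"Wt{layer}"] = x.T @ dat
        grads[f"bt{layer}"] = dat.sum(axis=0)
        dx = dx_in + dah @ params[f"Wh{layer}"].T + dat @ params[f"Wt{layer}"].T
    grads["Wp"] = cache["X"].T @ dx
    grads["bp"] = dx.sum(axis=0)
    return grads


def init_fbm_params(l: int, d: int, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """U, V ~ Glorot over the (l, d) slices, stacked along the last axis."""
    U = np.stack([_glorot(rng, l, d) for _ in range(m)], axis=2)
    V = np.stack([_glorot(rng, l, d) for _ in range(m)], axis=2)
    return {"U": U, "V": V}


def fbm_forward(
    z1: np.ndarray, z2: np.ndarray, U: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Cross-omics features: out[:, j] = z1^T U_j V_j^T z2 via rank-d projections."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"z1 shape {z1.shape} != z2 shape {z2.shape}")
    if U.shape != V.shape or z1.shape[1] != U.shape[0]:
        raise ValueError("FBM tensor shapes do not match the encoder width")
    P = np.einsum("nl,ldm->ndm", z1, U)
    Q = np.einsum("nl,ldm->ndm", z2, V)
    out = np.einsum("ndm,ndm->nm", P, Q)
    return out, {"z1": z1, "z2": z2, "P": P, "Q": Q}


def fbm_backward(
    d_out: np.ndarray, U: np.ndarray, V: np.ndarray, cache: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dz1, dz2, dU, dV) of a scalar loss given d(out)."""
    z1, z2, P, Q = cache["z1"], cache["z2"], cache["P"], cache["Q"]
    dP = d_out[:, None, :] * Q
    dQ = d_out[:, None, :] * P
    dU = np.einsum("nl,ndm->ldm", z1, dP)
    dV = np.einsum("nl,ndm->ldm", z2, dQ)
    dz1 = np.einsum("ndm,ldm->nl", dP, U)
    dz2 = np.einsum("ndm,ldm->nl", dQ, V)
    return dz1, dz2, dU, dV


@dataclass
class FusedFeatures:
    """Single-omics encodings, their sum, the cross-omics block, and the concat."""

    z1: np.ndarray
    z2: np.ndarray
    z_low: np.ndarray
    z_cross: np.ndarray
    z: np.ndarray


def fuse_features(z1: np.ndarray, z2: np.ndarray, z_cross: np.ndarray) -> FusedFeatures:
    """Z = (Z1 + Z2) concatenated with the cross-omics features."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    z_cross = np.asarray(z_cross, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z1 and z2 must share a shape")
    if z_cross.shape[0] != z1.shape[0]:
        raise ValueError("z_cross rows must align with z1/z2")
    z_low = z1 + z2
    z = np.concatenate([z_low, z_cross], axis=1)
    return FusedFeatures(z1=z1, z2=z2, z_low=z_low, z_cross=z_cross, z=z)
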