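"""Expression preprocessing: missingness filter, weighted-kNN imputation,
log transform, variance-based feature selection, standardisation and optional
quantile discretisation.

The pipeline order is fixed: align samples -> drop features with too many
missing values -> impute the remaining gaps -> log(x + pseudocount) ->
keep the top-k most variable features -> z-score each feature
(-> optionally discretise). :func:`preprocess` applies the whole chain to both
omics views and returns a model-ready :class:`MultiOmicsSurvivalDataset`.
"""

from __future__ import annotations

import numpy as np

from .data import (
    MultiOmicsSurvivalDataset,
    OmicsMatrix,
    PreprocessConfig,
    SurvivalOutcome,
)

__all__ = [
    "filter_missing_features",
    "impute_weighted_knn",
    "log_transform",
    "select_top_variance_features",
    "standardize",
    "discretize",
    "align_samples",
    "preprocess",
]


def filter_missing_features(X: OmicsMatrix, max_missing_frac: float = 0.10) -> OmicsMatrix:
    """Keep exactly the features whose missing fraction is <= the threshold."""
    frac = np.isnan(X.values).mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing_frac)
    if keep.size == 0:
        raise ValueError(
            f"all {X.n_features} features exceed missing fraction {max_missing_frac}"
        )
    return X.select_features(keep)


def impute_weighted_knn(X: OmicsMatrix, impute_neighbors: int = 10) -> OmicsMatrix:
    """Fill missing entries with an inverse-distance-weighted kNN mean.

    For a missing cell (i, f) the donors are the samples with feature f
    observed; the distance between sample i and a donor j is the plain
    Euclidean distance over the features observed in both rows, donors are
    ranked by that distance (ties broken by sample order) and the
    ``impute_neighbors`` nearest contribute with weight 1/distance. Donors at
    distance zero short-circuit to their plain mean. Returns the input
    unchanged when nothing is missing.
    """
    V = X.values
    if not np.isnan(V).any():
        return X
    V = V.copy()
    observed = ~np.isnan(X.values)
    all_missing = np.flatnonzero(~observed.any(axis=0))
    if all_missing.size:
        raise ValueError(
            f"feature {X.feature_ids[all_missing[0]]!r} is missing in every sample"
        )
    n = X.n_samples
    for i in range(n):
        miss_feats = np.flatnonzero(~observed[i])
        if miss_feats.size == 0:
            continue
        # distances from sample i to every other sample over shared features
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = observed[i] & observed[j]
            if not shared.any():
                continue
            diff = X.values[i, shared] - X.values[j, shared]
            dists[j] = float(np.sqrt(np.sum(diff * diff)))
        for f in miss_feats:
            donors = np.flatnonzero(observed[:, f] & np.isfinite(dists))
            if donors.size == 0:
                raise ValueError(
                    f"no usable donor for sample {X.sample_ids[i]!r}, feature "
                    f"{X.feature_ids[f]!r}"
                )
            order = donors[np.argsort(dists[donors], kind="stable")]
            nearest = order[: min(impute_neighbors, order.size)]
            d = dists[nearest]
            if np.any(d == 0.0):
                V[i, f] = float(X.values[nearest[d == 0.0], f].mean())
            else:
                w = 1.0 / d
                V[i, f] = float(np.sum(w * X.values[nearest, f]) / np.sum(w))
    return OmicsMatrix(V, list(X.sample_ids), list(X.feature_ids), X.omics_label)


def log_transform(X: OmicsMatrix, pseudocount: float = 1.0, base: str = "e") -> OmicsMatrix:
    """Elementwise log(value + pseudocount); natural log by default."""
    shifted = X.values + pseudocount
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"value + pseudocount <= 0 at sample {X.sample_ids[i]!r}, feature "
            f"{X.feature_ids[j]!r}"
        )
    out = np.log(shifted)
    if base == "2":
        out = out / np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return OmicsMatrix(out, list(X.sample_ids), list(X.feature_ids), X.omics_label)


def select_top_variance_features(X: OmicsMatrix, top_k: int) -> OmicsMatrix:
    """Retain the top_k features by sample variance, original order preserved.

    Features whose values remain almost unchanged across samples carry little
    prognostic information; ranking by variance (ties broken by original
    column order) removes them.
    """
    if top_k > X.n_features:
        raise ValueError(f"top_k={top_k} exceeds feature count {X.n_features}")
    var = X.values.var(axis=0)
    # stable sort on -var keeps original order among exact ties
    ranked = np.argsort(-var, kind="stable")[:top_k]
    keep = np.sort(ranked)
    return X.select_features(keep)


def standardize(X: OmicsMatrix) -> OmicsMatrix:
    """Scale every feature to zero mean and unit (population) variance."""
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0)  # ddof=0: population convention
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(
            f"constant feature {X.feature_ids[zero[0]]!r} cannot be standardized; "
            "remove it upstream (variance filter)"
        )
    return OmicsMatrix(
        (X.values - mean) / sd, list(X.sample_ids), list(X.feature_ids), X.omics_label
    )


def discretize(X: OmicsMatrix, n_bins: int = 4) -> OmicsMatrix:
    """Map each feature to per-feature quantile bins, re-centred to zero mean.

    Optional coarse-graining stage: values are replaced by their bin index
    0..n_bins-1 (equal-probability bins) minus the feature's mean bin index, so
    the output stays zero-mean and usable by the continuous downstream model.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    out = np.empty_like(X.values)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.n_features):
        col = X.values[:, j]
        edges = np.quantile(col, qs)
        cats = np.searchsorted(edges, col, side="left").astype(float)
        out[:, j] = cats - cats.mean()
    return OmicsMatrix(out, list(X.sample_ids), list(X.feature_ids), X.omics_label)


def align_samples(
    gene: OmicsMatrix, mirna: OmicsMatrix, outcome: SurvivalOutcome
) -> tuple[OmicsMatrix, OmicsMatrix, SurvivalOutcome]:
    """Restrict all three tables to their common samples, in survival-table order."""
    common = set(gene.sample_ids) & set(mirna.sample_ids) & set(outcome.sample_ids)
    if not common:
        raise ValueError("no samples shared by the omics matrices and the survival table")
    keep = [i for i, s in enumerate(outcome.sample_ids) if s in common]
    out = outcome.select(keep)
    gpos = {s: i for i, s in enumerate(gene.sample_ids)}
    mpos = {s: i for i, s in enumerate(mirna.sample_ids)}
    gene = gene.select_samples([gpos[s] for s in out.sample_ids])
    mirna = mirna.select_samples([mpos[s] for s in out.sample_ids])
    return gene, mirna, out


def _preprocess_one(X: OmicsMatrix, top_k: int, cfg: PreprocessConfig) -> OmicsMatrix:
    X = filter_missing_features(X, cfg.max_missing_frac)
    X = impute_weighted_knn(X, cfg.impute_neighbors)
    X = log_transform(X, cfg.pseudocount, cfg.log_base)
    X = select_top_variance_features(X, min(top_k, X.n_features))
    X = standardize(X)
    if cfg.discretize:
        X = discretize(X, cfg.n_bins)
    return X


def preprocess(
    gene_raw: OmicsMatrix,
    mirna_raw: OmicsMatrix,
    outcome: SurvivalOutcome,
    cfg: PreprocessConfig | None = None,
) -> MultiOmicsSurvivalDataset:
    """Run the full preprocessing chain on both omics views.

    Deterministic given input and config; on a complete (no-missing) matrix the
    filter and imputation stages are identities.
    """
    cfg = cfg or PreprocessConfig()
    gene, mirna, out = align_samples(gene_raw, mirna_raw, outcome)
    gene = _preprocess_one(gene, cfg.top_k_gene, cfg)
    mirna = _preprocess_one(mirna, cfg.top_k_mirna, cfg)
    return MultiOmicsSurvivalDataset(gene, mirna, out)
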