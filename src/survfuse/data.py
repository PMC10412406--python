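"""Core domain containers for multi-omics right-censored survival cohorts.

All containers are plain dataclasses around NumPy arrays: an
:class:`OmicsMatrix` is a samples x features expression matrix with aligned
identifier lists (missing entries are NaN), a :class:`SurvivalOutcome` holds
the observed follow-up time ``O_i = min(T_i, C_i)`` and the event indicator
``Delta_i`` (1 = event observed, 0 = right-censored), and a
:class:`MultiOmicsSurvivalDataset` bundles the two omics views and the outcome
on an identical sample ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OmicsMatrix",
    "SurvivalOutcome",
    "MultiOmicsSurvivalDataset",
    "PreprocessConfig",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """Expression matrix for one omics view.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Expression values; missing entries are ``np.nan``.
    sample_ids, feature_ids : list of str
        Ordered unique identifiers for rows and columns.
    omics_label : str
        Typically ``"gene"`` or ``"microRNA"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_label: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"row count {self.values.shape[0]} != number of sample ids "
                f"{len(self.sample_ids)}"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"column count {self.values.shape[1]} != number of feature ids "
                f"{len(self.feature_ids)}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def select_samples(self, index: np.ndarray | list[int]) -> "OmicsMatrix":
        index = np.asarray(index)
        return OmicsMatrix(
            self.values[index],
            [self.sample_ids[i] for i in index],
            list(self.feature_ids),
            self.omics_label,
        )

    def select_features(self, index: np.ndarray | list[int]) -> "OmicsMatrix":
        index = np.asarray(index)
        return OmicsMatrix(
            self.values[:, index],
            list(self.sample_ids),
            [self.feature_ids[i] for i in index],
            self.omics_label,
        )


@dataclass
class SurvivalOutcome:
    """Right-censored outcome: observed time and event indicator per sample."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or self.event.ndim != 1:
            raise ValueError("time and event must be 1-D")
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("observed_time must be finite and nonnegative")
        if not np.all(np.isin(self.event, (0, 1))):
            bad = self.event[~np.isin(self.event, (0, 1))][0]
            raise ValueError(f"event indicator must be 0 or 1, got {bad!r}")
        self.event = self.event.astype(int)
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(len(self.time))]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != len(self.time):
            raise ValueError("sample_ids length mismatch")
        _check_unique(self.sample_ids, "sample")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_proportion(self) -> float:
        return float(1.0 - self.event.mean())

    def select(self, index: np.ndarray | list[int]) -> "SurvivalOutcome":
        index = np.asarray(index)
        return SurvivalOutcome(
            self.time[index], self.event[index], [self.sample_ids[i] for i in index]
        )


@dataclass
class MultiOmicsSurvivalDataset:
    """Sample-aligned gene-expression view, microRNA view and outcome."""

    gene: OmicsMatrix
    mirna: OmicsMatrix
    outcome: SurvivalOutcome

    def __post_init__(self) -> None:
        if self.gene.sample_ids != self.mirna.sample_ids:
            raise ValueError("gene and microRNA views have different sample order")
        if self.gene.sample_ids != self.outcome.sample_ids:
            raise ValueError("omics views and survival outcome have different sample order")

    @property
    def n_samples(self) -> int:
        return self.gene.n_samples

    def select(self, index: np.ndarray | list[int]) -> "MultiOmicsSurvivalDataset":
        return MultiOmicsSurvivalDataset(
            self.gene.select_samples(index),
            self.mirna.select_samples(index),
            self.outcome.select(index),
        )


@dataclass
class PreprocessConfig:
    """Knobs of the expression preprocessing pipeline.

    Defaults follow the standard multi-omics survival setup: drop features with
    more than 10% missing values, impute the rest with 10 weighted nearest
    neighbours, log(x + 1) transform, keep the 6000 / 600 most variable gene /
    microRNA features, and z-score each feature. Quantile discretisation is
    available but off by default (downstream fusion operates on continuous
    features).
    """

    max_missing_frac: float = 0.10
    impute_neighbors: int = 10
    pseudocount: float = 1.0
    log_base: str = "e"  # "e" or "2"
    top_k_gene: int = 6000
    top_k_mirna: int = 600
    discretize: bool = False
    n_bins: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.top_k_gene < 1 or self.top_k_mirna < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")
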