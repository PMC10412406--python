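"""Evaluation protocol: repeated 80/20 holdout, neighbourhood-size selection
by inner cross-validation, the k-robustness sweep and the ablation harness.

Each repeat draws a random 80/20 train/test partition from its own seed,
trains the requested model variant transductively (test patients join the
graph, never the loss), and records the test-set concordance index and
cumulative AUC; the report carries per-repeat values plus mean and standard
deviation, fully reproducible from the seed list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import MultiOmicsSurvivalDataset
from .metrics import concordance_index, cumulative_auc
from .model import GraphFusionSurvival

__all__ = [
    "SplitScheme",
    "EvaluationReport",
    "make_split",
    "repeated_holdout",
    "select_k_cv",
    "k_sensitivity_sweep",
    "ablation_study",
]


@dataclass
class SplitScheme:
    """Repeated-holdout protocol: train fraction, repeat count, split seeds."""

    train_frac: float = 0.8
    n_repeats: int = 20
    seeds: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.seeds is None:
            self.seeds = list(range(self.n_repeats))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need exactly one seed per repeat")


@dataclass
class EvaluationReport:
    """Per-repeat test metrics and their aggregates."""

    c_indices: list[float] = field(default_factory=list)
    aucs: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def c_index_mean(self) -> float:
        return float(np.mean(self.c_indices))

    @property
    def c_index_sd(self) -> float:
        return float(np.std(self.c_indices))

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seed": self.seeds, "c_index": self.c_indices, "auc": self.aucs}
        )

    def summary(self) -> str:
        return (
            f"C-index {self.c_index_mean:.3f} +/- {self.c_index_sd:.3f}, "
            f"AUC {self.auc_mean:.3f} +/- {self.auc_sd:.3f} "
            f"({len(self.c_indices)} repeats)"
        )


def make_split(
    n: int, train_frac: float, seed: int, event: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test partition; resamples (with a warning) when the
    test part has no observed event, so both metrics stay defined."""
    for attempt in range(100):
        rng = np.random.default_rng(seed + 100_000 * attempt)
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if event is None or (event[train_idx].sum() > 0 and event[test_idx].sum() > 0):
            if attempt > 0:
                warnings.warn(
                    f"resampled split for seed {seed}: a part had no observed event",
                    stacklevel=2,
                )
            return train_idx, test_idx
    raise ValueError("could not draw a split with events in both parts")


def _fit_and_score(
    dataset: MultiOmicsSurvivalDataset,
    variant: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    model_params: dict,
) -> tuple[float, float]:
    n = dataset.n_samples
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    model = GraphFusionSurvival(variant=variant, random_state=seed, **model_params)
    model.fit(dataset, dataset.outcome, train_mask=mask)
    risk_test = model.risk_scores_[test_idx]
    out_test = dataset.outcome.select(test_idx)
    return (
        concordance_index(risk_test, out_test),
        cumulative_auc(risk_test, out_test),
    )


def repeated_holdout(
    dataset: MultiOmicsSurvivalDataset,
    variant: str = "FULL",
    scheme: SplitScheme | None = None,
    **model_params,
) -> EvaluationReport:
    """Repeated random 80/20 holdout of one model variant.

    Extra keyword arguments are forwarded to :class:`GraphFusionSurvival`.
    """
    scheme = scheme or SplitScheme()
    event = dataset.outcome.event
    report = EvaluationReport()
    for seed in scheme.seeds:
        train_idx, test_idx = make_split(
            dataset.n_samples, scheme.train_frac, seed, event
        )
        c, a = _fit_and_score(dataset, variant, train_idx, test_idx, seed, model_params)
        report.c_indices.append(c)
        report.aucs.append(a)
        report.seeds.append(seed)
    return report


def select_k_cv(
    dataset: MultiOmicsSurvivalDataset,
    candidate_ks: list[int] | None = None,
    n_folds: int = 5,
    variant: str = "FULL",
    seed: int = 0,
    **model_params,
) -> int:
    """Choose the graph neighbourhood size by inner cross-validation.

    Folds are stratified by the event indicator on the given (training) data;
    the k with the highest mean validation concordance wins, ties going to the
    smaller k.
    """
    if candidate_ks is None:
        candidate_ks = list(range(2, 16))
    if not candidate_ks:
        raise ValueError("candidate_ks must be nonempty")
    if len(candidate_ks) == 1:
        return candidate_ks[0]
    event = dataset.outcome.event
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(dataset.n_samples), event))
    best_k, best_score = None, -np.inf
    for k in sorted(candidate_ks):
        scores = []
        for train_idx, val_idx in folds:
            c, _ = _fit_and_score(
                dataset, variant, train_idx, val_idx, seed, {**model_params, "k": k}
            )
            scores.append(c)
        mean_c = float(np.mean(scores))
        if mean_c > best_score:  # strict: ties keep the smaller k
            best_k, best_score = k, mean_c
    return best_k


def k_sensitivity_sweep(
    dataset: MultiOmicsSurvivalDataset,
    ks: list[int],
    scheme: SplitScheme | None = None,
    variant: str = "FULL",
    **model_params,
) -> pd.DataFrame:
    """Repeated-holdout C-index for each neighbourhood size k."""
    if not ks:
        raise ValueError("ks must be nonempty")
    rows = []
    for k in ks:
        try:
            rep = repeated_holdout(
                dataset, variant=variant, scheme=scheme, **{**model_params, "k": k}
            )
            rows.append(
                {"k": k, "c_index_mean": rep.c_index_mean, "c_index_sd": rep.c_index_sd}
            )
        except (ValueError, FloatingPointError) as err:  # keep partial results
            warnings.warn(f"k={k} failed: {err}", stacklevel=2)
            rows.append({"k": k, "c_index_mean": np.nan, "c_index_sd": np.nan})
    return pd.DataFrame(rows)


def ablation_study(
    dataset: MultiOmicsSurvivalDataset,
    variants: list[str] | None = None,
    scheme: SplitScheme | None = None,
    **model_params,
) -> pd.DataFrame:
    """Repeated holdout for several wiring variants, one row per variant."""
    variants = variants or ["FULL", "NO_FBM", "NO_GRAPH", "HIGH_FF", "LOW_FF", "FBM_FF"]
    rows = []
    for v in variants:
        rep = repeated_holdout(dataset, variant=v, scheme=scheme, **model_params)
        rows.append(
            {
                "variant": v,
                "c_index_mean": rep.c_index_mean,
                "c_index_sd": rep.c_index_sd,
                "auc_mean": rep.auc_mean,
                "auc_sd": rep.auc_sd,
            }
        )
    return pd.DataFrame(rows)
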