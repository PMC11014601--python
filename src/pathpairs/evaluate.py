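"""Model training and evaluation over repeated stratified train-test splits.

The evaluation protocol for pair classifiers: each CV iteration draws a
fresh stratified train-test split of the pair entries, duplicates the
positive entries of the *training* set until they make up at most half of it
(test sets are never oversampled — duplicated test entries inflate scores),
trains a gradient-boosted-tree or multilayer-perceptron backend, predicts on
the untouched test set, and records accuracy, precision, recall, F1 and the
Matthews correlation coefficient (MCC), both over all test pairs and
restricted to each pathway category's pairs.  MCC is the primary metric
because the pair data is heavily imbalanced (~10% positive).

Hyperparameter search runs seeded random-sampling trials, each evaluated by
the median MCC over a small number of CV iterations, with median pruning of
trials that trail the field.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .exceptions import (
    ConfigError,
    DegenerateTrainingSetError,
    StratificationError,
    UnsupportedOperationError,
)
from .pairs import PairDataset

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "Metrics",
    "CVResults",
    "TuneResult",
    "stratified_split",
    "oversample_positives",
    "compute_metrics",
    "train_model",
    "run_cv",
    "tune",
    "default_search_space",
]

OVERALL = "OVERALL"


@dataclass(frozen=True)
class SplitSpec:
    """How to draw one train-test split.

    ``stratify_key='pathway_label'`` stratifies jointly on (pathway, label)
    so every pathway category is represented in every test set and
    per-pathway metrics are always computable; ``'label'`` stratifies on the
    binary label alone.
    """

    test_fraction: float = 0.15
    stratify_key: str = "pathway_label"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must lie in (0, 1)")
        if self.stratify_key not in ("label", "pathway_label", "metabolite_grouped"):
            raise ConfigError(f"unknown stratify_key {self.stratify_key!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier backend plus hyperparameters.

    ``backend='gbt'`` is gradient-boosted trees (XGBoost); ``'mlp'`` is a
    multilayer perceptron.  Hyperparameter names must be recognized by the
    backend.
    """

    backend: str = "gbt"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("gbt", "mlp"):
            raise ConfigError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class Metrics:
    """The five confusion-matrix metrics; undefined ratios are 0 by convention."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class CVResults:
    """Per-iteration, per-pathway metric records and their summaries."""

    records: pd.DataFrame  # columns: iteration, seed, pathway_id, + metrics
    importance_scores: list[np.ndarray] | None = None  # per-iteration raw scores
    feature_schema: list[tuple[str, str]] | None = None

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation per (pathway_id | OVERALL, metric)."""
        metrics = ["accuracy", "precision", "recall", "f1", "mcc"]
        g = self.records.groupby("pathway_id")[metrics]
        out = pd.concat({"mean": g.mean(), "std": g.std(ddof=1)}, axis=1)
        return out.swaplevel(axis=1).sort_index(axis=1)

    def overall(self, metric: str = "mcc") -> tuple[float, float]:
        vals = self.records.loc[self.records.pathway_id == OVERALL, metric]
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def _strata(ds: PairDataset, key: str) -> np.ndarray:
    if key == "label":
        return ds.labels.astype(np.int64)
    # joint (pathway, label) strata
    return ds.pathway_positions() * 2 + ds.labels


def stratified_split(
    ds: PairDataset, spec: SplitSpec
) -> tuple[PairDataset, PairDataset]:
    """Split pair entries into disjoint train and test views.

    Per-stratum positive proportions are preserved within integer rounding;
    identical specs give identical splits.  ``metabolite_grouped`` is an
    opt-in leakage control that keeps all 12 pairs of a metabolite on one
    side of the split (grouped by metabolite, not stratified by label).
    """
    n = ds.n_entries
    if spec.stratify_key == "metabolite_grouped":
        mids = ds.metabolite_positions()
        uniq = np.unique(mids)
        rng = np.random.default_rng(spec.seed)
        shuffled = rng.permutation(uniq)
        n_test = int(round(spec.test_fraction * len(uniq)))
        test_m = set(shuffled[:n_test].tolist())
        mask = np.array([m in test_m for m in mids])
        return ds.subset(np.flatnonzero(~mask)), ds.subset(np.flatnonzero(mask))
    strata = _strata(ds, spec.stratify_key)
    counts = np.bincount(strata)
    if np.any(counts[np.unique(strata)] < 2):
        raise StratificationError(
            "every stratum needs at least 2 entries to be split"
        )
    train_idx, test_idx = train_test_split(
        np.arange(n),
        test_size=spec.test_fraction,
        stratify=strata,
        random_state=spec.seed % (2**32),
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def oversample_positives(train: PairDataset) -> PairDataset:
    """Duplicate positive entries until their proportion is <= 50% and maximal.

    Each positive entry ends up appearing k = floor(n_neg / n_pos) times
    (at least once); one more full round of duplication would push the
    positive proportion past one half.  Apply to training sets only.
    """
    y = train.labels
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingSetError(
            "oversampling needs both positives and negatives"
        )
    k = max(1, n_neg // n_pos)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    repeated = np.concatenate([neg] + [pos] * k)
    return train.subset(np.sort(repeated))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion-matrix metrics with the 0-when-undefined convention.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    when any factor of the denominator is 0; precision, recall and F1 are
    likewise 0 when their denominators vanish.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return Metrics(accuracy, precision, recall, f1, float(mcc), tp, fp, fn, tn)


_GBT_DEFAULTS: dict[str, Any] = {
    "n_estimators": 200,
    "max_depth": 6,
    "learning_rate": 0.3,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "min_child_weight": 1.0,
    "reg_lambda": 1.0,
}

_MLP_DEFAULTS: dict[str, Any] = {
    "hidden_layer_sizes": (128, 64),
    "learning_rate_init": 1e-3,
    "alpha": 1e-4,
    "batch_size": 256,
    "max_iter": 60,
    "early_stopping": False,
}


def train_model(spec: ModelSpec, train: PairDataset):
    """Fit the backend on a (typically oversampled) training view.

    Returns a fitted classifier exposing ``predict`` on dense pair matrices.
    """
    X, y = train.materialize()
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingSetError("training set contains a single class")
    if spec.backend == "gbt":
        params = {**_GBT_DEFAULTS, **spec.hyperparameters}
        clf = XGBClassifier(
            **params,
            tree_method="hist",
            n_jobs=1,
            random_state=spec.seed % (2**31),
            eval_metric="logloss",
        )
    else:
        params = {**_MLP_DEFAULTS, **spec.hyperparameters}
        if isinstance(params.get("hidden_layer_sizes"), list):
            params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        clf = MLPClassifier(
            **params,
            random_state=spec.seed % (2**31),
        )
    clf.fit(X, y)
    return clf


def _iteration_records(
    it: int, seed: int, test: PairDataset, y_pred: np.ndarray
) -> list[dict[str, Any]]:
    y_true = test.labels
    rows = [
        {"iteration": it, "seed": seed, "pathway_id": OVERALL,
         **compute_metrics(y_true, y_pred).__dict__}
    ]
    ppos = test.pathway_positions()
    for j, pid in enumerate(test.catalog.pathway_ids):
        mask = ppos == j
        if not mask.any():
            continue
        rows.append(
            {"iteration": it, "seed": seed, "pathway_id": pid,
             **compute_metrics(y_true[mask], y_pred[mask]).__dict__}
        )
    return rows


def run_cv(
    ds: PairDataset,
    spec: ModelSpec,
    split: SplitSpec,
    n_iterations: int,
    collect_importance: bool = False,
    progress: Callable[[int, Metrics], None] | None = None,
) -> CVResults:
    """Repeat split -> oversample -> fit -> score for ``n_iterations``.

    Iteration *i* uses split seed ``split.seed + i`` (derived, auditable).
    Per-pathway records are computed on the test subset restricted to each
    category's pair entries; their confusion counts partition the OVERALL
    counts.  ``collect_importance`` gathers per-iteration raw feature scores
    (tree backend only).
    """
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    if collect_importance and spec.backend != "gbt":
        raise UnsupportedOperationError(
            "feature importance is only defined for the tree backend"
        )
    rows: list[dict[str, Any]] = []
    scores: list[np.ndarray] = []
    for it in range(1, n_iterations + 1):
        seed_i = split.seed + it
        tr, te = stratified_split(
            ds, SplitSpec(split.test_fraction, split.stratify_key, seed_i)
        )
        tr = oversample_positives(tr)
        clf = train_model(
            ModelSpec(spec.backend, spec.hyperparameters, spec.seed + it), tr
        )
        Xte, _ = te.materialize()
        y_pred = np.asarray(clf.predict(Xte)).astype(np.int64)
        recs = _iteration_records(it, seed_i, te, y_pred)
        rows.extend(recs)
        if collect_importance:
            scores.append(np.asarray(clf.feature_importances_, dtype=np.float64))
        if progress is not None:
            m = recs[0]
            progress(it, Metrics(m["accuracy"], m["precision"], m["recall"],
                                 m["f1"], m["mcc"]))
    return CVResults(
        pd.DataFrame(rows),
        scores if collect_importance else None,
        ds.feature_schema if collect_importance else None,
    )


# --------------------------------------------------------------------- tuning

@dataclass
class TuneResult:
    """Outcome of a hyperparameter search."""

    trials: pd.DataFrame  # trial, hyperparameters, median_mcc, n_iterations, pruned
    best_trial: int
    best_hyperparameters: dict[str, Any]
    best_median_mcc: float


def default_search_space(backend: str) -> dict[str, dict[str, Any]]:
    """Editable default search spaces for both backends."""
    if backend == "gbt":
        return {
            "n_estimators": {"type": "int", "low": 50, "high": 400},
            "max_depth": {"type": "int", "low": 3, "high": 10},
            "learning_rate": {"type": "float", "low": 0.01, "high": 0.5, "log": True},
            "subsample": {"type": "float", "low": 0.5, "high": 1.0},
            "colsample_bytree": {"type": "float", "low": 0.5, "high": 1.0},
        }
    if backend == "mlp":
        return {
            "hidden_layer_sizes": {
                "type": "categorical",
                "choices": [[64], [128], [128, 64], [256, 128]],
            },
            "learning_rate_init": {"type": "float", "low": 1e-4, "high": 1e-2,
                                   "log": True},
            "alpha": {"type": "float", "low": 1e-6, "high": 1e-2, "log": True},
            "batch_size": {"type": "categorical", "choices": [128, 256, 512]},
            "max_iter": {"type": "int", "low": 30, "high": 120},
        }
    raise ConfigError(f"unknown backend {backend!r}")


def _sample_params(
    space: Mapping[str, Mapping[str, Any]], rng: np.random.Generator
) -> dict[str, Any]:
    params: dict[str, Any] = {}
    for name, s in space.items():
        kind = s["type"]
        if kind == "int":
            params[name] = int(rng.integers(s["low"], s["high"] + 1))
        elif kind == "float":
            if s.get("log"):
                lo, hi = np.log(s["low"]), np.log(s["high"])
                params[name] = float(np.exp(rng.uniform(lo, hi)))
            else:
                params[name] = float(rng.uniform(s["low"], s["high"]))
        elif kind == "categorical":
            params[name] = s["choices"][int(rng.integers(len(s["choices"])))]
        else:
            raise ConfigError(f"unknown search-space type {kind!r}")
    return params


def tune(
    ds: PairDataset,
    backend: str,
    search_space: Mapping[str, Mapping[str, Any]] | None = None,
    n_trials: int = 20,
    max_cv_iterations: int = 20,
    split: SplitSpec | None = None,
    seed: int = 0,
    n_startup_trials: int = 5,
    n_warmup_steps: int = 5,
) -> TuneResult:
    """Random-search hyperparameter tuning with median pruning.

    Each trial samples a configuration, runs up to ``max_cv_iterations`` CV
    iterations and is scored by its median test MCC.  After the warm-up
    steps a trial is pruned when its running median falls below the median
    of the running medians that earlier completed trials had at the same
    iteration count (the conventional median-pruning rule).  Fully seeded
    and deterministic.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    space = default_search_space(backend) if search_space is None else search_space
    if not space:
        raise ConfigError("empty search space")
    split = split or SplitSpec()
    rng = np.random.default_rng(seed)
    history: list[list[float]] = []  # running-median trajectory per completed trial
    rows: list[dict[str, Any]] = []
    for t in range(n_trials):
        params = _sample_params(space, rng)
        mccs: list[float] = []
        trajectory: list[float] = []
        pruned = False
        for it in range(1, max_cv_iterations + 1):
            seed_i = split.seed + (t + 1) * 10_000 + it
            tr, te = stratified_split(
                ds, SplitSpec(split.test_fraction, split.stratify_key, seed_i)
            )
            tr = oversample_positives(tr)
            clf = train_model(ModelSpec(backend, params, seed_i), tr)
            Xte, _ = te.materialize()
            m = compute_metrics(te.labels, np.asarray(clf.predict(Xte)))
            mccs.append(m.mcc)
            running = statistics.median(mccs)
            trajectory.append(running)
            if (
                t + 1 > n_startup_trials
                and it >= n_warmup_steps
                and it <= min(len(h) for h in history)
            ):
                peers = [h[it - 1] for h in history]
                if running < statistics.median(peers):
                    pruned = True
                    break
        if not pruned:
            history.append(trajectory)
        rows.append(
            {"trial": t, "hyperparameters": params,
             "median_mcc": statistics.median(mccs),
             "n_iterations": len(mccs), "pruned": pruned}
        )
    trials = pd.DataFrame(rows)
    completed = trials[~trials.pruned]
    best = completed.loc[completed.median_mcc.idxmax()]
    return TuneResult(
        trials, int(best.trial), dict(best.hyperparameters),
        float(best.median_mcc),
    )
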