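"""Evaluation protocol: holdout splits, tenfold cross-validation, the k-mer
size sweep, per-genus model comparison, information-gain feature ranking and
a 1-nearest-neighbor baseline.

The holdout split is a simple random draw without replacement (not
stratified); genera that end up absent from the training side are recorded
as unclassifiable rather than silently dropped. Cross-validation folds are a
global random partition with sizes differing by at most one.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureVector, build_vectors
from .naive_bayes import GenusNaiveBayes

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "CVResult",
    "ModelComparison",
    "split_train_test",
    "accuracy",
    "cross_validate",
    "kmer_sweep",
    "compare_models",
    "info_gain_ranking",
    "nn_baseline",
]

UNCLASSIFIABLE = "<unclassifiable>"


@dataclass(frozen=True)
class SplitSpec:
    """Holdout split parameters: test fraction (default 20 %) and seed."""

    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class EvaluationReport:
    """Overall and per-genus accuracy plus confusion counts."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    per_class_n: dict[str, int]
    confusion: dict[tuple[str, str], int]
    n_records: int
    n_classes: int

    @classmethod
    def from_predictions(
        cls, predictions: Sequence[str], truths: Sequence[str]
    ) -> "EvaluationReport":
        if len(predictions) != len(truths):
            raise ValueError(
                f"{len(predictions)} predictions vs {len(truths)} truths"
            )
        if not truths:
            raise ValueError("cannot evaluate an empty prediction set")
        confusion: Counter = Counter(zip(truths, predictions))
        correct_per_class: Counter = Counter()
        n_per_class: Counter = Counter()
        for pred, true in zip(predictions, truths):
            n_per_class[true] += 1
            if pred == true:
                correct_per_class[true] += 1
        per_class = {
            c: 100.0 * correct_per_class[c] / n_per_class[c] for c in n_per_class
        }
        n_correct = sum(correct_per_class.values())
        return cls(
            overall_accuracy=100.0 * n_correct / len(truths),
            per_class_accuracy=per_class,
            per_class_n=dict(n_per_class),
            confusion=dict(confusion),
            n_records=len(truths),
            n_classes=len(n_per_class),
        )


def split_train_test(dataset: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Random 80/20-style holdout partition.

    Test size is floor(test_fraction x N); the draw is without replacement
    and NOT stratified by genus. Reproducible for a given seed; each split
    preserves the dataset's relative order.
    """
    dataset = list(dataset)
    n = len(dataset)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    n_test = math.floor(spec.test_fraction * n)
    rng = np.random.default_rng(spec.seed)
    test_idx = set(rng.permutation(n)[:n_test].tolist())
    train = [dataset[i] for i in range(n) if i not in test_idx]
    test = [dataset[i] for i in range(n) if i in test_idx]
    return train, test


def accuracy(predictions: Sequence[str], truths: Sequence[str]) -> EvaluationReport:
    """Percent of correctly assigned genera, with confusion counts."""
    return EvaluationReport.from_predictions(predictions, truths)


@dataclass
class CVResult:
    mean_accuracy: float
    fold_accuracies: list[float]
    n_unclassifiable: int = 0


def assign_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Random fold index per record; fold sizes differ by at most one."""
    if n_folds < 2:
        raise ValueError(f"need at least 2 folds, got {n_folds}")
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def _cv_over_folds(
    vectors: Sequence[FeatureVector], fold_idx: np.ndarray
) -> CVResult:
    vectors = list(vectors)
    n_folds = int(fold_idx.max()) + 1
    fold_accuracies = []
    total_correct = 0
    n_unclassifiable = 0
    for fold in range(n_folds):
        train_vecs = [v for v, f in zip(vectors, fold_idx) if f != fold]
        test_vecs = [v for v, f in zip(vectors, fold_idx) if f == fold]
        results = GenusNaiveBayes(train_vecs).fit()
        known = set(results.classes)
        preds = []
        for vec in test_vecs:
            if vec.label not in known:
                preds.append(UNCLASSIFIABLE)
                n_unclassifiable += 1
            else:
                preds.append(None)
        to_score = [v for v, p in zip(test_vecs, preds) if p is None]
        if to_score:
            scored = iter(results.predict(to_score))
            preds = [p if p is not None else next(scored) for p in preds]
        correct = sum(p == v.label for p, v in zip(preds, test_vecs))
        total_correct += correct
        fold_accuracies.append(100.0 * correct / len(test_vecs))
    return CVResult(
        mean_accuracy=100.0 * total_correct / len(vectors),
        fold_accuracies=fold_accuracies,
        n_unclassifiable=n_unclassifiable,
    )


def cross_validate(
    vectors: Sequence[FeatureVector], n_folds: int = 10, seed: int = 0
) -> CVResult:
    """Tenfold cross-validation: leave one fold out, train on the rest.

    The mean accuracy pools correct calls over all folds divided by N, so
    unequal fold sizes do not bias the mean.
    """
    vectors = list(vectors)
    fold_idx = assign_folds(len(vectors), n_folds, seed)
    return _cv_over_folds(vectors, fold_idx)


def kmer_sweep(
    records: Sequence,
    k_values: Sequence[int] = (2, 3, 4, 5, 6),
    n_folds: int = 10,
    seed: int = 0,
    include_length: bool = True,
    include_gc: bool = True,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of k-mer size.

    The fold assignment is drawn once and reused for every k, so the rows
    are directly comparable.
    """
    records = list(records)
    fold_idx = assign_folds(len(records), n_folds, seed)
    rows = []
    for k in k_values:
        config = FeatureConfig(k=k, include_length=include_length, include_gc=include_gc)
        vectors, _ = build_vectors(records, config)
        result = _cv_over_folds(vectors, fold_idx)
        rows.append((k, result.mean_accuracy))
    return pd.DataFrame(rows, columns=["k", "cv_accuracy"])


@dataclass
class ModelComparison:
    """Per-genus accuracy of two models on their shared genera."""

    table: pd.DataFrame  # genus, acc_a, acc_b, n_a, n_b; sorted acc_b - acc_a desc
    equal_fraction: float


def compare_models(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> ModelComparison:
    """Compare two evaluation reports genus by genus.

    Restricted to genera present in both reports; ordered by (acc_b - acc_a)
    descending, so the genera best handled by model B come first. The
    equal-performance fraction uses exact equality of the accuracies rounded
    to two decimals.
    """
    shared = sorted(
        set(report_a.per_class_accuracy) & set(report_b.per_class_accuracy)
    )
    if not shared:
        raise ValueError("the two reports share no genera")
    rows = [
        (
            g,
            report_a.per_class_accuracy[g],
            report_b.per_class_accuracy[g],
            report_a.per_class_n[g],
            report_b.per_class_n[g],
        )
        for g in shared
    ]
    table = pd.DataFrame(rows, columns=["genus", "acc_a", "acc_b", "n_a", "n_b"])
    table["delta"] = table["acc_b"] - table["acc_a"]
    table = table.sort_values(["delta", "genus"], ascending=[False, True]).drop(
        columns="delta"
    )
    table = table.reset_index(drop=True)
    equal = np.isclose(
        np.round(table["acc_a"].to_numpy(), 2), np.round(table["acc_b"].to_numpy(), 2)
    )
    return ModelComparison(table=table, equal_fraction=float(equal.mean()))


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain_ranking(
    vectors: Sequence[FeatureVector],
    n_bins: int = 10,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank features by information gain with respect to the genus label.

    Each feature is discretized into ``n_bins`` equal-width bins over its
    observed range; IG = H(class) - sum_b p(b) H(class | b), in bits.
    Descending order, ties broken by feature index.
    """
    vectors = list(vectors)
    X = np.array([v.values for v in vectors], dtype=float)
    y = np.array([v.label for v in vectors])
    if len(set(y.tolist())) < 2:
        raise ValueError("information gain is undefined for a constant class")
    h_class = _entropy_bits(y)
    gains = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        col = X[:, f]
        lo, hi = col.min(), col.max()
        if hi == lo:
            continue  # constant feature: one bin, IG = 0
        bins = np.minimum(((col - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            h_cond += mask.mean() * _entropy_bits(y[mask])
        gains[f] = h_class - h_cond
    order = np.lexsort((np.arange(len(gains)), -gains))
    table = pd.DataFrame(
        {
            "feature": order,
            "info_gain_bits": gains[order],
        }
    )
    if feature_names is not None:
        table.insert(1, "name", [feature_names[i] for i in order])
    return table.reset_index(drop=True)


def _infer_kmer_block(n_features: int) -> int:
    # layouts are 4^k plus up to two scalar features; 4^k + 2 < 4^(k+1)
    for k in range(1, 9):
        if 4 ** k <= n_features <= 4 ** k + 2:
            return 4 ** k
    raise ValueError(f"cannot infer k-mer block size from {n_features} features")


def nn_baseline(
    train_vectors: Sequence[FeatureVector],
    test_vectors: Sequence[FeatureVector],
    config: FeatureConfig | None = None,
) -> list[str]:
    """1-nearest-neighbor by cosine similarity on the k-mer block only.

    An alignment-free stand-in for a best-hit database search baseline.
    Ties go to the smallest training index.
    """
    train_vectors = list(train_vectors)
    test_vectors = list(test_vectors)
    if not train_vectors:
        raise ValueError("empty training set")
    if not test_vectors:
        return []
    n_block = (
        config.n_kmers if config is not None else _infer_kmer_block(len(train_vectors[0].values))
    )
    train_X = np.array([v.values[:n_block] for v in train_vectors], dtype=float)
    test_X = np.array([v.values[:n_block] for v in test_vectors], dtype=float)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test vectors have different feature layouts")

    def _unit(rows: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return rows / norms

    sims = _unit(test_X) @ _unit(train_X).T
    best = np.argmax(sims, axis=1)  # first max = smallest training index
    return [train_vectors[i].label for i in best]
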