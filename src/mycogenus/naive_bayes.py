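"""Gaussian naive Bayes over sequence feature vectors.

The model assumes each feature is conditionally Gaussian given the genus:

    log P(c | x) = log pi_c + sum_f log N(x_f; mu_cf, s2_cf) - log Z(x)

with maximum-likelihood (1/n) class-conditional means and variances, class
priors pi_c = n_c / N, and all arithmetic in natural-log space with
log-sum-exp normalization — 4^5 + 2 features underflow double precision
otherwise. Variances are clamped from below at (1e-4 x global feature
range)^2, with an absolute floor of 1e-12, to avoid degenerate zero-variance
likelihood spikes on constant features.

The API follows the model/results convention: build a
:class:`GenusNaiveBayes` from feature vectors (or records), call ``fit()``,
and use the returned :class:`GenusNaiveBayesResults` to classify. The
module-level :func:`train`, :func:`log_posteriors`, :func:`classify` and
:func:`classify_fasta` are thin functional wrappers over the same objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .features import FeatureConfig, FeatureVector, build_vectors
from .seqio import SequenceRecord, load_model, read_fasta, save_model

__all__ = [
    "GenusNaiveBayes",
    "GenusNaiveBayesResults",
    "train",
    "log_posteriors",
    "classify",
    "classify_fasta",
]

VAR_FLOOR_REL = 1e-4
VAR_FLOOR_ABS = 1e-12

NO_KMER_FLAG = "no_valid_kmers"


class GenusNaiveBayes:
    """Gaussian naive Bayes genus classifier, built from feature vectors.

    Parameters
    ----------
    vectors : sequence of FeatureVector
        Labeled training vectors sharing one feature layout.
    feature_config : FeatureConfig, optional
        Featurization metadata frozen into the fitted model; required for
        classifying raw sequences later.
    train_avg_length : float, optional
        Dataset average length used for the normalized-length feature;
        frozen into the model so single queries normalize consistently.
    """

    def __init__(
        self,
        vectors: Sequence[FeatureVector],
        feature_config: FeatureConfig | None = None,
        train_avg_length: float = float("nan"),
    ) -> None:
        vectors = list(vectors)
        if not vectors:
            raise ValueError("no training vectors")
        n_features = len(vectors[0].values)
        for vec in vectors:
            if len(vec.values) != n_features:
                raise ValueError(
                    f"vector {vec.source_id!r} has {len(vec.values)} features, "
                    f"expected {n_features}"
                )
        if feature_config is not None and feature_config.n_features != n_features:
            raise ValueError(
                f"feature config implies {feature_config.n_features} features, "
                f"vectors have {n_features}"
            )
        self.X = np.array([vec.values for vec in vectors], dtype=float)
        self.y = np.array([vec.label for vec in vectors])
        self.feature_config = feature_config
        self.train_avg_length = train_avg_length

    @classmethod
    def from_records(
        cls, records: Sequence[SequenceRecord], config: FeatureConfig | None = None
    ) -> "GenusNaiveBayes":
        config = config or FeatureConfig()
        vectors, avg_len = build_vectors(records, config)
        return cls(vectors, feature_config=config, train_avg_length=avg_len)

    def fit(self) -> "GenusNaiveBayesResults":
        classes = sorted(set(self.y))
        if len(classes) < 2:
            raise ValueError(f"need at least 2 classes to train, got {len(classes)}")
        n, n_features = self.X.shape
        ranges = self.X.max(axis=0) - self.X.min(axis=0)
        var_floor = np.maximum((VAR_FLOOR_REL * ranges) ** 2, VAR_FLOOR_ABS)
        log_priors = np.empty(len(classes))
        means = np.empty((len(classes), n_features))
        variances = np.empty((len(classes), n_features))
        for ci, cls_name in enumerate(classes):
            rows = self.X[self.y == cls_name]
            if len(rows) < 2:
                warnings.warn(
                    f"class {cls_name!r} has only {len(rows)} training vector(s); "
                    "its variances fall to the floor",
                    stacklevel=2,
                )
            log_priors[ci] = np.log(len(rows) / n)
            means[ci] = rows.mean(axis=0)
            variances[ci] = np.maximum(rows.var(axis=0), var_floor)
        return GenusNaiveBayesResults(
            classes=classes,
            log_priors=log_priors,
            means=means,
            variances=variances,
            feature_config=self.feature_config,
            train_avg_length=self.train_avg_length,
            n_train=n,
        )


@dataclass
class GenusNaiveBayesResults:
    """Fitted parameters plus prediction, summary and persistence."""

    classes: list[str]
    log_priors: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    feature_config: FeatureConfig | None = None
    train_avg_length: float = float("nan")
    n_train: int | None = None

    def __post_init__(self) -> None:
        self.log_priors = np.asarray(self.log_priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        n_classes = len(self.classes)
        if self.means.shape != self.variances.shape or self.means.shape[0] != n_classes:
            raise ValueError("means/variances dimensions do not match the class list")
        if not np.isclose(np.exp(logsumexp(self.log_priors)), 1.0, atol=1e-9):
            raise ValueError("class priors must sum to 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def _check_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"vector has {x.shape[1]} features, model expects {self.n_features}"
            )
        return x

    def predict_log_proba(self, x) -> np.ndarray:
        """Normalized log posteriors, rows = inputs, columns = self.classes."""
        x = self._check_x(x)
        # (n, C, F) broadcast of the Gaussian log-density
        diff = x[:, None, :] - self.means[None, :, :]
        log_like = -0.5 * (
            np.log(2 * np.pi * self.variances)[None, :, :]
            + diff * diff / self.variances[None, :, :]
        ).sum(axis=2)
        joint = log_like + self.log_priors[None, :]
        return joint - logsumexp(joint, axis=1, keepdims=True)

    def log_posteriors(self, vector) -> dict[str, float]:
        values = vector.values if isinstance(vector, FeatureVector) else vector
        row = self.predict_log_proba(values)[0]
        return dict(zip(self.classes, row.tolist()))

    def _best_index(self, row: np.ndarray) -> int:
        # exact ties go to the lexicographically smallest genus
        tied = np.flatnonzero(row == row.max())
        if len(tied) == 1:
            return int(tied[0])
        return int(min(tied, key=lambda i: self.classes[i]))

    def classify(self, vector) -> tuple[str, float]:
        """Argmax genus and its posterior probability."""
        values = vector.values if isinstance(vector, FeatureVector) else vector
        row = self.predict_log_proba(values)[0]
        best = self._best_index(row)
        return self.classes[best], float(np.exp(row[best]))

    def predict(self, vectors: Iterable) -> list[str]:
        values = np.array(
            [v.values if isinstance(v, FeatureVector) else v for v in vectors],
            dtype=float,
        )
        if values.size == 0:
            return []
        rows = self.predict_log_proba(values)
        return [self.classes[self._best_index(row)] for row in rows]

    def classify_fasta(self, fasta_path) -> pd.DataFrame:
        """Classify every sequence of a FASTA file.

        Featurizes with the model's frozen FeatureConfig and training-set
        average length; output order equals input order. Sequences with no
        valid k-mer window (e.g. shorter than k) are still classified, from
        an all-zero k-mer block, and flagged ``no_valid_kmers``.
        """
        if self.feature_config is None:
            raise ValueError("model carries no feature config; cannot featurize")
        if not np.isfinite(self.train_avg_length) or self.train_avg_length <= 0:
            raise ValueError("model carries no training average length")
        pairs = read_fasta(fasta_path)
        rows = []
        for rid, seq in pairs:
            rec = SequenceRecord(rid, seq)
            vectors, _ = build_vectors(
                [rec], self.feature_config, avg_len=self.train_avg_length
            )
            vec = vectors[0]
            kmer_block = vec.values[: self.feature_config.n_kmers]
            flags = "" if kmer_block.sum() > 0 else NO_KMER_FLAG
            genus, post = self.classify(vec)
            rows.append((rid, genus, post, flags))
        return pd.DataFrame(rows, columns=["id", "genus", "posterior", "flags"])

    def summary(self) -> pd.DataFrame:
        """Per-genus parameter overview: prior and mean/spread aggregates."""
        return pd.DataFrame(
            {
                "genus": self.classes,
                "prior": np.exp(self.log_priors),
                "mean_feature": self.means.mean(axis=1),
                "mean_variance": self.variances.mean(axis=1),
            }
        )

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "GenusNaiveBayesResults":
        return load_model(path)


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    vectors: Sequence[FeatureVector],
    feature_config: FeatureConfig | None = None,
    train_avg_length: float = float("nan"),
) -> GenusNaiveBayesResults:
    return GenusNaiveBayes(vectors, feature_config, train_avg_length).fit()


def log_posteriors(model: GenusNaiveBayesResults, vector) -> dict[str, float]:
    return model.log_posteriors(vector)


def classify(model: GenusNaiveBayesResults, vector) -> tuple[str, float]:
    return model.classify(vector)


def classify_fasta(model: GenusNaiveBayesResults, fasta_path) -> pd.DataFrame:
    return model.classify_fasta(fasta_path)
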