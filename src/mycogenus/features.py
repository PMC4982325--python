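"""Feature extraction: k-mer frequencies, normalized length, GC percent.

A sequence becomes a vector of 4^k k-mer relative frequencies (lexicographic
k-mer order), optionally followed by its length normalized by the dataset
average length and its GC content in percent — the 4^k + 2 layout used for
genus classification.

Ambiguity handling: only A/C/G/T participate. Sliding windows containing any
other IUPAC code are skipped and the frequency denominator is the number of
valid windows; GC percent is computed over A/C/G/T characters only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "enumerate_kmers",
    "kmer_frequencies",
    "gc_percent",
    "normalized_length",
    "build_vectors",
]

_BASES = "ACGT"

# byte -> base index, -1 for anything that is not A/C/G/T (upper or lower)
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class FeatureConfig:
    """Word length and which scalar features accompany the k-mer block."""

    k: int = 5
    include_length: bool = True
    include_gc: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 8:
            raise ValueError(f"k must be in [2, 8], got {self.k}")

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    @property
    def n_features(self) -> int:
        return self.n_kmers + int(self.include_length) + int(self.include_gc)

    def feature_names(self) -> list[str]:
        names = enumerate_kmers(self.k)
        if self.include_length:
            names.append("norm_length")
        if self.include_gc:
            names.append("gc_percent")
        return names


@dataclass(frozen=True)
class FeatureVector:
    """One featurized sequence: values, genus label, source sequence id."""

    values: np.ndarray
    label: str
    source_id: str


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k DNA words of length k in lexicographic order."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    return ["".join(p) for p in product(_BASES, repeat=k)]


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Relative k-mer frequencies over sliding windows of step 1.

    Windows containing any non-ACGT character are skipped; the vector is the
    counts divided by the number of valid windows, or all-zero when no valid
    window exists (e.g. sequence shorter than k).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_kmers = 4 ** k
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.zeros(n_kmers)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros(n_kmers)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    indices = windows[valid] @ powers
    counts = np.bincount(indices, minlength=n_kmers)
    return counts / n_valid


def gc_percent(seq: str) -> float:
    """GC content as a percentage of A/C/G/T characters; 0 if none present."""
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    n_acgt = int((codes >= 0).sum())
    if n_acgt == 0:
        return 0.0
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return 100.0 * n_gc / n_acgt


def normalized_length(seq_len: int, avg_len: float) -> float:
    """Sequence length divided by the dataset average length."""
    if avg_len <= 0:
        raise ValueError(f"average length must be positive, got {avg_len}")
    return seq_len / avg_len


def build_vectors(
    records: Sequence[SequenceRecord],
    config: FeatureConfig,
    avg_len: float | None = None,
) -> tuple[list[FeatureVector], float]:
    """Featurize records; returns the vectors and the average length used.

    At training time ``avg_len`` is left None and computed as the mean length
    of ``records``. At prediction time the caller passes the training-set
    average frozen in the model, so queries are classifiable one at a time.
    """
    records = list(records)
    if avg_len is None:
        if not records:
            raise ValueError("cannot featurize an empty dataset without a supplied avg_len")
        avg_len = float(np.mean([rec.length for rec in records]))
    if avg_len <= 0:
        raise ValueError(f"average length must be positive, got {avg_len}")
    vectors = []
    for rec in records:
        parts = [kmer_frequencies(rec.seq, config.k)]
        if config.include_length:
            parts.append([normalized_length(rec.length, avg_len)])
        if config.include_gc:
            parts.append([gc_percent(rec.seq)])
        vectors.append(
            FeatureVector(np.concatenate(parts), rec.lineage.genus, rec.id)
        )
    return vectors, avg_len
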