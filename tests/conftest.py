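import numpy as np
import pytest

from mycogenus.features import FeatureConfig, build_vectors
from mycogenus.naive_bayes import GenusNaiveBayes
from mycogenus.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated synthetic genus families: 10 genera x 8 sequences."""
    records, truth = generate_dataset(
        SyntheticSpec(n_genera=10, seqs_per_genus=8, seed=11)
    )
    return records, truth


@pytest.fixture(scope="session")
def small_vectors(small_dataset):
    records, _ = small_dataset
    config = FeatureConfig(k=5)
    vectors, avg_len = build_vectors(records, config)
    return vectors, config, avg_len


@pytest.fixture(scope="session")
def small_model(small_vectors):
    vectors, config, avg_len = small_vectors
    return GenusNaiveBayes(vectors, config, avg_len).fit()


def brute_force_kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Independent oracle: materialize every window string and count."""
    from mycogenus.features import enumerate_kmers

    words = enumerate_kmers(k)
    index = {w: i for i, w in enumerate(words)}
    counts = np.zeros(len(words))
    n_valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window in index:
            counts[index[window]] += 1
            n_valid += 1
    return counts / n_valid if n_valid else counts
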