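from collections import Counter

import numpy as np
import pytest

from mycogenus.evaluation import (
    CVResult,
    EvaluationReport,
    SplitSpec,
    accuracy,
    assign_folds,
    compare_models,
    cross_validate,
    info_gain_ranking,
    kmer_sweep,
    nn_baseline,
    split_train_test,
)
from mycogenus.features import FeatureConfig, FeatureVector
from mycogenus.seqio import Lineage, SequenceRecord


def _vec(values, label, source="s"):
    return FeatureVector(np.asarray(values, dtype=float), label, source)


def _separable_vectors(n_per_class=10, seed=0):
    """Two far-apart Gaussian clusters: trivially separable."""
    rng = np.random.default_rng(seed)
    vecs = [_vec(rng.normal(loc=0.0, size=3), "A") for _ in range(n_per_class)]
    vecs += [_vec(rng.normal(loc=50.0, size=3), "B") for _ in range(n_per_class)]
    return vecs


class TestSplit:
    def test_test_size_is_floor_of_fraction(self):
        train, test = split_train_test(list(range(10)), SplitSpec(0.2, seed=1))
        assert len(test) == 2 and len(train) == 8

    def test_same_seed_reproduces_partition(self):
        a = split_train_test(list(range(40)), SplitSpec(seed=3))
        b = split_train_test(list(range(40)), SplitSpec(seed=3))
        assert a == b

    def test_partition_properties(self):
        for seed in range(5):
            data = list(range(37))
            train, test = split_train_test(data, SplitSpec(0.2, seed=seed))
            assert sorted(train + test) == data
            assert not set(train) & set(test)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([1], SplitSpec())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.0)


class TestAccuracy:
    def test_all_correct(self):
        report = accuracy(["A", "B"], ["A", "B"])
        assert report.overall_accuracy == 100.0

    def test_percentage_of_matches(self):
        truths = ["A"] * 100
        preds = ["A"] * 87 + ["B"] * 13
        assert accuracy(preds, truths).overall_accuracy == 87.0

    def test_confusion_diagonal_identity(self):
        report = accuracy(["A", "B", "A", "B"], ["A", "B", "B", "B"])
        diag = sum(v for (t, p), v in report.confusion.items() if t == p)
        assert report.overall_accuracy == 100.0 * diag / report.n_records

    def test_per_class_defined_for_true_classes_only(self):
        report = accuracy(["C", "B"], ["A", "B"])
        assert set(report.per_class_accuracy) == {"A", "B"}

    def test_invariant_under_relabeling(self):
        preds, truths = ["A", "B", "A", "C"], ["A", "B", "B", "C"]
        relabel = {"A": "X", "B": "Y", "C": "Z"}
        a = accuracy(preds, truths).overall_accuracy
        b = accuracy([relabel[p] for p in preds], [relabel[t] for t in truths])
        assert a == b.overall_accuracy

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy(["A"], ["A", "B"])


class TestCrossValidate:
    def test_equal_folds_for_divisible_n(self):
        folds = assign_folds(20, 10, seed=0)
        assert sorted(Counter(folds.tolist()).values()) == [2] * 10

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = assign_folds(23, 10, seed=0)
        sizes = sorted(Counter(folds.tolist()).values())
        assert sizes == [2] * 7 + [3] * 3

    def test_every_index_in_exactly_one_fold(self):
        folds = assign_folds(57, 10, seed=4)
        assert folds.shape == (57,)
        assert set(folds.tolist()) == set(range(10))

    def test_separable_data_scores_100_each_fold(self):
        result = cross_validate(_separable_vectors(), n_folds=10, seed=2)
        assert result.fold_accuracies == [100.0] * 10
        assert result.mean_accuracy == 100.0

    def test_mean_pools_correct_calls_over_n(self):
        result = cross_validate(_separable_vectors(n_per_class=12), n_folds=8, seed=1)
        assert isinstance(result, CVResult)
        assert result.mean_accuracy == pytest.approx(
            np.average(result.fold_accuracies, weights=[3] * 8)
        )

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(_separable_vectors(), n_folds=1)


def _labeled_records(n_genera=4, per_genus=6, seed=0, length=150):
    rng = np.random.default_rng(seed)
    records = []
    for g in range(n_genera):
        base = "".join(rng.choice(list("ACGT"), size=length))
        for m in range(per_genus):
            seq = list(base)
            for pos in rng.integers(0, length, size=8):
                seq[pos] = rng.choice(list("ACGT"))
            records.append(
                SequenceRecord(
                    f"g{g}m{m}", "".join(seq), Lineage(genus=f"Genus{g:02d}")
                )
            )
    return records


class TestKmerSweep:
    def test_single_k_gives_single_row(self):
        table = kmer_sweep(_labeled_records(), k_values=[3], n_folds=4, seed=0)
        assert list(table.columns) == ["k", "cv_accuracy"]
        assert len(table) == 1 and table.loc[0, "k"] == 3

    def test_rows_share_one_fold_assignment(self):
        records = _labeled_records()
        a = kmer_sweep(records, k_values=[3, 3], n_folds=4, seed=5)
        assert a.loc[0, "cv_accuracy"] == a.loc[1, "cv_accuracy"]

    def test_single_class_error_propagates(self):
        records = _labeled_records(n_genera=1)
        with pytest.raises(ValueError, match="class"):
            kmer_sweep(records, k_values=[2], n_folds=3, seed=0)


def _report(per_class, per_n=None):
    per_n = per_n or {g: 10 for g in per_class}
    return EvaluationReport(
        overall_accuracy=float(np.mean(list(per_class.values()))),
        per_class_accuracy=per_class,
        per_class_n=per_n,
        confusion={},
        n_records=sum(per_n.values()),
        n_classes=len(per_class),
    )


class TestCompareModels:
    def test_identical_reports_are_fully_equal(self):
        report = _report({"Ga": 80.0, "Gb": 100.0})
        cmp = compare_models(report, report)
        assert cmp.equal_fraction == 1.0
        assert (cmp.table["acc_a"] == cmp.table["acc_b"]).all()

    def test_disjoint_class_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_report({"Ga": 50.0}), _report({"Gb": 50.0}))

    def test_hand_built_ordering_and_equal_fraction(self):
        a = _report({"g1": 50.0, "g2": 100.0, "g3": 80.0})
        b = _report({"g1": 90.0, "g2": 100.0, "g3": 60.0})
        cmp = compare_models(a, b)
        # deltas: g1 +40, g2 0, g3 -20 -> B-favoured genera first
        assert list(cmp.table["genus"]) == ["g1", "g2", "g3"]
        assert cmp.equal_fraction == pytest.approx(1 / 3)

    def test_restricted_to_shared_genera(self):
        a = _report({"g1": 50.0, "g2": 100.0})
        b = _report({"g2": 90.0, "g3": 10.0})
        cmp = compare_models(a, b)
        assert list(cmp.table["genus"]) == ["g2"]


class TestInfoGain:
    def test_perfectly_separating_feature_is_one_bit(self):
        vecs = [_vec([0.0], "A")] * 8 + [_vec([1.0], "B")] * 8
        table = info_gain_ranking(vecs)
        assert table.loc[0, "info_gain_bits"] == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        vecs = [_vec([3.3, 0.0], "A")] * 5 + [_vec([3.3, 1.0], "B")] * 5
        table = info_gain_ranking(vecs)
        row = table[table["feature"] == 0].iloc[0]
        assert row["info_gain_bits"] == 0.0

    def test_four_classes_split_into_pure_pairs_is_one_bit(self):
        # H(class)=2 bits; the feature resolves 2 pure pairs -> 1 bit left
        vecs = (
            [_vec([0.0], "A")] * 4
            + [_vec([0.0], "B")] * 4
            + [_vec([1.0], "C")] * 4
            + [_vec([1.0], "D")] * 4
        )
        table = info_gain_ranking(vecs)
        assert table.loc[0, "info_gain_bits"] == pytest.approx(1.0)

    def test_bounded_by_class_entropy_and_nonnegative(self):
        rng = np.random.default_rng(12)
        vecs = [
            _vec(rng.normal(size=6), rng.choice(["A", "B", "C"])) for _ in range(60)
        ]
        labels = [v.label for v in vecs]
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        h_class = -(p * np.log2(p)).sum()
        table = info_gain_ranking(vecs)
        assert (table["info_gain_bits"] >= 0).all()
        assert (table["info_gain_bits"] <= h_class + 1e-12).all()

    def test_constant_class_rejected(self):
        with pytest.raises(ValueError):
            info_gain_ranking([_vec([1.0], "A"), _vec([2.0], "A")])


class TestNNBaseline:
    def test_identical_vector_recovers_training_label(self):
        config = FeatureConfig(k=2, include_length=False, include_gc=False)
        rng = np.random.default_rng(0)
        train_vecs = [_vec(rng.random(16), l) for l in ["A", "B", "C"]]
        preds = nn_baseline(train_vecs, [train_vecs[1]], config)
        assert preds == ["B"]

    def test_orthogonal_toys(self):
        config = FeatureConfig(k=2, include_length=False, include_gc=False)
        e = np.eye(16)
        train_vecs = [_vec(e[0], "A"), _vec(e[1], "B")]
        assert nn_baseline(train_vecs, [_vec(e[1] * 3.0, "?")], config) == ["B"]

    def test_similarity_uses_kmer_block_only(self):
        # identical k-mer blocks, wildly different scalar features
        config = FeatureConfig(k=2)
        block = np.random.default_rng(1).random(16)
        train_vecs = [
            _vec(np.concatenate([block, [1.0, 50.0]]), "A"),
            _vec(np.concatenate([np.roll(block, 5), [0.5, 10.0]]), "B"),
        ]
        query = _vec(np.concatenate([block, [9.0, 99.0]]), "?")
        assert nn_baseline(train_vecs, [query], config) == ["A"]

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            nn_baseline([], [_vec(np.zeros(16), "?")], FeatureConfig(k=2))

    def test_competitive_with_nb_on_separated_genera(self, small_vectors, small_model):
        vectors, config, _ = small_vectors
        rng = np.random.default_rng(8)
        idx = rng.permutation(len(vectors))
        test_idx, train_idx = idx[:16], idx[16:]
        train_vecs = [vectors[i] for i in train_idx]
        test_vecs = [vectors[i] for i in test_idx]
        from mycogenus.naive_bayes import GenusNaiveBayes

        nb = GenusNaiveBayes(train_vecs).fit()
        nb_acc = accuracy(nb.predict(test_vecs), [v.label for v in test_vecs])
        nn_acc = accuracy(
            nn_baseline(train_vecs, test_vecs, config), [v.label for v in test_vecs]
        )
        assert nn_acc.overall_accuracy >= nb_acc.overall_accuracy - 10.0


class TestLabelNoiseDegradation:
    def test_cv_accuracy_degrades_monotonically(self, small_vectors):
        vectors, _, _ = small_vectors

        def noisy(rate, seed=77):
            rng = np.random.default_rng(seed)
            labels = sorted({v.label for v in vectors})
            out = []
            for v in vectors:
                if rng.random() < rate:
                    out.append(
                        FeatureVector(
                            v.values,
                            rng.choice([l for l in labels if l != v.label]),
                            v.source_id,
                        )
                    )
                else:
                    out.append(v)
            return out

        accs = [
            cross_validate(noisy(rate), n_folds=5, seed=3).mean_accuracy
            for rate in (0.0, 0.1, 0.25)
        ]
        assert accs[0] >= accs[1] - 2.0
        assert accs[1] >= accs[2] - 2.0
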