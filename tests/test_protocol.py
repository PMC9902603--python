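"""Splitting, metrics, and the repeated-trial protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromotype import (
    SplitSpec,
    augment_pool,
    balanced_subset,
    concordance_rate,
    generate_chromosome,
    generate_dataset,
    run_protocol,
    select_validation_and_training,
    split_dataset,
    type_distribution,
)
from chromotype.protocol import confusion_matrix, trial_seed


@pytest.fixture(scope="module")
def dataset(tiny_config):
    return generate_dataset({"A": 140, "B": 100, "C": 60}, tiny_config, seed=41)


class TestSplitDataset:
    def test_cell_split_is_disjoint_and_exhaustive(self, dataset):
        spec = SplitSpec(test_size=84, test_unit="cell", validation_size=40)
        test, pool = split_dataset(dataset, spec, seed=1)
        assert len(test) == 84
        assert len(test) + len(pool) == len(dataset)
        assert {im.cell_id for im in test}.isdisjoint({im.cell_id for im in pool})

    def test_image_split_exact_size(self, dataset):
        spec = SplitSpec(test_size=77, test_unit="image", validation_size=40)
        test, pool = split_dataset(dataset, spec, seed=1)
        assert len(test) == 77 and len(pool) == len(dataset) - 77

    def test_same_seed_gives_identical_split(self, dataset):
        spec = SplitSpec(test_size=84, test_unit="cell", validation_size=40)
        t1, p1 = split_dataset(dataset, spec, seed=5)
        t2, p2 = split_dataset(dataset, spec, seed=5)
        assert [id(im) for im in t1] == [id(im) for im in t2]
        assert [id(im) for im in p1] == [id(im) for im in p2]

    def test_oversized_test_rejected(self, dataset):
        spec = SplitSpec(test_size=10_000, validation_size=40)
        with pytest.raises(ValueError, match="exceeds"):
            split_dataset(dataset, spec)


class TestPoolOperations:
    def test_augment_increases_pool_by_exact_count(self, dataset, tiny_config):
        extras = [
            generate_chromosome("C", tiny_config, rng=1000 + i, cell_id=f"x{i}")
            for i in range(15)
        ]
        pool = augment_pool(list(dataset[:50]), extras)
        assert len(pool) == 65
        c_before = sum(im.label == "C" for im in dataset[:50])
        assert sum(im.label == "C" for im in pool) == c_before + 15
        assert all(getattr(im, "augmented", False) for im in pool[50:])

    def test_empty_extras_is_identity(self, dataset):
        pool = augment_pool(list(dataset[:20]), [])
        assert len(pool) == 20

    def test_validation_training_split_sizes(self, dataset):
        val, train = select_validation_and_training(list(dataset), 60, seed=2)
        assert len(val) == 60
        assert len(train) == len(dataset) - 60
        assert {id(i) for i in val}.isdisjoint({id(i) for i in train})

    def test_zero_validation_keeps_whole_pool(self, dataset):
        val, train = select_validation_and_training(list(dataset), 0, seed=2)
        assert val == [] and len(train) == len(dataset)

    def test_explicit_training_size_leaves_remainder_unused(self, dataset):
        val, train = select_validation_and_training(
            list(dataset), 60, seed=2, training_size=200
        )
        assert len(val) == 60 and len(train) == 200

    def test_oversize_validation_rejected(self, dataset):
        with pytest.raises(ValueError, match="pool size"):
            select_validation_and_training(list(dataset[:10]), 10)

    def test_balanced_subset_exact_counts(self, dataset):
        sub = balanced_subset(list(dataset), 20, seed=3)
        assert len(sub) == 60
        for lab in "ABC":
            assert sum(im.label == lab for im in sub) == 20

    def test_balanced_subset_minimal_case(self, dataset):
        sub = balanced_subset(list(dataset), 1, seed=3)
        assert sorted(im.label for im in sub) == ["A", "B", "C"]

    def test_insufficient_label_names_the_label(self, dataset):
        # type C (60 available) runs out first at 61 per label
        with pytest.raises(ValueError, match="type C"):
            balanced_subset(list(dataset), 61, seed=3)


class TestMetrics:
    def test_concordance_examples(self):
        assert concordance_rate("AAB", "AAB") == 100.0
        assert abs(concordance_rate(list("AAB"), list("ABB")) - 200 / 3) < 1e-9
        assert concordance_rate(list("AAA"), list("BBB")) == 0.0

    def test_concordance_errors(self):
        with pytest.raises(ValueError, match="length"):
            concordance_rate("AB", "A")
        with pytest.raises(ValueError, match="non-empty"):
            concordance_rate("", "")

    def test_distribution_examples(self):
        assert np.allclose(type_distribution(list("AABC")), [50, 25, 25])
        assert np.allclose(type_distribution(list("AAAA")), [100, 0, 0])
        with pytest.raises(ValueError):
            type_distribution([])

    def test_distribution_reproduces_reference_test_composition(self):
        # 654 labels at the observed 417/205/32 composition
        labels = ["A"] * 417 + ["B"] * 205 + ["C"] * 32
        dist = type_distribution(labels)
        assert np.allclose(np.round(dist, 1), [63.8, 31.3, 4.9])
        assert abs(dist.sum() - 100.0) < 1e-9

    @settings(deadline=None, max_examples=30)
    @given(
        labels=st.lists(st.sampled_from("ABC"), min_size=1, max_size=60),
        preds=st.lists(st.sampled_from("ABC"), min_size=60, max_size=60),
    )
    def test_confusion_trace_equals_concordance(self, labels, preds):
        preds = preds[: len(labels)]
        mat = confusion_matrix(labels, preds)
        assert mat.sum() == len(labels)
        assert 100.0 * np.trace(mat) / mat.sum() == concordance_rate(labels, preds)


@pytest.fixture(scope="module")
def small_run(default_config):
    data = generate_dataset({"A": 16, "B": 16, "C": 16}, default_config, seed=51)
    spec = SplitSpec(
        test_size=12, test_unit="image", validation_size=9,
        n_per_label_train=5, n_selections=2, n_repeats=2,
    )
    cache = {}
    report = run_protocol(data, spec, base_seed=9, feature_cache=cache)
    return data, spec, cache, report


class TestRunProtocol:

    def test_trial_count_is_selections_times_repeats(self, small_run):
        _, _, _, report = small_run
        assert report.n_trials == 4
        assert len(report.per_trial) == 4

    def test_averages_equal_mean_of_trials(self, small_run):
        _, _, _, report = small_run
        assert np.isclose(
            report.concordance, np.mean([t["concordance"] for t in report.per_trial])
        )
        assert np.allclose(
            report.distribution["PA"],
            np.mean([t["distribution"]["PA"] for t in report.per_trial], axis=0),
        )

    def test_confusion_consistency(self, small_run):
        _, _, _, report = small_run
        for t in report.per_trial:
            mat = t["confusion"]
            assert np.isclose(
                np.trace(mat) / mat.sum() * 100.0, t["concordance"]
            )

    def test_single_trial_report_equals_that_trial(self, default_config):
        data = generate_dataset({"A": 12, "B": 12, "C": 12}, default_config, seed=52)
        spec = SplitSpec(
            test_size=9, test_unit="image", validation_size=6,
            n_per_label_train=4, n_selections=1, n_repeats=1,
        )
        report = run_protocol(data, spec, base_seed=3, feature_cache={})
        assert report.n_trials == 1
        assert report.concordance == report.per_trial[0]["concordance"]

    def test_same_seed_reproduces_report(self, small_run):
        data, spec, cache, report = small_run
        report2 = run_protocol(data, spec, base_seed=9, feature_cache=cache)
        assert [t["concordance"] for t in report.per_trial] == [
            t["concordance"] for t in report2.per_trial
        ]

    def test_no_image_in_more_than_one_role(self, dataset):
        spec = SplitSpec(test_size=84, test_unit="cell", validation_size=40,
                         n_per_label_train=10)
        test, pool = split_dataset(dataset, spec, seed=4)
        val, train = select_validation_and_training(pool, 40, seed=4)
        ids = [set(map(id, s)) for s in (test, val, train)]
        assert ids[0].isdisjoint(ids[1]) and ids[0].isdisjoint(ids[2]) and ids[1].isdisjoint(ids[2])


def test_trial_seed_is_stable_and_distinct():
    s1 = trial_seed(7, 0, 0)
    assert s1 == trial_seed(7, 0, 0)
    seeds = {trial_seed(7, i, j) for i in range(5) for j in range(5)}
    assert len(seeds) == 25
    assert all(0 <= s < 2**31 for s in seeds)
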