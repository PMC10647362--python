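"""Group partitioning, configuration enumeration, retention and voting."""

import math
from collections import Counter

import numpy as np
import pytest

from ffrisk.cohort import CLASS_COLUMN, HIGH, LOW
from ffrisk.ensemble import (
    BaseModelSpec,
    EmptyEnsembleError,
    FilterPolicy,
    apply_filter,
    build_ensemble,
    enumerate_configurations,
    evaluate_on_heldout,
    partition_groups,
    predict_cohort,
    predict_sample,
    train_base_model,
    load_ensemble,
    save_ensemble,
)
from ffrisk.preprocessing import design_matrix, preprocess
from ffrisk.synthetic import GeneratorConfig, generate_cohort


def study_labels():
    """Class labels mirroring the study cohort: 123 low, 58 high."""
    return [LOW] * 123 + [HIGH] * 58


class TestPartition:
    def test_study_sized_partition_sizes_and_coverage(self):
        part = partition_groups(study_labels(), n_groups=20, seed=0)
        sizes = sorted(len(g) for g in part.groups)
        assert sizes == [9] * 19 + [10]  # 181 = 19 x 9 + 10
        labels = study_labels()
        for g in part.groups:
            classes = {labels[i] for i in g}
            assert classes == {LOW, HIGH}
        flat = sorted(i for g in part.groups for i in g)
        assert flat == list(range(181))  # disjoint and covering

    def test_even_split(self):
        part = partition_groups([LOW] * 20 + [HIGH] * 20, n_groups=4, seed=1)
        assert [len(g) for g in part.groups] == [10, 10, 10, 10]

    def test_single_class_coverage_unsatisfiable(self):
        with pytest.raises(ValueError, match="high"):
            partition_groups([LOW] * 8 + [HIGH] * 2, n_groups=4, seed=0)

    def test_deterministic_given_seed(self):
        a = partition_groups(study_labels(), 20, seed=42)
        b = partition_groups(study_labels(), 20, seed=42)
        c = partition_groups(study_labels(), 20, seed=43)
        assert a.groups == b.groups
        assert a.groups != c.groups


class TestEnumerate:
    def test_study_configuration_count(self):
        configs = enumerate_configurations(20, [1, 2, 3, 4])
        by_size = Counter(c.heldout_size for c in configs)
        assert by_size == {1: 20, 2: 190, 3: 1140, 4: 4845}
        assert len(configs) == 6195
        assert len({c.test_group_ids for c in configs}) == 6195  # no duplicates

    def test_small_cases(self):
        assert len(enumerate_configurations(4, [1, 2])) == 10
        assert len(enumerate_configurations(20, [1])) == 20

    def test_train_test_partition_each_config(self):
        for cfg in enumerate_configurations(5, [2]):
            assert set(cfg.train_group_ids) | set(cfg.test_group_ids) == set(range(5))
            assert not set(cfg.train_group_ids) & set(cfg.test_group_ids)

    def test_lexicographic_order(self):
        tests = [c.test_group_ids for c in enumerate_configurations(4, [2])]
        assert tests == sorted(tests)

    def test_oversized_heldout_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configurations(4, [4])


class TestBaseModel:
    def test_separable_toy_set_is_memorised(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = [LOW] * 10 + [HIGH] * 10
        clf = train_base_model(X, y, BaseModelSpec(n_trees=10, seed=0))
        assert evaluate_on_heldout(clf, X, y) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 4))
        y = [LOW, HIGH] * 15
        probe = rng.random((10, 4))
        a = train_base_model(X, y, BaseModelSpec(50, seed=7)).predict(probe)
        b = train_base_model(X, y, BaseModelSpec(50, seed=7)).predict(probe)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_base_model(np.zeros((5, 2)), [LOW] * 5, BaseModelSpec())

    def test_heldout_accuracy_is_correct_fraction(self):
        class Fixed:
            def predict(self, X):
                return np.array([LOW] * len(X), dtype=object)

        y = [LOW] * 6 + [HIGH] * 3
        assert evaluate_on_heldout(Fixed(), np.zeros((9, 1)), y) == pytest.approx(6 / 9)


class TestFilter:
    @pytest.mark.parametrize(
        "acc, size, keep",
        [
            (6 / 9, 1, True),    # the 6-of-9 rule
            (5 / 9, 1, False),
            (7 / 10, 1, True),   # 10-sample group needs 7 correct
            (6 / 10, 1, False),
            (0.75, 2, True),
            (0.74, 3, False),
            (0.80, 4, True),     # inclusive comparison at the threshold
            (0.79, 4, False),
        ],
    )
    def test_retention_thresholds(self, acc, size, keep):
        assert apply_filter(acc, size, FilterPolicy()) is keep

    def test_exclusive_mode(self):
        policy = FilterPolicy(inclusive=False)
        assert apply_filter(0.75, 2, policy) is False
        assert apply_filter(0.7501, 2, policy) is True

    def test_undefined_size_rejected(self):
        with pytest.raises(ValueError, match="size 9"):
            apply_filter(0.9, 9, FilterPolicy())


class TestBuildEnsemble:
    def test_members_subset_of_candidates_and_pass_filter(self, small_ensemble):
        configs = enumerate_configurations(6, [1, 2])
        valid = {c.test_group_ids for c in configs}
        assert 1 <= len(small_ensemble) <= len(configs)
        for m in small_ensemble.members:
            assert m.configuration.test_group_ids in valid
            assert apply_filter(
                m.heldout_accuracy, m.configuration.heldout_size, small_ensemble.policy
            )

    def test_vacuous_filter_retains_everything(self, small_clean_cohort):
        policy = FilterPolicy({1: 1e-9})
        ens = build_ensemble(
            small_clean_cohort, n_groups=4, heldout_sizes=(1,),
            spec=BaseModelSpec(n_trees=5), policy=policy, seed=0,
        )
        assert len(ens) == 4

    def test_unsatisfiable_filter_raises_empty_ensemble(self, small_clean_cohort):
        policy = FilterPolicy({1: 1.0}, inclusive=False)
        with pytest.raises(EmptyEnsembleError) as err:
            build_ensemble(
                small_clean_cohort, n_groups=4, heldout_sizes=(1,),
                spec=BaseModelSpec(n_trees=5), policy=policy, seed=0,
            )
        assert err.value.diagnostics[1]["candidates"] == 4

    def test_determinism_across_builds(self, small_clean_cohort):
        kw = dict(n_groups=5, heldout_sizes=(1,), spec=BaseModelSpec(n_trees=5), seed=9)
        a = build_ensemble(small_clean_cohort, **kw)
        b = build_ensemble(small_clean_cohort, **kw)
        assert len(a) == len(b)
        assert [m.heldout_accuracy for m in a.members] == [m.heldout_accuracy for m in b.members]
        assert predict_cohort(a, small_clean_cohort) == predict_cohort(b, small_clean_cohort)

    def test_build_log_counts(self, small_ensemble):
        log = small_ensemble.build_log
        assert log[1]["candidates"] == 6 and log[2]["candidates"] == 15
        assert sum(v["retained"] for v in log.values()) == len(small_ensemble)


class TestVoting:
    def test_predict_matches_brute_force_tally(self, small_ensemble, small_clean_cohort):
        X, _ = design_matrix(small_clean_cohort)
        preds = predict_cohort(small_ensemble, small_clean_cohort)
        for i in range(len(X)):
            votes = Counter(
                m.classifier.predict(X[i : i + 1])[0] for m in small_ensemble.members
            )
            if votes[HIGH] >= votes[LOW]:  # tie resolves to high risk
                assert preds[i] == HIGH
            else:
                assert preds[i] == LOW
            assert preds[i] == predict_sample(small_ensemble, X[i])

    def test_tie_breaks_high(self, small_ensemble):
        import copy

        ens = copy.copy(small_ensemble)

        class Const:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.array([self.label] * len(X), dtype=object)

        m0 = copy.copy(small_ensemble.members[0])
        m1 = copy.copy(small_ensemble.members[0])
        m0.classifier, m1.classifier = Const(HIGH), Const(LOW)
        ens.members = [m0, m1]
        x = np.zeros(len(ens.feature_names))
        assert predict_sample(ens, x) == HIGH
        ens.members = [m1]
        assert predict_sample(ens, x) == LOW

    def test_predict_cohort_cardinality_and_empty(self, small_ensemble, small_clean_cohort):
        preds = predict_cohort(small_ensemble, small_clean_cohort)
        assert len(preds) == len(small_clean_cohort)
        empty = small_clean_cohort.copy()
        empty.data = empty.data.iloc[:0]
        assert predict_cohort(small_ensemble, empty) == []


class TestRoundTripArchive:
    def test_save_load_preserves_predictions(self, tmp_path, small_ensemble, small_clean_cohort):
        path = save_ensemble(small_ensemble, tmp_path / "ens.joblib")
        back = load_ensemble(path)
        assert len(back) == len(small_ensemble)
        assert predict_cohort(back, small_clean_cohort) == predict_cohort(
            small_ensemble, small_clean_cohort
        )


class TestSignalRecovery:
    def test_strong_signal_beats_baseline(self):
        raw = generate_cohort(
            GeneratorConfig(n_patients=80, labeled_fraction=1.0, missing_rate=0.0,
                            text_rate=0.0, signal_strength=2.0, seed=21)
        )
        clean, _ = preprocess(raw)
        ens = build_ensemble(clean, n_groups=8, heldout_sizes=(1, 2),
                             spec=BaseModelSpec(n_trees=10), seed=2)
        fresh = generate_cohort(
            GeneratorConfig(n_patients=80, labeled_fraction=1.0, missing_rate=0.0,
                            text_rate=0.0, signal_strength=2.0, seed=22)
        )
        fclean, _ = preprocess(fresh)
        truth = [r.risk_class for r in fclean.records()]
        preds = predict_cohort(ens, fclean)
        acc = np.mean([p == t for p, t in zip(preds, truth)])
        baseline = truth.count(LOW) / len(truth)
        assert acc > baseline
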