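import numpy as np
import pandas as pd
import pytest

import phasicpain as pp
from phasicpain.evaluation import (
    TASKS,
    TaskSpec,
    compare_predictors,
    make_folds,
    observer_subset,
    trivial_baseline,
)
from phasicpain.models import ArchitectureSpec
from phasicpain.synthetic import SyntheticDataset


def _bare_dataset(manifest):
    return SyntheticDataset(manifest=manifest, samples={})


class TestTaskSpecs:
    def test_seven_tasks_cover_expected_sizes(self):
        sizes = sorted(t.n_classes for t in TASKS.values())
        assert sizes == [3, 3, 3, 3, 5, 5, 7]
        assert all("B" in t.class_list for t in TASKS.values())

    def test_baseline_required(self):
        with pytest.raises(ValueError):
            TaskSpec("nope", ("E1", "E3"))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("nope", ("B", "E1", "E1"))


class TestMakeFolds:
    def test_balanced_subjects_split_evenly(self):
        ds = pp.generate_dataset(10, 2, seed=0)
        plan = make_folds(ds.manifest, k=5, seed=0)
        sizes = [len(plan.fold_subjects(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]
        # balanced per-subject classes => per-fold proportions equal global
        merged = ds.manifest.assign(
            fold=ds.manifest["subject_id"].map(plan.assignment)
        )
        props = merged.groupby("fold")["class"].value_counts(normalize=True)
        assert np.allclose(props, 1 / 7)

    def test_subject_disjoint_for_uneven_cohorts(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(17):
            for i in range(rng.integers(3, 15)):
                cls = ["B", "H1", "E3"][rng.integers(3)]
                rows.append({"sample_id": f"s{s}_{i}", "subject_id": s,
                             "class": cls, "au_csv": "", "frames_dir": ""})
        manifest = pd.DataFrame(rows)
        plan = make_folds(manifest, k=5, seed=1)
        assigned = [s for f in range(5) for s in plan.fold_subjects(f)]
        assert sorted(assigned) == list(range(17))

    def test_too_few_subjects_rejected(self):
        ds = pp.generate_dataset(4, 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(ds.manifest, k=5)

    def test_deterministic(self):
        ds = pp.generate_dataset(8, 1, seed=2)
        a = make_folds(ds.manifest, k=4, seed=5)
        b = make_folds(ds.manifest, k=4, seed=5)
        assert a.assignment == b.assignment


class TestTrivialBaseline:
    def test_balanced_seven_class_is_one_seventh(self):
        ds = pp.generate_dataset(10, 2, seed=1)
        res = trivial_baseline("7class", ds, seed=0)
        assert res.pooled_accuracy == pytest.approx(1 / 7)

    def test_balanced_three_class_is_one_third(self):
        ds = pp.generate_dataset(10, 2, seed=1)
        res = trivial_baseline("3class_E_low", ds, seed=0)
        assert res.pooled_accuracy == pytest.approx(1 / 3)

    def test_majority_rate_on_skewed_binary(self):
        rows = []
        for s in range(10):
            for i in range(3):
                rows.append({"sample_id": f"s{s}_b{i}", "subject_id": s,
                             "class": "B", "au_csv": "", "frames_dir": ""})
            for i in range(2):
                rows.append({"sample_id": f"s{s}_h{i}", "subject_id": s,
                             "class": "H3", "au_csv": "", "frames_dir": ""})
        ds = _bare_dataset(pd.DataFrame(rows))
        res = trivial_baseline(TaskSpec("binary", ("B", "H3")), ds, seed=0)
        assert res.pooled_accuracy == pytest.approx(0.6)

    def test_confusion_rows_match_class_counts(self):
        ds = pp.generate_dataset(10, 2, seed=1)
        res = trivial_baseline("7class", ds, seed=0)
        assert (res.confusion.sum(axis=1) == 20).all()


class TestRunCV:
    def test_strong_signal_beats_chance_and_stays_disjoint(self, strong_dataset):
        arch = ArchitectureSpec(kind="rfc_fad", n_trees=60)
        res = pp.run_cv("7class", arch, strong_dataset, seed=0)
        assert res.pooled_accuracy > 2 / 7
        # every subject's samples fall in exactly one fold
        per_subject = res.predictions.groupby("subject_id")["fold"].nunique()
        assert (per_subject == 1).all()
        assert len(res.fold_accuracies) == 5
        assert res.predictions.shape[0] == len(strong_dataset)

    def test_missing_task_class_rejected(self):
        rows = [{"sample_id": f"s{i}", "subject_id": i, "class": "B",
                 "au_csv": "", "frames_dir": ""} for i in range(6)]
        ds = _bare_dataset(pd.DataFrame(rows))
        arch = ArchitectureSpec(kind="rfc_fad", n_trees=5)
        with pytest.raises(ValueError, match="lacks"):
            pp.run_cv("7class", arch, ds, seed=0)

    def test_forest_weighting_runs_and_keeps_test_untouched(self, strong_dataset):
        arch = ArchitectureSpec(kind="rfc_fad", n_trees=30)
        base, weighted, plans = pp.weighting_experiment(
            "3class_E_low", arch, strong_dataset, seed=0)
        assert len(plans) == 5
        assert not weighted.predictions["sample_id"].duplicated().any()
        assert set(weighted.predictions["sample_id"]) == set(
            base.predictions["sample_id"])


class TestObserverSubset:
    def test_ten_percent_of_balanced_cohort(self):
        ds = pp.generate_dataset(10, 4, seed=0)  # 280 samples, 40 per class
        ids = observer_subset(ds.manifest, fraction=0.10, seed=0)
        assert len(ids) == 28
        classes = ds.manifest.set_index("sample_id").loc[ids, "class"]
        assert (classes.value_counts() == 4).all()

    def test_full_fraction_returns_everything(self):
        ds = pp.generate_dataset(5, 2, seed=0)
        ids = observer_subset(ds.manifest, fraction=1.0, seed=0)
        assert sorted(ids) == sorted(ds.manifest["sample_id"])

    def test_seeds_change_members_not_counts(self):
        ds = pp.generate_dataset(10, 4, seed=0)
        a = observer_subset(ds.manifest, 0.10, seed=1)
        b = observer_subset(ds.manifest, 0.10, seed=2)
        assert len(a) == len(b)
        assert set(a) != set(b)

    def test_bad_fraction_rejected(self):
        ds = pp.generate_dataset(5, 1, seed=0)
        with pytest.raises(ValueError):
            observer_subset(ds.manifest, 0.0)


@pytest.fixture(scope="module")
def setup():
    ds = pp.generate_dataset(30, 1, seed=4)
    truth = dict(zip(ds.manifest["sample_id"], ds.manifest["class"]))
    ids = list(ds.manifest["sample_id"])
    return ds.manifest, truth, ids


class TestComparePredictors:
    def test_identical_predictors_p_one(self, setup):
        manifest, truth, ids = setup
        res = compare_predictors(truth, dict(truth), truth, ids, manifest)
        assert res.p_value == 1.0
        assert res.accuracy_a == res.accuracy_b == 1.0

    def test_single_subject_perturbation(self, setup):
        manifest, truth, ids = setup
        flipped = dict(truth)
        subj0 = manifest[manifest["subject_id"] == 0]["sample_id"]
        for sid in subj0:
            flipped[sid] = "E3" if truth[sid] != "E3" else "B"
        res = compare_predictors(truth, flipped, truth, ids, manifest)
        assert res.accuracy_a - res.accuracy_b == pytest.approx(len(subj0) / len(ids))

    def test_perfect_vs_chance_is_significant(self, setup):
        manifest, truth, ids = setup
        rng = np.random.default_rng(0)
        chance = {sid: pp.CLASSES[rng.integers(7)] for sid in ids}
        res = compare_predictors(truth, chance, truth, ids, manifest)
        assert res.p_value < 0.01
        assert res.mcnemar_p < 0.01

    def test_too_few_subjects_rejected(self, setup):
        manifest, truth, ids = setup
        two = list(manifest[manifest["subject_id"] < 2]["sample_id"])
        with pytest.raises(ValueError, match="3 subjects"):
            compare_predictors(truth, truth, truth, two, manifest)

    def test_uncovered_ids_rejected(self, setup):
        manifest, truth, ids = setup
        partial = {k: v for k, v in truth.items() if k != ids[0]}
        with pytest.raises(ValueError, match="cover"):
            compare_predictors(partial, truth, truth, ids, manifest)
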