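"""Experiment harness: tasks, folds, cross-validation and comparisons.

Defines the seven classification tasks (one 7-class, two 5-class, four
3-class), subject-disjoint stratified 5-fold cross-validation, the trivial
majority-class baseline, the 10% observer subset draw, and the paired
t-test comparison between two predictors (e.g. a model and a human
observer label file).

No subject's samples ever appear on both sides of a fold; the harness
asserts this on every run.  When duplication weighting is enabled it is
applied to training folds only, and the weighted model is scored by a model
trained on the same training fold (never on test data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import fad as fad_mod
from . import models as models_mod
from .constants import CLASS_TO_INDEX, CLASSES
from .preprocess import encode_prediction, spatiotemporal_from_sample
from .weighting import apply_weighting, guard_test_integrity, score_training_samples

__all__ = [
    "TaskSpec",
    "TASKS",
    "FoldPlan",
    "EvalResult",
    "ComparisonResult",
    "make_folds",
    "run_cv",
    "weighting_experiment",
    "trivial_baseline",
    "observer_subset",
    "compare_predictors",
]


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: a named ordered subset of the 7 classes."""

    name: str
    class_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if "B" not in self.class_list:
            raise ValueError("every task includes the baseline class B")
        if len(set(self.class_list)) != len(self.class_list):
            raise ValueError("task classes must be unique")
        unknown = set(self.class_list) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class codes {sorted(unknown)}")

    @property
    def n_classes(self) -> int:
        return len(self.class_list)


#: The seven evaluated tasks: full 7-class, two 5-class subsets dropping one
#: of the lower intensities per modality, and four single-modality 3-class
#: subsets.
TASKS: dict[str, TaskSpec] = {
    t.name: t
    for t in [
        TaskSpec("7class", ("B", "H1", "H2", "H3", "E1", "E2", "E3")),
        TaskSpec("5class_low", ("B", "E1", "H1", "E3", "H3")),
        TaskSpec("5class_med", ("B", "E2", "H2", "E3", "H3")),
        TaskSpec("3class_E_low", ("B", "E1", "E3")),
        TaskSpec("3class_E_med", ("B", "E2", "E3")),
        TaskSpec("3class_H_low", ("B", "H1", "H3")),
        TaskSpec("3class_H_med", ("B", "H2", "H3")),
    ]
}


@dataclass(frozen=True)
class FoldPlan:
    """Subject-disjoint fold assignment: subject id -> fold index."""

    k: int
    assignment: dict[int, int]

    def fold_subjects(self, fold: int) -> list[int]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


@dataclass
class EvalResult:
    """Cross-validation outcome for one (task, model) combination."""

    task: str
    model: str
    fold_accuracies: list[float]
    pooled_accuracy: float
    confusion: pd.DataFrame
    predictions: pd.DataFrame  # sample_id, subject_id, fold, true, pred
    p_value: float | None = None

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class ComparisonResult:
    accuracy_a: float
    accuracy_b: float
    p_value: float
    mcnemar_p: float
    n_subjects: int


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified assignment of whole subjects to ``k`` folds.

    Subjects never straddle folds, and each fold ends up with roughly the
    same class proportions as the full manifest (grouped stratification).
    Deterministic given the seed.
    """
    subjects = manifest["subject_id"].unique()
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, "
                         f"got {len(subjects)}")
    from sklearn.model_selection import StratifiedGroupKFold

    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    y = manifest["class"].to_numpy()
    groups = manifest["subject_id"].to_numpy()
    assignment: dict[int, int] = {}
    for fold, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(manifest)), y, groups)
    ):
        for subject in np.unique(groups[test_idx]):
            assignment[int(subject)] = fold
    return FoldPlan(k=k, assignment=assignment)


def _split_ids(manifest: pd.DataFrame, plan: FoldPlan, fold: int):
    in_fold = manifest["subject_id"].map(plan.assignment) == fold
    test = manifest.loc[in_fold]
    train = manifest.loc[~in_fold]
    overlap = set(train["subject_id"]) & set(test["subject_id"])
    if overlap:
        raise AssertionError(f"subjects in both train and test: {sorted(overlap)}")
    return list(train["sample_id"]), list(test["sample_id"])


# ---------------------------------------------------------------------------
# model inputs
# ---------------------------------------------------------------------------

class _InputCache:
    """Per-dataset caches of the expensive model inputs."""

    def __init__(self, dataset, arch: models_mod.ArchitectureSpec,
                 smoothing_window: int = 5, render_size: int | None = None):
        self.dataset = dataset
        self.arch = arch
        self.smoothing_window = smoothing_window
        self.render_size = render_size
        self._fad: pd.DataFrame | None = None
        self._st: dict[str, np.ndarray] = {}

    @property
    def fad(self) -> pd.DataFrame:
        if self._fad is None:
            self._fad = fad_mod.feature_matrix(
                self.dataset.samples.values(), self.smoothing_window
            )
        return self._fad

    def st_image(self, sample_id: str) -> np.ndarray:
        if sample_id not in self._st:
            self._st[sample_id] = spatiotemporal_from_sample(
                self.dataset.sample(sample_id),
                size=self.arch.image_size,
                render_size=self.render_size,
            )
        return self._st[sample_id]

    def st_stack(self, ids: list[str]) -> np.ndarray:
        return np.stack([self.st_image(sid) for sid in ids])


def _labels_of(manifest: pd.DataFrame, ids: list[str]) -> list[str]:
    lookup = dict(zip(manifest["sample_id"], manifest["class"]))
    return [lookup[sid] for sid in ids]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fit_fold(task, arch, cache, manifest, train_ids, test_ids, seed,
              weighting, threshold, prediction_trees, score_reading):
    """Fit on one training fold; returns test scores without weighting and,
    if requested, with weighting (plus the plan)."""
    y_train = _labels_of(manifest, train_ids)
    if len(set(y_train)) < task.n_classes:
        warnings.warn(
            f"training fold is missing {task.n_classes - len(set(y_train))} "
            "task classes; fold kept", stacklevel=2,
        )

    if arch.kind in models_mod.FOREST_KINDS:
        if arch.kind == "rfc_fad":
            x_all = cache.fad
            x_train = x_all.loc[train_ids].to_numpy()
            x_test = x_all.loc[test_ids].to_numpy()
        else:  # rfc_bl: flattened spatio-temporal pixels
            x_train = cache.st_stack(train_ids).reshape(len(train_ids), -1)
            x_test = cache.st_stack(test_ids).reshape(len(test_ids), -1)
        model = models_mod.train_forest(
            x_train, y_train, n_trees=arch.n_trees, seed=seed,
            spec=arch, class_list=task.class_list,
        )
        base_scores = model.predict(x_test)
        if not weighting:
            return base_scores, None, None
        scores = score_training_samples(model, x_train, y_train, train_ids,
                                        score=score_reading)
        weighted_ids, plan = apply_weighting(train_ids, scores, threshold, seed)
        guard_test_integrity(plan, test_ids)
        row = {sid: i for i, sid in enumerate(train_ids)}
        idx = [row[sid] for sid in weighted_ids]
        weighted = models_mod.train_forest(
            x_train[idx], [y_train[i] for i in idx], n_trees=arch.n_trees,
            seed=seed, spec=arch, class_list=task.class_list,
        )
        return base_scores, weighted.predict(x_test), plan

    # CNN families: an inner forest supplies the prediction-image branch
    # input, trained on this fold's training data only.  Training samples
    # get the forest's *out-of-bag* prediction (an in-sample prediction
    # would echo the label and let the network shortcut past the images);
    # test samples get ordinary out-of-sample predictions.
    inner = models_mod.train_forest(
        cache.fad.loc[train_ids].to_numpy(), y_train,
        n_trees=prediction_trees, seed=seed, class_list=task.class_list,
        oob=True,
    )

    def to_images(scores):
        hard = models_mod.hard_labels(scores, task.class_list)
        return np.stack([encode_prediction(CLASS_TO_INDEX[c]) for c in hard])

    x_img_train = cache.st_stack(train_ids)
    x_img_test = cache.st_stack(test_ids)
    x_pred_train = to_images(models_mod.oob_scores(inner))
    x_pred_test = to_images(inner.predict(cache.fad.loc[test_ids].to_numpy()))

    model = models_mod.train_cnn(
        arch, (x_img_train, x_pred_train), y_train, seed=seed,
        class_list=task.class_list,
    )
    base_scores = model.predict((x_img_test, x_pred_test))
    if not weighting:
        return base_scores, None, None

    scores = score_training_samples(
        model, (x_img_train, x_pred_train), y_train, train_ids,
        score=score_reading,
    )
    weighted_ids, plan = apply_weighting(train_ids, scores, threshold, seed)
    guard_test_integrity(plan, test_ids)
    row = {sid: i for i, sid in enumerate(train_ids)}
    idx = np.array([row[sid] for sid in weighted_ids])
    weighted = models_mod.train_cnn(
        arch, (x_img_train[idx], x_pred_train[idx]),
        [y_train[i] for i in idx], seed=seed, class_list=task.class_list,
    )
    return base_scores, weighted.predict((x_img_test, x_pred_test)), plan


def _collect(task, model_name, manifest, plan, fold_rows) -> EvalResult:
    predictions = pd.concat(fold_rows, ignore_index=True)
    fold_accs = [
        float((g["true"] == g["pred"]).mean())
        for _, g in predictions.groupby("fold")
    ]
    pooled = float((predictions["true"] == predictions["pred"]).mean())
    confusion = (
        predictions.groupby(["true", "pred"]).size().unstack(fill_value=0)
        .reindex(index=task.class_list, columns=task.class_list, fill_value=0)
    )
    return EvalResult(
        task=task.name, model=model_name, fold_accuracies=fold_accs,
        pooled_accuracy=pooled, confusion=confusion, predictions=predictions,
    )


def run_cv(task: TaskSpec | str, arch: models_mod.ArchitectureSpec, dataset,
           seed: int = 0, k: int = 5, weighting: bool = False,
           threshold: float = 0.3, prediction_trees: int = 100,
           score_reading: str = "true_class",
           render_size: int | None = None) -> EvalResult:
    """Subject-disjoint stratified k-fold cross-validation of one model.

    Per fold: fit on the training subjects (with duplication weighting
    applied to the training data only, if enabled), predict the held-out
    subjects, and pool the predictions.  The headline accuracy is pooled
    over the concatenated fold predictions; per-fold accuracies are kept
    alongside.
    """
    without, with_w, _ = _run_cv_impl(
        task, arch, dataset, seed, k, weighting, threshold, prediction_trees,
        score_reading, render_size,
    )
    return with_w if weighting else without


def weighting_experiment(task, arch, dataset, seed: int = 0, k: int = 5,
                         threshold: float = 0.3, prediction_trees: int = 100,
                         score_reading: str = "true_class",
                         render_size: int | None = None):
    """Matched contrast of one model with and without duplication weighting.

    The unweighted model of each training fold doubles as the scoring model
    for the weighted arm, so both arms share fold plans, seeds and inputs
    and differ only in the duplication.
    Returns ``(result_without, result_with, plans)``.
    """
    return _run_cv_impl(task, arch, dataset, seed, k, True, threshold,
                        prediction_trees, score_reading, render_size)


def _run_cv_impl(task, arch, dataset, seed, k, weighting, threshold,
                 prediction_trees, score_reading, render_size):
    if isinstance(task, str):
        task = TASKS[task]
    manifest = dataset.manifest
    present = set(manifest["class"])
    missing = set(task.class_list) - present
    if missing:
        raise ValueError(f"dataset lacks task classes {sorted(missing)}")
    manifest = manifest[manifest["class"].isin(task.class_list)].reset_index(drop=True)

    plan = make_folds(manifest, k=k, seed=seed)
    cache = _InputCache(dataset, arch, render_size=render_size)
    base_rows, weighted_rows, plans = [], [], []
    for fold in range(k):
        train_ids, test_ids = _split_ids(manifest, plan, fold)
        base_scores, w_scores, wplan = _fit_fold(
            task, arch, cache, manifest, train_ids, test_ids,
            seed + fold, weighting, threshold, prediction_trees, score_reading,
        )
        y_test = _labels_of(manifest, test_ids)
        subj = dict(zip(manifest["sample_id"], manifest["subject_id"]))

        def rows(scores):
            return pd.DataFrame({
                "sample_id": test_ids,
                "subject_id": [subj[sid] for sid in test_ids],
                "fold": fold,
                "true": y_test,
                "pred": models_mod.hard_labels(scores, task.class_list),
            })

        base_rows.append(rows(base_scores))
        if w_scores is not None:
            weighted_rows.append(rows(w_scores))
            plans.append(wplan)

    name = arch.kind if arch.mtl_variant == "none" else f"{arch.kind}+{arch.mtl_variant}"
    base = _collect(task, name, manifest, plan, base_rows)
    weighted = (
        _collect(task, name + "*", manifest, plan, weighted_rows)
        if weighted_rows else None
    )
    return base, weighted, plans


# ---------------------------------------------------------------------------
# baselines, observer subset, comparisons
# ---------------------------------------------------------------------------

def trivial_baseline(task: TaskSpec | str, dataset, seed: int = 0,
                     k: int = 5) -> EvalResult:
    """Chance-level reference: predict the training fold's majority class
    (lowest class index on ties) for every test sample."""
    if isinstance(task, str):
        task = TASKS[task]
    manifest = dataset.manifest
    manifest = manifest[manifest["class"].isin(task.class_list)].reset_index(drop=True)
    plan = make_folds(manifest, k=k, seed=seed)
    fold_rows = []
    for fold in range(k):
        train_ids, test_ids = _split_ids(manifest, plan, fold)
        y_train = pd.Series(_labels_of(manifest, train_ids))
        counts = y_train.value_counts()
        majority = min(
            counts[counts == counts.max()].index, key=task.class_list.index
        )
        subj = dict(zip(manifest["sample_id"], manifest["subject_id"]))
        fold_rows.append(pd.DataFrame({
            "sample_id": test_ids,
            "subject_id": [subj[sid] for sid in test_ids],
            "fold": fold,
            "true": _labels_of(manifest, test_ids),
            "pred": majority,
        }))
    return _collect(task, "trivial", manifest, plan, fold_rows)


def observer_subset(manifest: pd.DataFrame, fraction: float = 0.10,
                    seed: int = 0) -> list[str]:
    """Draw the observer-labelling subset: a class-balanced random fraction.

    Each class contributes ``round(fraction * n_class)`` samples, spread as
    evenly as possible across that class's subjects (one id per subject
    cell in seeded round-robin order), so no subject dominates the subset.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    all_subjects = set(manifest["subject_id"])
    chosen: list[str] = []
    for cls, group in manifest.groupby("class"):
        quota = int(np.floor(fraction * len(group) + 0.5))
        missing = all_subjects - set(group["subject_id"])
        if missing:
            warnings.warn(
                f"class {cls}: subjects {sorted(missing)[:5]} have no samples; "
                "their cells are skipped", stacklevel=2,
            )
        cells = []
        for _, cell in group.groupby("subject_id"):
            ids = cell["sample_id"].to_numpy()
            cells.append(list(ids[rng.permutation(len(ids))]))
        cells = [cells[i] for i in rng.permutation(len(cells))]
        picked: list[str] = []
        while len(picked) < quota:
            progressed = False
            for cell in cells:
                if cell and len(picked) < quota:
                    picked.append(cell.pop())
                    progressed = True
            if not progressed:
                break
        chosen.extend(picked)
    return chosen


def _as_label_dict(pred) -> dict[str, str]:
    if hasattr(pred, "as_dict"):
        return pred.as_dict()
    if isinstance(pred, pd.DataFrame):
        col = "pred" if "pred" in pred.columns else "class"
        return dict(zip(pred["sample_id"], pred[col]))
    return dict(pred)


def compare_predictors(pred_a, pred_b, ground_truth, restrict_to: list[str],
                       manifest: pd.DataFrame) -> ComparisonResult:
    """Compare two predictors on a common sample subset.

    The pairing unit is per-subject accuracy (subjects are the exchangeable
    unit under subject-disjoint cross-validation): a two-sided paired
    t-test across subjects gives the headline p-value, with a per-sample
    McNemar test reported as a secondary check.
    """
    a, b = _as_label_dict(pred_a), _as_label_dict(pred_b)
    truth = _as_label_dict(ground_truth)
    missing = [sid for sid in restrict_to if sid not in a or sid not in b]
    if missing:
        raise ValueError(f"predictors do not cover {len(missing)} requested ids, "
                         f"e.g. {missing[:5]}")
    subj = dict(zip(manifest["sample_id"], manifest["subject_id"]))
    frame = pd.DataFrame({
        "subject_id": [subj[sid] for sid in restrict_to],
        "hit_a": [a[sid] == truth[sid] for sid in restrict_to],
        "hit_b": [b[sid] == truth[sid] for sid in restrict_to],
    })
    per_subject = frame.groupby("subject_id")[["hit_a", "hit_b"]].mean()
    if len(per_subject) < 3:
        raise ValueError("need at least 3 subjects for a paired comparison")
    diffs = per_subject["hit_a"] - per_subject["hit_b"]
    if np.allclose(diffs, 0.0):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(per_subject["hit_a"],
                                        per_subject["hit_b"]).pvalue)

    from statsmodels.stats.contingency_tables import mcnemar

    table = pd.crosstab(frame["hit_a"], frame["hit_b"]).reindex(
        index=[False, True], columns=[False, True], fill_value=0
    )
    mcn = mcnemar(table.to_numpy(), exact=True)
    return ComparisonResult(
        accuracy_a=float(frame["hit_a"].mean()),
        accuracy_b=float(frame["hit_b"].mean()),
        p_value=p_value,
        mcnemar_p=float(mcn.pvalue),
        n_subjects=len(per_subject),
    )
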