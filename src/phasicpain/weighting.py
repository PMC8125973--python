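"""Score-threshold sample-duplication weighting.

Many pain samples carry no observable facial response and act as label
noise.  This weighting upweights the learnable samples instead of mining
the hard ones: after training a model on the training fold, every training
sample whose classification score exceeds a threshold (default 0.3) is
duplicated once.  Test data is never touched; an integrity guard asserts
that no test set contains duplicates.

The "classification score" defaults to the model's softmax probability of
the ground-truth class (the goal is upweighting samples whose true pain
reaction was learned); ``score="max_prob"`` switches to the top-1
probability reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightingPlan",
    "IntegrityError",
    "score_training_samples",
    "apply_weighting",
    "guard_test_integrity",
]


class IntegrityError(RuntimeError):
    """Test-set comparability is violated (duplicated evaluation samples)."""


@dataclass
class WeightingPlan:
    """Record of one duplication pass over a training fold."""

    threshold: float
    score_source: str
    duplicated_ids: list[str]
    n_before: int
    n_after: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "score_source": self.score_source,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "duplicated_ids": list(self.duplicated_ids),
        }


def score_training_samples(model, train_inputs, train_labels, sample_ids,
                           score: str = "true_class") -> dict[str, float]:
    """Score each training sample with the model trained on that same data.

    ``score="true_class"`` (default) takes the probability assigned to the
    ground-truth class; ``score="max_prob"`` takes the largest probability
    regardless of correctness.
    """
    if score not in ("true_class", "max_prob"):
        raise ValueError(f"unknown score reading {score!r}")
    sample_ids = list(sample_ids)
    scores_matrix = np.asarray(model.predict(train_inputs))
    if scores_matrix.shape[0] != len(sample_ids):
        raise ValueError(
            f"model produced {scores_matrix.shape[0]} score rows for "
            f"{len(sample_ids)} samples"
        )
    if score == "max_prob":
        values = scores_matrix.max(axis=1)
    else:
        class_index = {c: i for i, c in enumerate(model.class_list)}
        cols = [class_index[lab] for lab in train_labels]
        values = scores_matrix[np.arange(len(cols)), cols]
    return dict(zip(sample_ids, values.astype(float)))


def apply_weighting(train_ids: list[str], scores: dict[str, float],
                    threshold: float = 0.3,
                    seed: int = 0) -> tuple[list[str], WeightingPlan]:
    """Duplicate once every training sample whose score exceeds ``threshold``.

    Returns the reshuffled (seeded) weighted id list plus the plan that
    records exactly what was duplicated.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    missing = [sid for sid in train_ids if sid not in scores]
    if missing:
        raise ValueError(f"scores missing for {len(missing)} training samples, "
                         f"e.g. {missing[:5]}")
    duplicated = [sid for sid in train_ids if scores[sid] > threshold]
    weighted = list(train_ids) + duplicated
    rng = np.random.default_rng(seed)
    weighted = [weighted[i] for i in rng.permutation(len(weighted))]
    plan = WeightingPlan(
        threshold=threshold,
        score_source="true_class",
        duplicated_ids=duplicated,
        n_before=len(train_ids),
        n_after=len(weighted),
    )
    return weighted, plan


def guard_test_integrity(plan: WeightingPlan, test_ids: list[str]) -> bool:
    """Assert the test set is untouched by weighting.

    Fails if any test id occurs more than once, or if a duplicated training
    id leaked into the test set at all.
    """
    seen: set[str] = set()
    doubled: set[str] = set()
    for sid in test_ids:
        (doubled if sid in seen else seen).add(sid)
    doubled = sorted(doubled)
    if doubled:
        raise IntegrityError(f"test set contains repeated sample ids: {doubled[:10]}")
    leaked = sorted(set(test_ids) & set(plan.duplicated_ids))
    if leaked:
        raise IntegrityError(
            f"duplicated training samples appear in the test set: {leaked[:10]}"
        )
    return True
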