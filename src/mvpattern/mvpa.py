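"""Pattern discriminability: linear SVM with leave-one-run-out CV.

Two contrast-pattern sets are treated as classes; folds are scanner runs.
For each fold the classifier (linear kernel, cost ``c``, default 1) is
trained on the remaining runs' vectors and tested on the held-out run's two
vectors, and fold accuracies are averaged. No feature scaling is applied
beyond optional sphere-mean removal, so margins stay faithful to the raw
pattern geometry. Chance level is 50%.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .patterns import ContrastPatterns, ContrastSpec


@dataclass
class ClassificationTask:
    class_a: ContrastPatterns
    class_b: ContrastPatterns
    cost: float = 1.0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.class_a.runs != self.class_b.runs:
            raise ValueError("classes must cover the same runs")
        if self.class_a.n_voxels != self.class_b.n_voxels:
            raise ValueError("classes must share the voxel set")


@dataclass
class CVResult:
    fold_accuracies: dict[int, float]
    mean_accuracy: float
    degenerate_folds: list[int] = field(default_factory=list)


def remove_sphere_mean(vectors: np.ndarray) -> np.ndarray:
    """Subtract each pattern vector's own mean across voxels.

    Removes mean-activation differences so classification reflects the
    spatial pattern, not overall amplitude. Accepts a single vector or a
    stack of row vectors.
    """
    vectors = np.asarray(vectors, float)
    if vectors.ndim == 1:
        return vectors - vectors.mean()
    return vectors - vectors.mean(axis=1, keepdims=True)


def loro_cv_accuracy(task: ClassificationTask, center: bool = False) -> CVResult:
    """Leave-one-run-out CV accuracy of a linear max-margin classifier.

    Labels are +1 for class_a and -1 for class_b; a decision value of
    exactly 0 is assigned to class_b. A degenerate training fold (the two
    classes' training matrices are identical) falls back to predicting
    class_a everywhere and is flagged in the result.
    """
    runs = task.class_a.runs
    if len(runs) < 2:
        raise ValueError("leave-one-run-out CV needs >= 2 runs")
    mats = {}
    for run in runs:
        a, b = task.class_a.per_run[run], task.class_b.per_run[run]
        if center:
            a, b = remove_sphere_mean(a), remove_sphere_mean(b)
        mats[run] = (a, b)
    fold_acc: dict[int, float] = {}
    degenerate: list[int] = []
    for test_run in runs:
        train_runs = [r for r in runs if r != test_run]
        x_a = np.stack([mats[r][0] for r in train_runs])
        x_b = np.stack([mats[r][1] for r in train_runs])
        x_test = np.stack(mats[test_run])
        y_test = np.array([1, -1])
        if np.array_equal(x_a, x_b):
            degenerate.append(test_run)
            pred = np.ones(2)  # fall back: class_a (lower label index)
        else:
            clf = SVC(kernel="linear", C=task.cost)
            x_train = np.vstack([x_a, x_b])
            y_train = np.r_[np.ones(len(x_a)), -np.ones(len(x_b))]
            clf.fit(x_train, y_train)
            dec = clf.decision_function(x_test)
            pred = np.where(dec > 0, 1.0, -1.0)  # exactly 0 -> class_b
        fold_acc[test_run] = float(np.mean(pred == y_test))
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(list(fold_acc.values()))),
        degenerate_folds=degenerate,
    )


def relabel_blocks(
    block_patterns: dict[tuple[int, int], np.ndarray],
    block_scores: dict[tuple[int, int], float],
    label_a: str = "short",
    label_b: str = "long",
) -> ClassificationTask:
    """Median-split blocks by score into two classes of per-run patterns.

    Blocks with score <= the within-participant median go to the first
    class ("short"), the rest to the second; ties at the median therefore
    land deterministically in the first class. Block patterns are averaged
    within (run, class) to yield per-run class patterns. Raises if every
    score is equal (no split exists) or some run lacks a block in either
    class.
    """
    if set(block_patterns) != set(block_scores):
        raise ValueError("block_patterns and block_scores must cover the same blocks")
    values = list(block_scores.values())
    if len(set(values)) < 2:
        raise ValueError("all block scores are equal; no median split exists")
    med = statistics.median(values)
    runs = sorted({r for r, _ in block_patterns})
    per_run_a: dict[int, np.ndarray] = {}
    per_run_b: dict[int, np.ndarray] = {}
    for run in runs:
        lo = [block_patterns[k] for k in block_patterns if k[0] == run and block_scores[k] <= med]
        hi = [block_patterns[k] for k in block_patterns if k[0] == run and block_scores[k] > med]
        if not lo or not hi:
            raise ValueError(f"run {run} has no block in one of the split classes")
        per_run_a[run] = np.mean(lo, axis=0)
        per_run_b[run] = np.mean(hi, axis=0)
    return ClassificationTask(
        class_a=ContrastPatterns(ContrastSpec(label_a, label_a, "rest"), per_run_a),
        class_b=ContrastPatterns(ContrastSpec(label_b, label_b, "rest"), per_run_b),
    )


def permutation_chance_check(task: ClassificationTask, n_perm: int, seed: int) -> float:
    """Mean accuracy over label-swapped replicates (diagnostic null)."""
    rng = np.random.default_rng(seed)
    runs = task.class_a.runs
    accs = []
    for _ in range(n_perm):
        swap = rng.random(len(runs)) < 0.5
        pa, pb = {}, {}
        for flip, run in zip(swap, runs):
            a, b = task.class_a.per_run[run], task.class_b.per_run[run]
            pa[run], pb[run] = (b, a) if flip else (a, b)
        t = ClassificationTask(
            class_a=ContrastPatterns(task.class_a.contrast, pa),
            class_b=ContrastPatterns(task.class_b.contrast, pb),
            cost=task.cost,
        )
        accs.append(loro_cv_accuracy(t).mean_accuracy)
    return float(np.mean(accs))
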