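"""Contrasts over condition patterns and ROI extraction.

A contrast pattern is the voxelwise difference between one condition's
per-run pattern and a control condition's pattern from the same run
(``minus="rest"`` means a zero baseline, returning the condition pattern
unchanged). Contrasts are plain differences of patterns — no pooled-error
t statistic — which preserves the pattern geometry the downstream
similarity, classification and regression stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PatternDataset, volume_to_vector

REST = "rest"


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    plus: str
    minus: str = REST

    def __post_init__(self) -> None:
        if self.plus == self.minus:
            raise ValueError(f"contrast {self.name!r}: plus == minus ({self.plus!r})")


#: The study design's named contrasts: each task condition against its
#: matched control, plus the self condition against the implicit baseline.
DEFAULT_CONTRASTS = {
    "self_gt_semantic": ContrastSpec("self_gt_semantic", "self", "semantic"),
    "other_gt_semantic": ContrastSpec("other_gt_semantic", "other", "semantic"),
    "introspection_gt_categorization": ContrastSpec(
        "introspection_gt_categorization", "introspection", "categorization"
    ),
    "memory_gt_knowledge": ContrastSpec(
        "memory_gt_knowledge", "memory", "knowledge"
    ),
    "self_gt_other": ContrastSpec("self_gt_other", "self", "other"),
    "self_gt_rest": ContrastSpec("self_gt_rest", "self", REST),
}


@dataclass
class ContrastPatterns:
    """Per-run contrast vectors for one contrast definition."""

    contrast: ContrastSpec
    per_run: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.per_run.values()}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent vector lengths across runs: {lengths}")

    @property
    def runs(self) -> list[int]:
        return sorted(self.per_run)

    @property
    def n_voxels(self) -> int:
        return len(next(iter(self.per_run.values())))


@dataclass
class ROIMask:
    """A named subset of the dataset's in-mask voxels.

    ``indices`` are positions into the length-V in-mask pattern vectors
    (ascending flat-order positions, the package-wide convention), not raw
    volume coordinates.
    """

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, int))
        if idx.size == 0:
            raise ValueError(f"ROI {self.name!r} is empty")
        if idx.min() < 0:
            raise ValueError(f"ROI {self.name!r} has negative indices")
        self.indices = idx

    @property
    def size(self) -> int:
        return int(self.indices.size)

    @classmethod
    def from_volume(
        cls, name: str, roi_volume: np.ndarray, dataset_mask: np.ndarray
    ) -> "ROIMask":
        """Build from a binary ROI volume; must be a subset of the dataset mask."""
        roi_volume = np.asarray(roi_volume, bool)
        dataset_mask = np.asarray(dataset_mask, bool)
        if np.any(roi_volume & ~dataset_mask):
            raise ValueError(f"ROI {name!r} has voxels outside the dataset mask")
        in_roi = volume_to_vector(roi_volume.astype(float), dataset_mask) > 0.5
        return cls(name=name, indices=np.flatnonzero(in_roi))


def compute_contrast(dataset: PatternDataset, spec: ContrastSpec) -> ContrastPatterns:
    """Per-run difference pattern(run, plus) - pattern(run, minus)."""
    conds = dataset.conditions
    if spec.plus not in conds:
        raise KeyError(f"contrast {spec.name!r}: unknown condition {spec.plus!r}")
    if spec.minus != REST and spec.minus not in conds:
        raise KeyError(f"contrast {spec.name!r}: unknown condition {spec.minus!r}")
    per_run = {}
    for run in dataset.runs:
        plus = dataset.get(run, spec.plus)
        if spec.minus == REST:
            per_run[run] = plus.copy()
        else:
            per_run[run] = plus - dataset.get(run, spec.minus)
    return ContrastPatterns(contrast=spec, per_run=per_run)


def extract_roi(patterns, roi: ROIMask):
    """Restrict patterns to the ROI's voxels (ascending flat-index order).

    Accepts either ``ContrastPatterns`` or a ``PatternDataset``.
    """
    if isinstance(patterns, PatternDataset):
        return patterns.restrict(roi.indices)
    if isinstance(patterns, ContrastPatterns):
        if roi.indices.max() >= patterns.n_voxels:
            raise ValueError(
                f"ROI {roi.name!r} indices exceed pattern length {patterns.n_voxels}"
            )
        return ContrastPatterns(
            contrast=patterns.contrast,
            per_run={r: v[roi.indices] for r, v in patterns.per_run.items()},
        )
    raise TypeError(f"cannot extract ROI from {type(patterns).__name__}")
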