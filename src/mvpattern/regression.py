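"""Run-pair multivariate pattern regression, noise ceiling, and
variance partitioning (commonality analysis).

The dependent contrast pattern from one run is regressed, across ROI
voxels, on the predictor contrast patterns from a *different* run, so that
run-shared noise can never inflate the fit. With five runs this yields the
20 ordered cross-run pairs; betas, R^2 and adjusted R^2 are averaged over
pairs. The noise-ceiling model appends the dependent contrast from the
predictor run as an extra predictor: how well the pattern predicts its own
replicate bounds what any model could explain given measurement noise.

Commonality analysis decomposes the three-predictor R^2 into seven
portions (three unique, three pairwise-common, one common to all) via
inclusion–exclusion over the seven sub-model R^2 values. The portions are
computed on pair-averaged raw R^2 (the additive algebra requires raw R^2);
adjusted R^2 is reported alongside for the full and ceiling models.
Negative commonality portions (suppressor structure) are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import PatternDataset
from .patterns import ContrastSpec, ROIMask, compute_contrast, extract_roi

DEFAULT_DESIGN_PREDICTORS = (
    "other_gt_semantic",
    "introspection_gt_categorization",
    "memory_gt_knowledge",
)


@dataclass
class RegressionDesign:
    dependent: ContrastSpec
    predictors: tuple[ContrastSpec, ...]
    include_ceiling: bool = False

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        if not self.predictors:
            raise ValueError("need at least one predictor")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate predictor names: {names}")


@dataclass
class PairFit:
    betas: np.ndarray
    intercept: float
    r2: float
    adj_r2: float


@dataclass
class RunPairRegressionResult:
    predictor_names: tuple[str, ...]
    per_pair: dict[tuple[int, int], PairFit]  # (dependent run, predictor run)
    mean_betas: np.ndarray
    mean_r2: float
    mean_adj_r2: float
    n_voxels: int


@dataclass
class VPAResult:
    """Seven commonality portions of the full-model R^2.

    Predictor roles O/I/M follow the design's predictor order.
    """

    unique_O: float
    unique_I: float
    unique_M: float
    common_OI: float
    common_OM: float
    common_IM: float
    common_OIM: float
    full_r2: float
    submodel_r2: dict[str, float] = field(default_factory=dict)

    @property
    def portions(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "unique_O",
                "unique_I",
                "unique_M",
                "common_OI",
                "common_OM",
                "common_IM",
                "common_OIM",
            )
        }


def _ols(y: np.ndarray, x_cols: np.ndarray, names) -> PairFit:
    """OLS with intercept across voxels; raises on a rank-deficient design."""
    n, p = x_cols.shape
    design = np.column_stack([np.ones(n), x_cols])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise ValueError(
            f"rank-deficient predictor matrix (rank {rank} < {p + 1}); "
            f"collinear among: {list(names)}"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("dependent pattern has zero variance")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return PairFit(betas=coef[1:], intercept=float(coef[0]), r2=r2, adj_r2=adj)


def _contrast_vectors(dataset, specs, roi):
    out = {}
    for spec in specs:
        cp = compute_contrast(dataset, spec)
        if roi is not None:
            cp = extract_roi(cp, roi)
        out[spec.name] = cp
    return out


def run_pairs(runs) -> list[tuple[int, int]]:
    """All ordered (dependent run, predictor run) pairs with distinct runs."""
    return [(a, b) for a in runs for b in runs if a != b]


def fit_runpair_regressions(
    design: RegressionDesign,
    dataset: PatternDataset,
    roi: ROIMask | None = None,
    ceiling: bool = False,
) -> RunPairRegressionResult:
    """OLS of the dependent contrast (run a) on predictor contrasts (run b).

    ``ceiling=True`` appends the dependent contrast from the predictor run
    as an additional predictor (the noise-ceiling model).
    """
    specs = list(design.predictors)
    vecs = _contrast_vectors(dataset, [design.dependent] + specs, roi)
    dep = vecs[design.dependent.name]
    runs = dep.runs
    if len(runs) < 2:
        raise ValueError("need >= 2 runs for cross-run regression")
    names = tuple(p.name for p in specs)
    if ceiling:
        names = names + (design.dependent.name + "__ceiling",)
    n_vox = dep.n_voxels
    if n_vox <= len(names) + 2:
        raise ValueError(
            f"ROI too small ({n_vox} voxels) for {len(names)} predictors"
        )
    per_pair: dict[tuple[int, int], PairFit] = {}
    for a, b in run_pairs(runs):
        cols = [vecs[p.name].per_run[b] for p in specs]
        if ceiling:
            cols.append(dep.per_run[b])
        per_pair[(a, b)] = _ols(dep.per_run[a], np.column_stack(cols), names)
    fits = list(per_pair.values())
    return RunPairRegressionResult(
        predictor_names=names,
        per_pair=per_pair,
        mean_betas=np.mean([f.betas for f in fits], axis=0),
        mean_r2=float(np.mean([f.r2 for f in fits])),
        mean_adj_r2=float(np.mean([f.adj_r2 for f in fits])),
        n_voxels=n_vox,
    )


def fit_noise_ceiling(
    design: RegressionDesign, dataset: PatternDataset, roi: ROIMask | None = None
) -> RunPairRegressionResult:
    """The noise-ceiling fit: the full model plus the dependent's replicate."""
    return fit_runpair_regressions(design, dataset, roi, ceiling=True)


def _subset_mean_r2(design, dataset, roi) -> dict[frozenset, float]:
    """Pair-averaged raw R^2 for all 7 non-empty predictor subsets."""
    specs = list(design.predictors)
    vecs = _contrast_vectors(dataset, [design.dependent] + specs, roi)
    dep = vecs[design.dependent.name]
    runs = dep.runs
    out: dict[frozenset, float] = {}
    pairs = run_pairs(runs)
    for k in (1, 2, 3):
        for subset in combinations(range(3), k):
            r2s = []
            for a, b in pairs:
                cols = np.column_stack([vecs[specs[i].name].per_run[b] for i in subset])
                names = [specs[i].name for i in subset]
                r2s.append(_ols(dep.per_run[a], cols, names).r2)
            out[frozenset(subset)] = float(np.mean(r2s))
    return out


def variance_partition(
    design: RegressionDesign, dataset: PatternDataset, roi: ROIMask | None = None
) -> VPAResult:
    """Commonality decomposition of the three-predictor regression.

    Fits the seven sub-models (every non-empty subset of the three
    predictors) over all run pairs, averages each raw R^2 across pairs,
    and applies the inclusion–exclusion formulas. The seven portions sum
    to the full-model R^2 exactly (an algebraic identity).
    """
    if len(design.predictors) != 3:
        raise ValueError(
            f"variance partitioning needs exactly 3 predictors, got {len(design.predictors)}"
        )
    r2 = _subset_mean_r2(design, dataset, roi)
    O, I, M = frozenset([0]), frozenset([1]), frozenset([2])
    OI, OM, IM = O | I, O | M, I | M
    OIM = O | I | M
    res = VPAResult(
        unique_O=r2[OIM] - r2[IM],
        unique_I=r2[OIM] - r2[OM],
        unique_M=r2[OIM] - r2[OI],
        common_OI=r2[OM] + r2[IM] - r2[M] - r2[OIM],
        common_OM=r2[OI] + r2[IM] - r2[I] - r2[OIM],
        common_IM=r2[OI] + r2[OM] - r2[O] - r2[OIM],
        common_OIM=r2[O] + r2[I] + r2[M] - r2[OI] - r2[OM] - r2[IM] + r2[OIM],
        full_r2=r2[OIM],
        submodel_r2={
            "O": r2[O], "I": r2[I], "M": r2[M],
            "OI": r2[OI], "OM": r2[OM], "IM": r2[IM], "OIM": r2[OIM],
        },
    )
    return res


def explainable_variance_pct(
    full_results: list[RunPairRegressionResult],
    ceiling_results: list[RunPairRegressionResult],
) -> float:
    """Mean percent of the noise-ceiling adjusted R^2 the full model reaches.

    Per subject: 100 * full mean adjusted R^2 / ceiling mean adjusted R^2;
    subjects with a nonpositive ceiling are excluded with a warning.
    """
    if len(full_results) != len(ceiling_results):
        raise ValueError("full and ceiling result lists differ in length")
    pcts = []
    for i, (f, c) in enumerate(zip(full_results, ceiling_results)):
        if c.mean_adj_r2 <= 0:
            warnings.warn(
                f"subject {i}: nonpositive noise ceiling "
                f"({c.mean_adj_r2:.4f}); excluded",
                stacklevel=2,
            )
            continue
        pcts.append(100.0 * f.mean_adj_r2 / c.mean_adj_r2)
    if not pcts:
        raise ValueError("no subject has a positive noise ceiling")
    return float(np.mean(pcts))
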