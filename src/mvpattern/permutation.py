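"""Smoothness-preserving voxel-shuffle permutation null.

Shuffling voxels destroys the spatial autocorrelation of real pattern
maps, which would make a naive voxel-permutation null anticonservative.
The remedy implemented here: (1) measure the observed map's smoothness
with Moran's I under inverse-Euclidean-distance weights; (2) calibrate a
Gaussian kernel SD (grid 0 to 2.0 voxel units, step 0.02) such that
shuffled-then-smoothed maps best match that smoothness, by minimizing the
sum of squared Moran's-I differences over repeated shuffles; (3) build the
null by re-shuffling the self-condition pattern — the same permutation
applied to every run, so cross-run reliability structure is preserved —
smoothing at the calibrated SD, recomputing contrasts and re-running the
statistic. p-values use the add-one rule and can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import PatternDataset, mask_voxel_coords, vector_to_volume, volume_to_vector
from .synth import smooth_volume

DEFAULT_SD_GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.02), 2)


@dataclass
class MoransIWeights:
    """Inverse-Euclidean pairwise weights over ROI voxels (zero diagonal).

    ``cutoff_mm`` truncates weights beyond that distance; the full matrix
    is O(V^2), so a cutoff (default 12 mm) is advisable for V beyond a few
    thousand voxels.
    """

    weights: np.ndarray
    cutoff_mm: float | None = None

    @classmethod
    def from_coords(
        cls, coords_mm: np.ndarray, cutoff_mm: float | None = None
    ) -> "MoransIWeights":
        coords_mm = np.asarray(coords_mm, float)
        d = np.sqrt(
            np.sum((coords_mm[:, None, :] - coords_mm[None, :, :]) ** 2, axis=2)
        )
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        if cutoff_mm is not None:
            w[d > cutoff_mm] = 0.0
        return cls(weights=w, cutoff_mm=cutoff_mm)

    @classmethod
    def for_dataset(
        cls, dataset: PatternDataset, cutoff_mm: float | None = 12.0
    ) -> "MoransIWeights":
        coords = dataset.grid.voxel_to_mm(mask_voxel_coords(dataset.mask))
        if len(coords) <= 2000:
            cutoff_mm = None  # exact full matrix is cheap at this size
        return cls.from_coords(coords, cutoff_mm=cutoff_mm)


def morans_i(values: np.ndarray, weights: MoransIWeights) -> float:
    """Global spatial autocorrelation: I = (N/W) * x'Wx / x'x, x centered.

    Under spatial independence E[I] = -1/(N-1); smooth maps push I upward.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need >= 2 voxels")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant map: Moran's I undefined")
    w = weights.weights
    w_sum = float(w.sum())
    return (x.size / w_sum) * float(xc @ (w @ xc)) / denom


@dataclass
class SmoothnessCalibration:
    sd_grid: np.ndarray
    sse_per_sd: np.ndarray
    best_sd: float
    observed_i: float


def calibrate_smoothing_sd(
    observed: np.ndarray,
    dataset: PatternDataset,
    weights: MoransIWeights | None = None,
    sd_grid: np.ndarray = DEFAULT_SD_GRID,
    n_rep: int = 1000,
    seed: int = 0,
) -> SmoothnessCalibration:
    """Choose the post-shuffle smoothing SD that best restores smoothness.

    For each candidate SD, ``n_rep`` voxel shuffles of the observed map
    are smoothed within the mask at that SD (voxel units) and their
    Moran's I compared with the observed map's; the SD minimizing the
    summed squared difference wins (ties to the smaller SD). The same
    ``n_rep`` permutation draws are reused across the whole SD grid
    (common random numbers), so the SSE profile over SDs is compared on
    identical shuffles and SDs whose kernels coincide tie exactly.
    """
    sd_grid = np.asarray(sd_grid, float)
    if sd_grid.size == 0:
        raise ValueError("sd_grid is empty")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if weights is None:
        weights = MoransIWeights.for_dataset(dataset)
    observed = np.asarray(observed, float)
    i_obs = morans_i(observed, weights)
    mask = dataset.mask
    sse = np.zeros(sd_grid.size)
    rng = np.random.default_rng(seed)
    for _ in range(n_rep):
        shuffled = observed[rng.permutation(observed.size)]
        vol = vector_to_volume(shuffled, mask, fill=0.0)
        for si, sd in enumerate(sd_grid):
            if sd > 0:
                sm = smooth_volume(vol, mask=mask, sd_voxels=float(sd))
                vec = volume_to_vector(sm, mask)
            else:
                vec = shuffled
            sse[si] += (morans_i(vec, weights) - i_obs) ** 2
    best = int(np.argmin(sse))  # argmin takes the first = smallest sd on ties
    return SmoothnessCalibration(
        sd_grid=sd_grid, sse_per_sd=sse, best_sd=float(sd_grid[best]), observed_i=i_obs
    )


@dataclass
class PermutationNull:
    n_perm: int
    seed: int
    best_sd: float
    observed: dict[str, float]
    null_samples: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_resampled: int = 0


def permuted_statistic_null(
    dataset: PatternDataset,
    statistic: Callable[[PatternDataset], dict[str, float]],
    calibration: SmoothnessCalibration,
    shuffle_condition: str = "self",
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "greater",
) -> PermutationNull:
    """Null distributions and p-values for a map-level statistic.

    Each iteration draws one voxel permutation, applies it identically to
    the shuffle condition's pattern in every run, smooths the shuffled
    patterns within the mask at the calibrated SD, and re-runs
    ``statistic`` (which sees a dataset where only that condition's
    patterns changed — so contrasts built from it are recomputed). After
    smoothing, each shuffled pattern is rescaled to its original mean and
    SD: smoothing shrinks marginal variance as a side effect, which would
    make null statistics systematically smaller than the observed one;
    Moran's I is location/scale-invariant, so the rescale leaves the
    calibrated smoothness match intact. An iteration whose statistic
    raises is resampled, up to 1% of ``n_perm``.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if shuffle_condition not in dataset.conditions:
        raise KeyError(f"condition {shuffle_condition!r} not in dataset")
    observed = dict(statistic(dataset))
    keys = list(observed)
    mask = dataset.mask
    sd = calibration.best_sd
    rng = np.random.default_rng(seed)
    v = dataset.n_voxels
    null: dict[str, list[float]] = {k: [] for k in keys}
    n_resampled = 0
    max_resample = max(1, int(0.01 * n_perm))
    done = 0
    while done < n_perm:
        perm = rng.permutation(v)
        pats = dict(dataset.patterns)
        for run in dataset.runs:
            orig = pats[(run, shuffle_condition)]
            vec = orig[perm]
            if sd > 0:
                vol = vector_to_volume(vec, mask, fill=0.0)
                vol = smooth_volume(vol, mask=mask, sd_voxels=sd)
                vec = volume_to_vector(vol, mask)
                spread = vec.std()
                if spread > 0:
                    vec = (vec - vec.mean()) / spread * orig.std() + orig.mean()
            pats[(run, shuffle_condition)] = vec
        shuffled_ds = PatternDataset(
            grid=dataset.grid, mask=mask, patterns=pats,
            provenance=dataset.provenance,
        )
        try:
            vals = statistic(shuffled_ds)
        except Exception:  # noqa: BLE001 - resample contract
            n_resampled += 1
            if n_resampled > max_resample:
                raise RuntimeError(
                    f"statistic failed in more than {max_resample} permutations"
                )
            continue
        for k in keys:
            null[k].append(float(vals[k]))
        done += 1
    null_arr = {k: np.asarray(vs) for k, vs in null.items()}
    p_values = {}
    for k in keys:
        if tail == "greater":
            exceed = np.sum(null_arr[k] >= observed[k])
        else:
            exceed = np.sum(np.abs(null_arr[k]) >= abs(observed[k]))
        p_values[k] = float((1 + exceed) / (1 + n_perm))
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        best_sd=sd,
        observed=observed,
        null_samples=null_arr,
        p_values=p_values,
        n_resampled=n_resampled,
    )


def regression_statistic(
    design, roi=None, include_vpa: bool = False
) -> Callable[[PatternDataset], dict[str, float]]:
    """Statistic adapter: run-pair regression betas/adjusted R^2 (+ VPA)."""
    from .regression import fit_runpair_regressions, variance_partition

    def stat(ds: PatternDataset) -> dict[str, float]:
        res = fit_runpair_regressions(design, ds, roi)
        out = {f"beta_{n}": float(b) for n, b in zip(res.predictor_names, res.mean_betas)}
        out["adj_r2"] = res.mean_adj_r2
        if include_vpa:
            vpa = variance_partition(design, ds, roi)
            out.update(vpa.portions)
        return out

    return stat
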