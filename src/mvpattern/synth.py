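"""Synthetic block designs and multivoxel pattern datasets.

The generator emulates the statistical structure a multi-run block-design
pattern analysis assumes: a 7-condition x 5-run design with 14 blocks per
run and no condition repeated back to back, latent spatially smooth signal
components shared across runs, a run-specific nuisance field shared by all
conditions of a run (the "shared physiological noise" that motivates
excluding within-run similarity cells), and i.i.d. observation noise.

Pattern model, for run r and condition c::

    pattern(r, c) = sum_k loading[c, k] * s_k  +  eta_r  +  eps_{r,c}

where each ``s_k`` is a unit-variance spatially smoothed Gaussian field
fixed across runs, ``eta_r`` is a fresh unit-variance field per run scaled
by ``run_noise_sd``, and ``eps`` is i.i.d. N(0, obs_noise_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import PatternDataset, VolumeGrid, volume_to_vector

FWHM_PER_SD = math.sqrt(8.0 * math.log(2.0))

DEFAULT_CONDITIONS = (
    "self",
    "other",
    "semantic",
    "introspection",
    "categorization",
    "memory",
    "knowledge",
)


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered block list per run; no condition occupies two adjacent blocks."""

    n_runs: int
    entries: tuple[tuple[int, int, str], ...]  # (run, block, condition)
    condition_labels: tuple[str, ...]

    def run_order(self, run: int) -> list[str]:
        return [c for r, _, c in self.entries if r == run]


def generate_block_sequence(
    condition_labels,
    n_runs: int,
    blocks_per_condition: int,
    seed: int,
    max_tries: int = 10_000,
) -> BlockSchedule:
    """Pseudorandomize block order per run with no adjacent repeats.

    Rejection sampling: shuffle the multiset of blocks until no two
    consecutive blocks share a condition. Raises if the constraint is
    infeasible (a single label with >= 2 blocks) or the retry cap is hit.
    """
    labels = tuple(condition_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be distinct")
    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    n_blocks = len(labels) * blocks_per_condition
    # A label occupying more than ceil(n/2) slots cannot avoid self-adjacency.
    if blocks_per_condition > (n_blocks + 1) // 2:
        raise ValueError(
            f"no-adjacent-repeat order is infeasible: {blocks_per_condition} "
            f"blocks of one condition among {n_blocks} total"
        )
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(len(labels)), blocks_per_condition)
    entries: list[tuple[int, int, str]] = []
    for run in range(n_runs):
        for _ in range(max_tries):
            order = rng.permutation(base)
            if not np.any(order[1:] == order[:-1]):
                break
        else:  # pragma: no cover - astronomically unlikely for feasible designs
            raise RuntimeError("retry cap exceeded while pseudorandomizing blocks")
        entries.extend((run, b, labels[i]) for b, i in enumerate(order))
    return BlockSchedule(n_runs=n_runs, entries=tuple(entries), condition_labels=labels)


def smooth_volume(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    fwhm_mm: float | None = None,
    sd_voxels: float | None = None,
    voxel_size_mm=(3.0, 3.0, 3.0),
) -> np.ndarray:
    """Separable Gaussian smoothing with zero padding, then re-masking.

    The kernel width is given either as a physical FWHM in mm (converted to
    a per-axis sigma in voxels, so anisotropic voxels are handled per axis)
    or directly as an isotropic standard deviation in voxel units. A zero
    kernel returns the (masked) input unchanged. Out-of-mask voxels are set
    to zero before convolution and masked out again afterwards (zero-padded
    mask edges); the volume boundary itself is mirrored so that smoothing a
    constant unmasked volume is the identity.
    """
    if (fwhm_mm is None) == (sd_voxels is None):
        raise ValueError("specify exactly one of fwhm_mm or sd_voxels")
    vol = np.asarray(volume, float)
    if fwhm_mm is not None:
        if fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        sigmas = [fwhm_mm / (FWHM_PER_SD * vs) for vs in voxel_size_mm]
    else:
        if sd_voxels < 0:
            raise ValueError("sd_voxels must be >= 0")
        sigmas = [float(sd_voxels)] * 3
    if mask is not None:
        mask = np.asarray(mask, bool)
        vol = np.where(mask, vol, 0.0)
    if max(sigmas) == 0.0:
        return vol.copy()
    out = ndimage.gaussian_filter(vol, sigma=sigmas, mode="reflect")
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


@dataclass
class GeneratorSpec:
    """Everything needed to simulate one participant's pattern dataset."""

    grid: VolumeGrid
    mask: np.ndarray
    n_runs: int
    condition_labels: tuple[str, ...]
    loading_matrix: np.ndarray  # conditions x latent components
    component_smoothness_fwhm_mm: float = 0.0
    run_noise_sd: float = 0.0
    obs_noise_sd: float = 1.0
    seed: int = 0
    provenance: str = field(default="synthetic", repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        self.loading_matrix = np.atleast_2d(np.asarray(self.loading_matrix, float))
        self.condition_labels = tuple(self.condition_labels)
        if self.loading_matrix.shape[0] != len(self.condition_labels):
            raise ValueError(
                f"loading_matrix has {self.loading_matrix.shape[0]} rows for "
                f"{len(self.condition_labels)} conditions"
            )
        if min(self.run_noise_sd, self.obs_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.component_smoothness_fwhm_mm < 0:
            raise ValueError("component smoothness must be >= 0")
        if not self.mask.any():
            raise ValueError("mask is empty")


def _smooth_unit_field(rng, spec: GeneratorSpec) -> np.ndarray:
    """Smoothed Gaussian field standardized to zero mean / unit SD in-mask."""
    vol = rng.standard_normal(spec.grid.dims)
    if spec.component_smoothness_fwhm_mm > 0:
        vol = smooth_volume(
            vol,
            fwhm_mm=spec.component_smoothness_fwhm_mm,
            voxel_size_mm=spec.grid.voxel_size_mm,
        )
    vec = volume_to_vector(vol, spec.mask)
    sd = vec.std(ddof=1) if vec.size > 1 else 1.0
    if sd == 0:  # pragma: no cover - degenerate single-voxel mask
        sd = 1.0
    return (vec - vec.mean()) / sd


def generate_pattern_dataset(spec: GeneratorSpec) -> PatternDataset:
    """Simulate per-run, per-condition patterns with planted latent structure."""
    rng = np.random.default_rng(spec.seed)
    n_cond, n_comp = spec.loading_matrix.shape
    v = int(spec.mask.sum())
    components = np.stack(
        [_smooth_unit_field(rng, spec) for _ in range(n_comp)]
    ) if n_comp else np.zeros((0, v))
    signal = spec.loading_matrix @ components  # conditions x V
    patterns: dict[tuple[int, str], np.ndarray] = {}
    for run in range(spec.n_runs):
        eta = (
            spec.run_noise_sd * _smooth_unit_field(rng, spec)
            if spec.run_noise_sd > 0
            else np.zeros(v)
        )
        for ci, cond in enumerate(spec.condition_labels):
            eps = (
                spec.obs_noise_sd * rng.standard_normal(v)
                if spec.obs_noise_sd > 0
                else 0.0
            )
            patterns[(run, cond)] = signal[ci] + eta + eps
    return PatternDataset(
        grid=spec.grid, mask=spec.mask, patterns=patterns, provenance=spec.provenance
    )


def default_test_grid(n: int = 20, voxel_mm: float = 3.0) -> VolumeGrid:
    """The package's default simulation grid: an n^3 cube of 3 mm voxels."""
    return VolumeGrid(dims=(n, n, n), voxel_size_mm=(voxel_mm,) * 3)
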