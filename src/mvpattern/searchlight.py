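"""Searchlight mapping: evaluate a multivariate statistic in a moving sphere.

A sphere of radius 3 voxels on an isotropic grid holds at most 123 voxels
(fewer at mask edges). Sphere membership uses exact integer arithmetic on
squared voxel distances (d^2 <= r^2), so there is no floating-point
boundary ambiguity; on anisotropic grids distances are measured in mm with
per-axis scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import PatternDataset, VolumeGrid, vector_to_volume, RAVEL_ORDER


@dataclass
class SphereIndex:
    center: tuple[int, int, int]
    member_indices: np.ndarray  # positions into the in-mask pattern vectors


@dataclass
class StatMap:
    grid: VolumeGrid
    values: np.ndarray  # 3-D, NaN outside mask
    statistic_name: str = ""


def sphere_offsets(radius_voxels: float, voxel_size_mm=None) -> np.ndarray:
    """Integer voxel offsets within the sphere, via exhaustive lattice scan.

    With ``voxel_size_mm`` given, the radius is interpreted in voxel units
    of the smallest axis and distances are compared in mm per axis;
    otherwise plain voxel units (isotropic) with integer d^2 <= r^2.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if voxel_size_mm is None:
        r = int(np.floor(radius_voxels))
        rr = np.arange(-r, r + 1)
        dx, dy, dz = np.meshgrid(rr, rr, rr, indexing="ij")
        keep = dx**2 + dy**2 + dz**2 <= int(radius_voxels**2)
    else:
        vs = np.asarray(voxel_size_mm, float)
        radius_mm = radius_voxels * vs.min()
        lims = [int(np.floor(radius_mm / v)) for v in vs]
        ax = [np.arange(-l, l + 1) for l in lims]
        dx, dy, dz = np.meshgrid(*ax, indexing="ij")
        keep = (dx * vs[0]) ** 2 + (dy * vs[1]) ** 2 + (dz * vs[2]) ** 2 <= radius_mm**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _position_volume(mask: np.ndarray) -> np.ndarray:
    """Volume mapping each in-mask voxel to its flat-order vector position."""
    mask = np.asarray(mask, bool)
    pos = np.full(mask.size, -1, dtype=np.int64)
    flat = mask.ravel(order=RAVEL_ORDER)
    pos[flat] = np.arange(flat.sum())
    return pos.reshape(mask.shape, order=RAVEL_ORDER)


def sphere_indices(
    center, mask: np.ndarray, radius_voxels: float = 3.0, voxel_size_mm=None
) -> SphereIndex:
    """In-mask members of the sphere around ``center`` (a voxel coordinate)."""
    mask = np.asarray(mask, bool)
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise ValueError(f"center {center} is outside the mask")
    pos = _position_volume(mask)
    offs = sphere_offsets(radius_voxels, voxel_size_mm)
    coords = offs + np.array(center)
    ok = np.all((coords >= 0) & (coords < np.array(mask.shape)), axis=1)
    coords = coords[ok]
    members = pos[coords[:, 0], coords[:, 1], coords[:, 2]]
    members = np.sort(members[members >= 0])
    return SphereIndex(center=center, member_indices=members)


def run_searchlight(
    dataset: PatternDataset,
    statistic: Callable[[dict[tuple[int, str], np.ndarray]], float],
    radius_voxels: float = 3.0,
    min_sphere_size: int = 1,
    statistic_name: str = "statistic",
    use_mm_distances: bool = False,
) -> StatMap:
    """Evaluate ``statistic`` on every sphere; write results at the centers.

    The statistic receives the sphere-restricted patterns as a dict
    ``(run, condition) -> vector`` and returns a float. A failing center
    yields NaN with a warning rather than aborting the whole map. Results
    do not depend on traversal order (the statistic must be pure).
    """
    mask = dataset.mask
    vs = dataset.grid.voxel_size_mm if use_mm_distances else None
    pos = _position_volume(mask)
    offs = sphere_offsets(radius_voxels, vs)
    coords = dataset.voxel_coords()
    keys = list(dataset.patterns)
    data = np.stack([dataset.patterns[k] for k in keys])
    out = np.full(dataset.n_voxels, np.nan)
    n_failed = 0
    shape = np.array(mask.shape)
    for vi, center in enumerate(coords):
        cc = offs + center
        ok = np.all((cc >= 0) & (cc < shape), axis=1)
        cc = cc[ok]
        members = pos[cc[:, 0], cc[:, 1], cc[:, 2]]
        members = members[members >= 0]
        if members.size < min_sphere_size:
            continue
        sub = data[:, members]
        sphere_pats = {k: sub[i] for i, k in enumerate(keys)}
        try:
            out[vi] = statistic(sphere_pats)
        except Exception as exc:  # noqa: BLE001 - per-center isolation contract
            n_failed += 1
            if n_failed <= 3:
                warnings.warn(
                    f"statistic failed at center {tuple(center)}: {exc}",
                    stacklevel=2,
                )
    if n_failed:
        warnings.warn(f"statistic failed at {n_failed} centers (NaN)", stacklevel=2)
    return StatMap(
        grid=dataset.grid,
        values=vector_to_volume(out, mask, fill=np.nan),
        statistic_name=statistic_name,
    )


def rsa_statistic(model_rsm, items) -> Callable:
    """Per-sphere Kendall tau-a between the local neural RSM and a model."""
    from .rsa import NeuralRSM, kendall_tau_a

    items = tuple((c, r) for c, r in items)

    def stat(sphere_pats: dict[tuple[int, str], np.ndarray]) -> float:
        mat = np.stack([sphere_pats[(r, c)] for c, r in items])
        sds = mat.std(axis=1, ddof=1)
        if mat.shape[1] < 2 or np.any(sds == 0):
            raise ValueError("degenerate sphere patterns")
        neural = NeuralRSM(items=items, values=np.corrcoef(mat))
        return kendall_tau_a(neural, model_rsm)

    return stat


def mvpa_statistic(
    contrast_a, contrast_b, cost: float = 1.0, center: bool = True
) -> Callable:
    """Per-sphere leave-one-run-out SVM accuracy for two contrasts.

    Sphere-mean removal (``center=True``) is the searchlight default so
    that accuracy reflects local pattern shape, not mean amplitude.
    """
    from .mvpa import ClassificationTask, loro_cv_accuracy
    from .patterns import ContrastPatterns, REST

    def _contrast(sphere_pats, spec):
        runs = sorted({r for r, _ in sphere_pats})
        per_run = {}
        for r in runs:
            v = sphere_pats[(r, spec.plus)]
            per_run[r] = v.copy() if spec.minus == REST else v - sphere_pats[(r, spec.minus)]
        return ContrastPatterns(spec, per_run)

    def stat(sphere_pats: dict[tuple[int, str], np.ndarray]) -> float:
        task = ClassificationTask(
            class_a=_contrast(sphere_pats, contrast_a),
            class_b=_contrast(sphere_pats, contrast_b),
            cost=cost,
        )
        return loro_cv_accuracy(task, center=center).mean_accuracy

    return stat
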