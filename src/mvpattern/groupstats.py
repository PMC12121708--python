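"""Second-level inference over subject statistic maps.

Subject maps (tau-a or accuracy searchlight outputs) are centered at their
theoretical null value (0 for correlations, 0.5 for accuracies), optionally
smoothed, and tested voxelwise with a one-sample t statistic whose null is
built by random per-subject sign flips. The voxel-forming threshold is the
parametric t quantile at the requested voxel p (df = n-1); the permutation
distribution of the maximum suprathreshold cluster size then provides
familywise-error-corrected cluster p values. Dual voxel thresholds are
supported (a lenient threshold inside a hypothesis ROI, a stricter one
elsewhere). Cluster connectivity is face (6-neighbour) by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import volume_to_vector, vector_to_volume
from .searchlight import StatMap
from .synth import smooth_volume

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GroupSample:
    """Subject statistic maps on a common grid plus their chance value."""

    subject_maps: list[StatMap]
    mask: np.ndarray
    null_value: float = 0.0

    def __post_init__(self) -> None:
        if len(self.subject_maps) < 2:
            raise ValueError("need >= 2 subjects")
        grids = {m.grid.dims for m in self.subject_maps}
        if len(grids) > 1:
            raise ValueError(f"subject maps on different grids: {grids}")
        self.mask = np.asarray(self.mask, bool)

    def data_matrix(self, smooth_fwhm_mm: float = 0.0) -> np.ndarray:
        """Subjects x V matrix of centered (optionally smoothed) map values."""
        rows = []
        for m in self.subject_maps:
            vol = np.nan_to_num(m.values, nan=self.null_value)
            if smooth_fwhm_mm > 0:
                vol = smooth_volume(
                    vol,
                    mask=self.mask,
                    fwhm_mm=smooth_fwhm_mm,
                    voxel_size_mm=m.grid.voxel_size_mm,
                )
            rows.append(volume_to_vector(vol, self.mask) - self.null_value)
        return np.stack(rows)


@dataclass
class Cluster:
    size_voxels: int
    peak_coordinate: tuple[int, int, int]
    peak_value: float
    cluster_p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    thresholded_map: np.ndarray  # binary: voxels in significant clusters
    t_map: np.ndarray
    max_null_sizes: np.ndarray = field(repr=False, default=None)


def _t_stat(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = data.mean(axis=0) * np.sqrt(n) / sd
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _cluster_sizes(supra_vol: np.ndarray, struct) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(supra_vol, structure=struct)
    return labels, n


def signflip_permutation_test(
    sample: GroupSample,
    n_perm: int = 5000,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    seed: int = 0,
    roi: np.ndarray | None = None,
    voxel_p_roi: float = 0.005,
    connectivity: int = 6,
    smooth_fwhm_mm: float = 0.0,
) -> ClusterResult:
    """One-sample sign-flip permutation test with cluster-extent FWE.

    ``roi``, if given, is a binary volume inside which the voxel-forming
    threshold uses ``voxel_p_roi`` instead of ``voxel_p``. When ``n_perm``
    meets or exceeds the 2^n possible sign assignments the null is
    enumerated exhaustively instead (with a warning).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    struct = _STRUCTS[connectivity]
    data = sample.data_matrix(smooth_fwhm_mm)
    n_sub, n_vox = data.shape
    df = n_sub - 1
    t_thr = np.full(n_vox, stats.t.ppf(1 - voxel_p, df))
    if roi is not None:
        in_roi = volume_to_vector(np.asarray(roi, bool).astype(float), sample.mask) > 0.5
        t_thr[in_roi] = stats.t.ppf(1 - voxel_p_roi, df)

    def max_cluster(t_vec: np.ndarray) -> int:
        supra = vector_to_volume((t_vec > t_thr).astype(float), sample.mask, 0.0) > 0.5
        labels, n = _cluster_sizes(supra, struct)
        if n == 0:
            return 0
        return int(np.bincount(labels.ravel())[1:].max())

    t_obs = _t_stat(data)

    if n_perm >= 2**n_sub:
        warnings.warn(
            f"n_perm={n_perm} >= 2^{n_sub} sign assignments; enumerating "
            "the null exhaustively",
            stacklevel=2,
        )
        signs_iter = (np.array(s) for s in itertools.product((1.0, -1.0), repeat=n_sub))
        n_perm = 2**n_sub
    else:
        rng = np.random.default_rng(seed)
        signs_iter = (
            rng.choice([1.0, -1.0], size=n_sub) for _ in range(n_perm)
        )
    max_null = np.array([max_cluster(_t_stat(data * s[:, None])) for s in signs_iter])

    supra = vector_to_volume((t_obs > t_thr).astype(float), sample.mask, 0.0) > 0.5
    labels, n_clust = _cluster_sizes(supra, struct)
    t_vol = vector_to_volume(t_obs, sample.mask, 0.0)
    clusters: list[Cluster] = []
    sig_map = np.zeros_like(supra)
    for lab in range(1, n_clust + 1):
        where = labels == lab
        size = int(where.sum())
        p = float((1 + np.sum(max_null >= size)) / (1 + n_perm))
        masked_t = np.where(where, t_vol, -np.inf)
        peak = np.unravel_index(np.argmax(masked_t), masked_t.shape)
        clusters.append(
            Cluster(
                size_voxels=size,
                peak_coordinate=tuple(int(i) for i in peak),
                peak_value=float(t_vol[peak]),
                cluster_p=p,
            )
        )
        if p < cluster_p:
            sig_map |= where
    clusters.sort(key=lambda c: -c.size_voxels)
    return ClusterResult(
        clusters=clusters,
        thresholded_map=sig_map,
        t_map=t_vol,
        max_null_sizes=max_null,
    )


def overlap_map(
    binary_maps: list[np.ndarray],
    min_cluster_size: int = 1,
    connectivity: int = 6,
) -> tuple[np.ndarray, list[int]]:
    """Voxelwise AND of binary maps, dropping small connected components."""
    if not binary_maps:
        raise ValueError("need at least one map")
    out = np.asarray(binary_maps[0], bool).copy()
    for m in binary_maps[1:]:
        out &= np.asarray(m, bool)
    labels, n = ndimage.label(out, structure=_STRUCTS[connectivity])
    sizes = []
    for lab in range(1, n + 1):
        where = labels == lab
        size = int(where.sum())
        if size < min_cluster_size:
            out[where] = False
        else:
            sizes.append(size)
    return out, sorted(sizes, reverse=True)
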