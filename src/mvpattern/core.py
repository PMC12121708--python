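"""Core containers shared by every analysis stage.

Voxel-ordering convention
-------------------------
Volumes are numpy arrays indexed ``[x, y, z]``. Whenever a volume is
flattened to a per-voxel vector (pattern vectors, ROI indices, searchlight
members, Moran's-I weights) the flat index runs in Fortran order, i.e. the
x axis varies fastest. Every module uses the helpers below so that pattern
vectors, ROI masks and statistic maps always agree on which entry is which
voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

RAVEL_ORDER = "F"  # x fastest; fixed everywhere


def volume_to_vector(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract in-mask values as a 1-D vector in the package flat order."""
    return np.asarray(volume).ravel(order=RAVEL_ORDER)[
        np.asarray(mask, bool).ravel(order=RAVEL_ORDER)
    ]


def vector_to_volume(
    vector: np.ndarray, mask: np.ndarray, fill: float = np.nan
) -> np.ndarray:
    """Scatter a length-V vector back into a volume; out-of-mask gets `fill`."""
    mask = np.asarray(mask, bool)
    flat = np.full(mask.size, fill, dtype=float)
    flat[mask.ravel(order=RAVEL_ORDER)] = vector
    return flat.reshape(mask.shape, order=RAVEL_ORDER)


def mask_voxel_coords(mask: np.ndarray) -> np.ndarray:
    """(V, 3) integer voxel coordinates of in-mask voxels, in flat order."""
    mask = np.asarray(mask, bool)
    idx = np.flatnonzero(mask.ravel(order=RAVEL_ORDER))
    xs, ys, zs = np.unravel_index(idx, mask.shape, order=RAVEL_ORDER)
    return np.column_stack([xs, ys, zs])


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a voxel grid: shape, physical voxel size and origin (mm)."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling plus origin translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) * np.asarray(
            self.voxel_size_mm
        ) + np.asarray(self.origin)


@dataclass
class PatternDataset:
    """Per-run, per-condition voxel patterns under a common binary mask.

    ``patterns`` maps ``(run, condition)`` to a length-V vector, where V is
    the number of in-mask voxels and vector order follows the package flat
    convention (see module docstring).
    """

    grid: VolumeGrid
    mask: np.ndarray
    patterns: dict[tuple[int, str], np.ndarray]
    provenance: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.mask.shape} != grid dims {self.grid.dims}"
            )
        v = self.n_voxels
        if v < 1:
            raise ValueError("mask is empty")
        runs, conds = self.runs, self.conditions
        for r in runs:
            for c in conds:
                if (r, c) not in self.patterns:
                    raise ValueError(f"missing pattern cell (run={r}, condition={c!r})")
        for key, vec in self.patterns.items():
            vec = np.asarray(vec, float)
            if vec.shape != (v,):
                raise ValueError(
                    f"pattern {key} has length {vec.shape}, expected ({v},)"
                )
            self.patterns[key] = vec

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def runs(self) -> list[int]:
        return sorted({r for r, _ in self.patterns})

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, c in self.patterns:
            if c not in seen:
                seen.append(c)
        return seen

    def voxel_coords(self) -> np.ndarray:
        """(V, 3) voxel coordinates of the in-mask voxels, cached."""
        if self._coords is None:
            self._coords = mask_voxel_coords(self.mask)
        return self._coords

    def get(self, run: int, condition: str) -> np.ndarray:
        try:
            return self.patterns[(run, condition)]
        except KeyError:
            raise KeyError(
                f"no pattern for run {run}, condition {condition!r}; "
                f"runs={self.runs}, conditions={self.conditions}"
            ) from None

    def restrict(self, roi_indices: np.ndarray) -> "PatternDataset":
        """New dataset whose mask keeps only the given in-mask voxel positions."""
        roi_indices = np.asarray(roi_indices, int)
        if roi_indices.size == 0:
            raise ValueError("empty ROI")
        if roi_indices.min() < 0 or roi_indices.max() >= self.n_voxels:
            raise ValueError("ROI indices outside the dataset mask")
        keep = np.zeros(self.n_voxels, bool)
        keep[roi_indices] = True
        new_mask = vector_to_volume(keep.astype(float), self.mask, fill=0.0) > 0.5
        pats = {k: v[keep] for k, v in self.patterns.items()}
        return PatternDataset(self.grid, new_mask, pats, provenance=self.provenance)
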