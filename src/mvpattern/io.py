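"""Reading and writing datasets, masks, RSMs and statistic maps.

Two on-disk encodings of a pattern dataset are supported and round-trip
equivalent:

* a directory of NIfTI volumes (one per run x condition) plus a binary
  mask volume and a JSON manifest listing the cells, and
* a single flat TSV (one row per in-mask voxel: x, y, z, then one column
  per ``run{r}:{condition}``) with a JSON sidecar carrying the grid
  geometry — convenient for headless tests and diffable fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PatternDataset, VolumeGrid, vector_to_volume, volume_to_vector


def _grid_from_affine(affine: np.ndarray, dims) -> VolumeGrid:
    vs = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VolumeGrid(dims=tuple(int(d) for d in dims), voxel_size_mm=vs, origin=origin)


def write_mask_nifti(mask: np.ndarray, grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), grid.affine), str(path))


def read_mask_nifti(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data > 0.5, _grid_from_affine(img.affine, data.shape)


def write_pattern_dataset(dataset: PatternDataset, out_dir) -> Path:
    """Write as one NIfTI per (run, condition) plus mask and JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask_nifti(dataset.mask, dataset.grid, out_dir / "mask.nii")
    cells = []
    for (run, cond), vec in sorted(dataset.patterns.items()):
        fname = f"pattern_run-{run}_cond-{cond}.nii"
        vol = vector_to_volume(vec, dataset.mask, fill=0.0)
        nib.save(
            nib.Nifti1Image(vol.astype(np.float64), dataset.grid.affine),
            str(out_dir / fname),
        )
        cells.append({"run": run, "condition": cond, "file": fname})
    manifest = {
        "format": "mvpattern-dataset",
        "mask": "mask.nii",
        "cells": cells,
        "provenance": dataset.provenance,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


def _read_nifti_dataset(manifest_path: Path) -> PatternDataset:
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    mask, grid = read_mask_nifti(root / manifest["mask"])
    patterns = {}
    for cell in manifest["cells"]:
        img = nib.load(str(root / cell["file"]))
        data = np.asanyarray(img.dataobj)
        cell_grid = _grid_from_affine(img.affine, data.shape)
        if cell_grid != grid:
            raise ValueError(
                f"grid mismatch: {cell['file']} has {cell_grid}, mask has {grid}"
            )
        vec = volume_to_vector(data.astype(float), mask)
        if np.any(~np.isfinite(vec)):
            raise ValueError(f"NaN/inf voxels inside mask in {cell['file']}")
        patterns[(int(cell["run"]), str(cell["condition"]))] = vec
    ds = PatternDataset(
        grid=grid, mask=mask, patterns=patterns,
        provenance=manifest.get("provenance", ""),
    )
    _check_complete(ds)
    return ds


def _check_complete(ds: PatternDataset) -> None:
    for r in ds.runs:
        for c in ds.conditions:
            if (r, c) not in ds.patterns:
                raise ValueError(f"incomplete dataset: missing (run={r}, condition={c!r})")


def write_pattern_dataset_tsv(dataset: PatternDataset, path) -> Path:
    """Flat TSV encoding (plus ``<path>.json`` geometry sidecar)."""
    path = Path(path)
    coords = dataset.voxel_coords()
    cols = {"x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
    for (run, cond), vec in sorted(dataset.patterns.items()):
        cols[f"run{run}:{cond}"] = vec
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "dims": list(dataset.grid.dims),
        "voxel_size_mm": list(dataset.grid.voxel_size_mm),
        "origin": list(dataset.grid.origin),
        "provenance": dataset.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_tsv_dataset(path: Path) -> PatternDataset:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    grid = VolumeGrid(
        dims=tuple(sidecar["dims"]),
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
        origin=tuple(sidecar.get("origin", (0.0, 0.0, 0.0))),
    )
    df = pd.read_csv(path, sep="\t")
    mask = np.zeros(grid.dims, bool)
    mask[df["x"], df["y"], df["z"]] = True
    # rows may be in any order on disk; sort into the package flat order
    flat = np.ravel_multi_index(
        (df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy()),
        grid.dims,
        order="F",
    )
    order = np.argsort(flat)
    patterns = {}
    for col in df.columns:
        if not col.startswith("run"):
            continue
        run_s, cond = col.split(":", 1)
        vec = df[col].to_numpy(float)[order]
        if np.any(~np.isfinite(vec)):
            raise ValueError(f"NaN/inf values in column {col!r}")
        patterns[(int(run_s[3:]), cond)] = vec
    ds = PatternDataset(grid=grid, mask=mask, patterns=patterns,
                        provenance=sidecar.get("provenance", ""))
    _check_complete(ds)
    return ds


def read_pattern_dataset(path) -> PatternDataset:
    """Read either encoding: a manifest.json (or its directory) or a TSV."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    if path.suffix == ".json":
        return _read_nifti_dataset(path)
    if path.suffix in (".tsv", ".txt"):
        return _read_tsv_dataset(path)
    raise ValueError(f"unrecognized dataset path {path}")


def rsm_to_tsv(items, values: np.ndarray, path) -> None:
    """Serialize an RSM (neural or model) with item labels as a TSV."""
    labels = [f"{c}:r{r}" for c, r in items]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def rsm_from_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    items = tuple(
        (lab.rsplit(":r", 1)[0], int(lab.rsplit(":r", 1)[1])) for lab in df.index
    )
    return items, df.to_numpy(float)


def write_stat_map(stat_map, path) -> None:
    nib.save(
        nib.Nifti1Image(stat_map.values.astype(np.float64), stat_map.grid.affine),
        str(path),
    )


def read_stat_map(path, statistic_name: str = ""):
    from .searchlight import StatMap

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    return StatMap(
        grid=_grid_from_affine(img.affine, data.shape),
        values=data,
        statistic_name=statistic_name,
    )
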