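"""Reading and writing image/label volumes in standard formats.

Volumes are 3D grayscale grids indexed ``(z, y, x)`` — the serial-section
convention: ``z`` walks through sections, ``y``/``x`` are the in-plane axes.
Per-axis voxel size is carried in nanometres as ``(z, y, x)``; serial-section
EM is typically strongly anisotropic (e.g. 8x8 nm in plane, 50 nm sections).

Supported containers: multi-page TIFF, a directory of per-slice 2D images in
lexical order, and HDF5 (one dataset per volume).  TIFF and slice directories
carry no voxel-size metadata, so a small JSON sidecar (``<file>.meta.json``)
is written next to them; HDF5 stores voxel size as a dataset attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "LabelGrid",
    "FormatError",
    "read_volume",
    "write_volume",
]

_SLICE_SUFFIXES = (".tif", ".tiff", ".png")
_DEFAULT_H5_DATASET = "volume"


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk volumes."""


def _check_voxel_size(voxel_size: Sequence[float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive floats (z,y,x), got {voxel_size!r}")
    return vs


@dataclass
class VoxelGrid:
    """A 3D scalar intensity grid with per-axis voxel size in nm.

    ``values`` is indexed ``(z, y, x)``.  Raw volumes are 8-bit unsigned;
    preprocessed volumes are floating point.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a non-empty 3D (z,y,x) array, got shape {self.values.shape}")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelGrid:
    """Binary mask aligned voxel-for-voxel with a companion :class:`VoxelGrid`.

    One grid per organelle class; conventional class names in the source
    datasets are ``N`` (neurites), ``M`` (mitochondria), ``ER`` (endoplasmic
    reticulum) and ``LD`` (lipid droplets), but any name is accepted.
    """

    values: np.ndarray
    class_name: str = "M"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a non-empty 3D (z,y,x) array, got shape {self.values.shape}")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"label values must be binary {{0,1}}, found {uniq[:10]}")
        self.values = self.values.astype(np.uint8)
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_sidecar(path: Path, voxel_size: Sequence[float]) -> None:
    meta = {"voxel_size_nm_zyx": list(voxel_size), "axis_order": "zyx"}
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_sidecar(path: Path) -> tuple[float, float, float] | None:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    meta = json.loads(sc.read_text())
    vs = meta.get("voxel_size_nm_zyx")
    return _check_voxel_size(vs) if vs is not None else None


# ---------------------------------------------------------------------------
# readers / writers


def _read_slice_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
    if not files:
        raise FormatError(f"no 2D slice images (tif/png) found in directory {path}")
    slices = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise FormatError(f"slice {f.name} is not a single-channel 2D image (shape {img.shape})")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    return np.stack(slices, axis=0)


def read_volume(
    path: str | Path,
    voxel_size: Sequence[float] | None = None,
    *,
    dataset: str = _DEFAULT_H5_DATASET,
) -> VoxelGrid:
    """Read a volume from TIFF stack, per-slice directory, or HDF5.

    Slices are stacked along Z in file order (lexical order for directories).
    ``voxel_size`` overrides any voxel size found in file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume path does not exist: {path}")

    meta_vs: tuple[float, float, float] | None = None
    if path.is_dir():
        values = _read_slice_dir(path)
        meta_vs = _read_sidecar(path)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise FormatError(f"dataset {dataset!r} not found in {path}; has {list(f)}")
            ds = f[dataset]
            values = ds[...]
            if "voxel_size_nm_zyx" in ds.attrs:
                meta_vs = _check_voxel_size(ds.attrs["voxel_size_nm_zyx"])
    else:
        values = tifffile.imread(path)
        meta_vs = _read_sidecar(path)

    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.ndim != 3:
        raise FormatError(f"expected a 3D volume in {path}, got shape {values.shape}")

    vs = _check_voxel_size(voxel_size) if voxel_size is not None else (meta_vs or (1.0, 1.0, 1.0))
    return VoxelGrid(values=values, voxel_size=vs)


def write_volume(grid: VoxelGrid | LabelGrid, path: str | Path, *, dataset: str = _DEFAULT_H5_DATASET) -> None:
    """Write a volume as multi-page TIFF or HDF5 (by extension).

    Integer grids round-trip losslessly; float grids are stored at 32-bit
    precision.  Voxel size goes to an HDF5 attribute or a JSON sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = grid.values
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)

    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=values)
            ds.attrs["voxel_size_nm_zyx"] = list(grid.voxel_size)
            if isinstance(grid, LabelGrid):
                ds.attrs["class_name"] = grid.class_name
    else:
        tifffile.imwrite(path, values, photometric="minisblack")
        _write_sidecar(path, grid.voxel_size)


def write_table(rows: "Mapping[str, Sequence] | object", path: str | Path) -> None:
    """Write an experiment table to CSV (accepts a DataFrame or column mapping)."""
    import pandas as pd

    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
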