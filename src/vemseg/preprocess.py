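"""Volume normalization, rescaling, patching and stitching.

The preprocessing pipeline mirrors standard practice for serial-section EM
segmentation: per-slice contrast-limited adaptive histogram equalization
(CLAHE) to flatten section-to-section contrast, a light per-slice Gaussian
blur, global standardization to zero mean / unit variance, resolution
rescaling so object sizes are comparable across datasets, and tiling into
fixed-size patches — (18, 160, 160) in (z, y, x), i.e. 160x160x18 in the
X-Y-Z order segmentation tools usually quote — for the network.

Everything here is (z, y, x) indexed.  Patch windows are half-open
``[origin, origin + shape)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure

from .volume_io import LabelGrid, VoxelGrid

__all__ = [
    "PatchSpec",
    "Patch",
    "CoverageError",
    "clahe_slice",
    "normalize",
    "rescale",
    "tile",
    "tile_origins",
    "patch_count",
    "stitch",
    "save_patches",
    "load_patches",
    "subsample_fraction",
]


class CoverageError(ValueError):
    """Stitching input does not cover the requested output volume."""


@dataclass(frozen=True)
class PatchSpec:
    """Windowing scheme for tiling a volume into network inputs.

    ``border_policy``: ``"drop"`` discards incomplete windows at the far
    borders (used for patch counting / training sets); ``"reflect"``
    reflect-pads the volume so every voxel is covered (used for whole-volume
    inference).
    """

    patch_shape: tuple[int, int, int] = (18, 160, 160)
    stride: tuple[int, int, int] | None = None  # None -> non-overlapping
    border_policy: str = "drop"

    def __post_init__(self) -> None:
        ps = tuple(int(p) for p in self.patch_shape)
        if len(ps) != 3 or min(ps) < 1:
            raise ValueError(f"patch_shape must be 3 positive ints, got {self.patch_shape!r}")
        st = ps if self.stride is None else tuple(int(s) for s in self.stride)
        if len(st) != 3 or any(not (1 <= s <= p) for s, p in zip(st, ps)):
            raise ValueError(f"stride must satisfy 1 <= stride <= patch_shape, got {self.stride!r}")
        if self.border_policy not in ("drop", "reflect"):
            raise ValueError(f"border_policy must be 'drop' or 'reflect', got {self.border_policy!r}")
        object.__setattr__(self, "patch_shape", ps)
        object.__setattr__(self, "stride", st)


@dataclass
class Patch:
    """An extracted window and the (z,y,x) index of its first voxel."""

    data: np.ndarray
    origin: tuple[int, int, int]


# ---------------------------------------------------------------------------
# intensity normalization


def clahe_slice(
    img: np.ndarray,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
    value_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one 2D slice.

    The slice is equalized on a ``tile_grid`` of contextual regions with the
    histogram clipped at ``clip_limit`` (normalized).  Output stays within
    ``value_range``; a constant slice is returned unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"clahe_slice expects a 2D slice, got shape {img.shape}")
    if tile_grid[0] > img.shape[0] or tile_grid[1] > img.shape[1]:
        raise ValueError(f"tile_grid {tile_grid} larger than image {img.shape}")
    lo, hi = value_range
    if hi <= lo:
        raise ValueError("value_range must be increasing")
    if img.min() < lo or img.max() > hi:
        raise ValueError("image values fall outside the declared value_range")
    if np.ptp(img) == 0:
        return img.copy()
    unit = (img - lo) / (hi - lo)
    kernel = (max(1, img.shape[0] // tile_grid[0]), max(1, img.shape[1] // tile_grid[1]))
    eq = exposure.equalize_adapthist(unit, kernel_size=kernel, clip_limit=clip_limit)
    return lo + eq * (hi - lo)


def normalize(
    grid: VoxelGrid,
    blur_sigma: float = 1.0,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
    apply_clahe: bool = True,
) -> VoxelGrid:
    """Per-slice CLAHE, per-slice 2D Gaussian blur, then global z-score.

    The standardization is global (one affine transform for the whole
    volume), since CLAHE already equalizes local contrast.  Raises if the
    volume has zero variance (cannot standardize).
    """
    vals = np.asarray(grid.values, dtype=np.float64)
    if np.issubdtype(grid.values.dtype, np.integer):
        vals = vals / float(np.iinfo(grid.values.dtype).max)
    out = np.empty_like(vals)
    for zi in range(vals.shape[0]):
        sl = vals[zi]
        if apply_clahe:
            sl = clahe_slice(sl, clip_limit=clip_limit, tile_grid=tile_grid)
        if blur_sigma > 0:
            sl = ndimage.gaussian_filter(sl, sigma=blur_sigma, mode="nearest")
        out[zi] = sl
    sd = out.std()
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance volume")
    out = (out - out.mean()) / sd
    return VoxelGrid(values=out, voxel_size=grid.voxel_size)


# ---------------------------------------------------------------------------
# resolution rescaling


def rescale(
    grid: VoxelGrid | LabelGrid,
    src_res: Sequence[float],
    dst_res: Sequence[float],
    is_label: bool | None = None,
) -> VoxelGrid | LabelGrid:
    """Resample to a new voxel size (nm per axis, (z,y,x)).

    Scale factor per axis is ``src/dst``.  Images use linear interpolation,
    labels nearest-neighbour (so masks stay binary).  The output carries
    ``dst_res`` as its voxel size.
    """
    src = np.asarray(src_res, dtype=float)
    dst = np.asarray(dst_res, dtype=float)
    if (src <= 0).any() or (dst <= 0).any():
        raise ValueError("resolutions must be positive")
    factors = src / dst
    if not np.isfinite(factors).all():
        raise ValueError(f"non-finite scale factor from {src_res} -> {dst_res}")
    if is_label is None:
        is_label = isinstance(grid, LabelGrid)

    if np.allclose(factors, 1.0):
        out_vals = grid.values.copy()
    else:
        order = 0 if is_label else 1
        vals = grid.values.astype(np.float64) if not is_label else grid.values
        out_vals = ndimage.zoom(vals, zoom=factors, order=order, mode="nearest", prefilter=False)
        if is_label:
            out_vals = (out_vals > 0).astype(np.uint8)

    vs = tuple(float(d) for d in dst)
    if is_label:
        cname = grid.class_name if isinstance(grid, LabelGrid) else "label"
        return LabelGrid(values=out_vals, class_name=cname, voxel_size=vs)
    return VoxelGrid(values=out_vals, voxel_size=vs)


# ---------------------------------------------------------------------------
# patching


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    if extent < patch:
        return []
    return list(range(0, extent - patch + 1, stride))


def patch_count(volume_shape: Sequence[int], spec: PatchSpec) -> int:
    """Number of patches a drop-incomplete tiling yields (pure arithmetic)."""
    n = 1
    for ext, p, s in zip(volume_shape, spec.patch_shape, spec.stride):
        n *= len(_axis_origins(int(ext), p, s))
    return n


def tile_origins(volume_shape: Sequence[int], spec: PatchSpec) -> list[tuple[int, int, int]]:
    """Patch origins in (z,y,x)-major order; for 'reflect' the padded extent."""
    shape = [int(s) for s in volume_shape]
    if spec.border_policy == "reflect":
        shape = [_padded_extent(e, p, s) for e, p, s in zip(shape, spec.patch_shape, spec.stride)]
    axes = [_axis_origins(e, p, s) for e, p, s in zip(shape, spec.patch_shape, spec.stride)]
    return [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]


def _padded_extent(extent: int, patch: int, stride: int) -> int:
    if extent <= patch:
        return patch
    steps = math.ceil((extent - patch) / stride)
    return patch + steps * stride


def _reflect_pad(values: np.ndarray, spec: PatchSpec) -> np.ndarray:
    pads = []
    for ext, p, s in zip(values.shape, spec.patch_shape, spec.stride):
        pads.append((0, _padded_extent(ext, p, s) - ext))
    if any(p[1] for p in pads):
        # reflect needs extent >= 2; fall back to edge for singleton axes
        mode = "reflect" if all(e >= 2 for e in values.shape) else "edge"
        values = np.pad(values, pads, mode=mode)
    return values


def tile(grid: VoxelGrid | LabelGrid | np.ndarray, spec: PatchSpec) -> list[Patch]:
    """Tile a volume into patches per the spec, in (z,y,x)-major order.

    With ``drop`` borders and stride equal to patch shape the patch count per
    axis is ``floor(extent / patch_extent)``; a volume smaller than one patch
    yields an empty list.
    """
    values = grid if isinstance(grid, np.ndarray) else grid.values
    if spec.border_policy == "reflect":
        values = _reflect_pad(values, spec)
    pz, py, px = spec.patch_shape
    return [
        Patch(data=values[z : z + pz, y : y + py, x : x + px].copy(), origin=(z, y, x))
        for (z, y, x) in tile_origins(values.shape, spec)
    ]


def stitch(
    patches: Iterable[tuple[tuple[int, int, int], np.ndarray] | Patch],
    out_shape: Sequence[int],
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> VoxelGrid:
    """Assemble per-patch predictions into a volume by voxelwise averaging.

    Overlapping patches are averaged; patches extending past ``out_shape``
    (from reflect-padded tiling) are cropped.  Voxels covered by no patch are
    an error listing the gap.
    """
    out_shape = tuple(int(s) for s in out_shape)
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int32)
    for item in patches:
        origin, data = (item.origin, item.data) if isinstance(item, Patch) else item
        data = np.asarray(data)
        z, y, x = (int(o) for o in origin)
        ez, ey, ex = (min(o + d, s) for o, d, s in zip((z, y, x), data.shape, out_shape))
        if ez <= z or ey <= y or ex <= x:
            continue
        acc[z:ez, y:ey, x:ex] += data[: ez - z, : ey - y, : ex - x]
        cnt[z:ez, y:ey, x:ex] += 1
    if (cnt == 0).any():
        gaps = np.argwhere(cnt == 0)
        lo, hi = gaps.min(axis=0), gaps.max(axis=0)
        raise CoverageError(
            f"{len(gaps)} voxels uncovered; gap bounding box (z,y,x) {tuple(lo)}..{tuple(hi)}"
        )
    return VoxelGrid(values=acc / cnt, voxel_size=tuple(float(v) for v in voxel_size))


def save_patches(patches: Sequence[Patch], path) -> None:
    """Persist a patch set as HDF5: one stacked data array plus origins."""
    import h5py

    patches = list(patches)
    if not patches:
        raise ValueError("cannot save an empty patch set")
    from pathlib import Path as _Path

    p = _Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(p, "w") as f:
        f.create_dataset("data", data=np.stack([pt.data for pt in patches]))
        f.create_dataset("origins", data=np.array([pt.origin for pt in patches], dtype=np.int64))


def load_patches(path) -> list[Patch]:
    """Read a patch set written by :func:`save_patches`."""
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][...]
        origins = f["origins"][...]
    return [Patch(data=d, origin=tuple(int(o) for o in org)) for d, org in zip(data, origins)]


def subsample_fraction(patches: Sequence, fraction: float, seed: int) -> list:
    """Uniform random subset (without replacement) of ``round(fraction * n)``.

    Deterministic given ``seed``; emulates restricting the target-task
    training set to a fraction of its patches (label scarcity).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(patches)
    if n == 0:
        raise ValueError("cannot subsample an empty patch list")
    k = int(round(fraction * n))
    k = max(k, 1)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [patches[i] for i in idx]
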