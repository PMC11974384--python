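"""Synthetic anisotropic EM-like volumes with ground-truth organelle masks.

Serial-section electron microscopy of tissue produces grayscale stacks with
fine in-plane resolution and coarse section spacing, heavy-metal-stained
organelles darker than cytosol, and stack-level artifacts: per-section
brightness variation, small per-section misalignment, and noise.  This module
emulates those properties well enough that the whole downstream pipeline —
preprocessing, patching, network training, the pretrain/fine-tune transfer
experiment, evaluation and meshing — can run end to end with no external data.

Three foreground morphologies are provided, named for what they imitate:

* rotund textured blobs (mitochondria-like): random-orientation ellipsoids
  with a sinusoidal internal stripe texture imitating cristae;
* thin branching tubules (ER-like): sparse random-walk tube networks;
* long spanning tubes (neurite-like): thick tubes crossing the volume.

The scene is rendered as: per-class flat intensity (foreground darker than
background, the heavy-metal stain convention) + intra-blob texture, blurred
by an anisotropic Gaussian PSF, then per-slice brightness drift, per-slice
integer misalignment (applied identically to image and labels), and additive
Gaussian noise, in that order.

A single integer seed drives every stochastic stage through a named
sub-stream, so stages are individually reproducible and regenerating with the
same config is bit-for-bit identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .volume_io import LabelGrid, VoxelGrid, write_volume

__all__ = [
    "ConfigurationError",
    "BlobClass",
    "TubuleClass",
    "TubeClass",
    "SceneConfig",
    "SyntheticDataset",
    "generate_scene",
    "make_domain_pair",
    "save_dataset",
]


class ConfigurationError(ValueError):
    """Invalid scene configuration (non-positive shape, negative rate, ...)."""


# Named sub-streams of the master seed, one per stochastic stage.
_STAGES = {"blob": 1, "tubule": 2, "tube": 3, "texture": 4, "drift": 5, "misalign": 6, "noise": 7}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), _STAGES[stage])))


@dataclass
class BlobClass:
    """Rotund textured blobs — mitochondria-like ellipsoids.

    ``count`` ellipsoids with semi-axes drawn around ``semi_axes_nm`` at random
    3D orientation; ``intensity`` is the flat rendered gray level (darker than
    background).
    """

    count: int = 12
    semi_axes_nm: tuple[float, float, float] = (400.0, 250.0, 250.0)
    size_jitter: float = 0.25  # relative spread of semi-axis lengths
    intensity: float = 0.30
    kind: str = "blob"


@dataclass
class TubuleClass:
    """Thin branching tubules — ER-like random-walk networks.

    ``density`` seeds independent persistent random walks; each walk deposits
    overlapping spheres of radius ``radius_nm`` along its path.
    """

    density: int = 4
    radius_nm: float = 60.0
    steps: int = 160
    turn_sigma: float = 0.35  # direction jitter per step (radians-ish)
    intensity: float = 0.42
    kind: str = "tubule"


@dataclass
class TubeClass:
    """Long spanning tubes — neurite-like processes crossing the volume."""

    count: int = 6
    radius_nm: float = 180.0
    tilt: float = 0.15  # off-axis tilt of the tube direction
    intensity: float = 0.36
    kind: str = "tube"


@dataclass
class SceneConfig:
    """Full description of one synthetic scene; regeneration is deterministic."""

    grid_shape: tuple[int, int, int] = (16, 96, 96)  # (z, y, x) voxels
    # nm; anisotropic, at the working resolution volumes are rescaled to
    # before patching (coarse Z from section thickness, ~4x binned XY)
    voxel_size: tuple[float, float, float] = (40.0, 32.0, 32.0)
    class_params: Mapping[str, BlobClass | TubuleClass | TubeClass] = field(
        default_factory=lambda: {"M": BlobClass()}
    )
    texture_period_nm: float = 240.0
    texture_contrast: float = 0.35
    background: float = 0.75
    psf_sigma_vox: float = 0.7  # per-axis sigma in voxel units -> broader in nm along Z
    noise_sigma: float = 0.05
    slice_brightness_drift: float = 0.04
    misalign_max_px: int = 1
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive ints, got {self.grid_shape!r}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 positive floats, got {self.voxel_size!r}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.misalign_max_px < 0:
            raise ConfigurationError("misalign_max_px must be >= 0")
        if self.slice_brightness_drift < 0:
            raise ConfigurationError("slice_brightness_drift must be >= 0")
        if self.texture_period_nm <= 0:
            raise ConfigurationError("texture_period_nm must be > 0")
        for name, cp in self.class_params.items():
            n = cp.count if hasattr(cp, "count") else cp.density  # type: ignore[union-attr]
            if n < 0:
                raise ConfigurationError(f"class {name!r}: count/density must be >= 0")
            if getattr(cp, "radius_nm", 1.0) <= 0 or min(getattr(cp, "semi_axes_nm", (1.0,))) <= 0:
                raise ConfigurationError(f"class {name!r}: sizes must be > 0")


@dataclass
class SyntheticDataset:
    """A rendered image volume plus one binary mask per organelle class."""

    image: VoxelGrid
    labels: dict[str, LabelGrid]
    config: SceneConfig

    def __post_init__(self) -> None:
        for name, lab in self.labels.items():
            if lab.shape != self.image.shape or lab.voxel_size != self.image.voxel_size:
                raise ValueError(f"label {name!r} not aligned with image grid")


# ---------------------------------------------------------------------------
# rasterizers (nm-aware: distances are computed in physical units)


def _coords_nm(shape, voxel_size):
    z = np.arange(shape[0]) * voxel_size[0]
    y = np.arange(shape[1]) * voxel_size[1]
    x = np.arange(shape[2]) * voxel_size[2]
    return z, y, x


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _raster_ellipsoid(mask, center_nm, rot, semi_nm, voxel_size) -> None:
    """Set mask voxels inside a rotated ellipsoid (center/semi-axes in nm)."""
    shape = mask.shape
    rmax = max(semi_nm)
    lo = [max(0, int((center_nm[i] - rmax) / voxel_size[i]) - 1) for i in range(3)]
    hi = [min(shape[i], int((center_nm[i] + rmax) / voxel_size[i]) + 2) for i in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = (np.arange(lo[0], hi[0]) * voxel_size[0] - center_nm[0])[:, None, None]
    yy = (np.arange(lo[1], hi[1]) * voxel_size[1] - center_nm[1])[None, :, None]
    xx = (np.arange(lo[2], hi[2]) * voxel_size[2] - center_nm[2])[None, None, :]
    # rotate displacement into the ellipsoid frame and scale by semi-axes
    d0 = rot[0, 0] * zz + rot[0, 1] * yy + rot[0, 2] * xx
    d1 = rot[1, 0] * zz + rot[1, 1] * yy + rot[1, 2] * xx
    d2 = rot[2, 0] * zz + rot[2, 1] * yy + rot[2, 2] * xx
    inside = (d0 / semi_nm[0]) ** 2 + (d1 / semi_nm[1]) ** 2 + (d2 / semi_nm[2]) ** 2 <= 1.0
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= inside


def _raster_sphere(mask, center_nm, radius_nm, voxel_size) -> None:
    _raster_ellipsoid(mask, center_nm, np.eye(3), (radius_nm,) * 3, voxel_size)


def _blob_mask(cfg: SceneConfig, params: BlobClass, rng) -> np.ndarray:
    shape = tuple(cfg.grid_shape)
    extent = np.array(shape) * np.array(cfg.voxel_size)
    mask = np.zeros(shape, dtype=bool)
    # one blob per loop iteration: draws are prefix-stable, so increasing
    # `count` only adds blobs (label fraction monotone in count)
    for _ in range(int(params.count)):
        center = rng.uniform(0, 1, size=3) * extent
        rot = _random_rotation(rng)
        jit = 1.0 + params.size_jitter * rng.uniform(-1, 1, size=3)
        semi = np.asarray(params.semi_axes_nm) * jit
        _raster_ellipsoid(mask, center, rot, semi, cfg.voxel_size)
    return mask


def _tubule_mask(cfg: SceneConfig, params: TubuleClass, rng) -> np.ndarray:
    shape = tuple(cfg.grid_shape)
    extent = np.array(shape) * np.array(cfg.voxel_size)
    mask = np.zeros(shape, dtype=bool)
    step_nm = max(params.radius_nm, min(cfg.voxel_size))
    for _ in range(int(params.density)):
        pos = rng.uniform(0, 1, size=3) * extent
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(int(params.steps)):
            _raster_sphere(mask, pos, params.radius_nm, cfg.voxel_size)
            direction = direction + params.turn_sigma * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = np.clip(pos + step_nm * direction, 0, extent)
    return mask


def _tube_mask(cfg: SceneConfig, params: TubeClass, rng) -> np.ndarray:
    shape = tuple(cfg.grid_shape)
    z, y, x = _coords_nm(shape, cfg.voxel_size)
    extent = np.array(shape) * np.array(cfg.voxel_size)
    P = np.stack(np.meshgrid(z, y, x, indexing="ij"), axis=-1)  # (Z,Y,X,3) nm
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(params.count)):
        axis = int(rng.integers(1, 3))  # span along y or x (in-plane processes)
        direction = params.tilt * rng.normal(size=3)
        direction[axis] = 1.0
        direction /= np.linalg.norm(direction)
        anchor = rng.uniform(0, 1, size=3) * extent
        anchor[axis] = 0.0
        d = P - anchor
        t = d @ direction
        perp = d - t[..., None] * direction
        mask |= (perp**2).sum(-1) <= params.radius_nm**2
    return mask


_RASTERIZERS = {"blob": _blob_mask, "tubule": _tubule_mask, "tube": _tube_mask}


# ---------------------------------------------------------------------------
# scene assembly


def generate_scene(config: SceneConfig) -> SyntheticDataset:
    """Render one synthetic scene: masks, image, PSF, artifacts, noise."""
    config.validate()
    shape = tuple(int(s) for s in config.grid_shape)
    vs = tuple(float(v) for v in config.voxel_size)

    masks: dict[str, np.ndarray] = {}
    for name, cp in config.class_params.items():
        rng = _stage_rng(config.seed, cp.kind)
        masks[name] = _RASTERIZERS[cp.kind](config, cp, rng)

    img = np.full(shape, config.background, dtype=np.float64)
    tex_rng = _stage_rng(config.seed, "texture")
    stripe_dir = tex_rng.normal(size=3)
    stripe_dir /= np.linalg.norm(stripe_dir)
    z, y, x = _coords_nm(shape, vs)
    phase = (
        z[:, None, None] * stripe_dir[0]
        + y[None, :, None] * stripe_dir[1]
        + x[None, None, :] * stripe_dir[2]
    )
    stripes = 1.0 + config.texture_contrast * np.sin(2 * np.pi * phase / config.texture_period_nm)

    for name, cp in config.class_params.items():
        m = masks[name]
        img[m] = cp.intensity
        if cp.kind == "blob":  # cristae-like internal stripes
            img[m] *= stripes[m]

    if config.psf_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma=config.psf_sigma_vox, mode="nearest")

    drift_rng = _stage_rng(config.seed, "drift")
    if config.slice_brightness_drift > 0:
        offsets = drift_rng.uniform(-config.slice_brightness_drift, config.slice_brightness_drift, size=shape[0])
        img += offsets[:, None, None]

    mis_rng = _stage_rng(config.seed, "misalign")
    if config.misalign_max_px > 0:
        m = int(config.misalign_max_px)
        shifts = mis_rng.integers(-m, m + 1, size=(shape[0], 2))
        for zi in range(shape[0]):
            dy, dx = int(shifts[zi, 0]), int(shifts[zi, 1])
            if dy == 0 and dx == 0:
                continue
            img[zi] = ndimage.shift(img[zi], (dy, dx), order=0, mode="nearest")
            for name in masks:
                masks[name][zi] = ndimage.shift(masks[name][zi], (dy, dx), order=0, mode="nearest")

    noise_rng = _stage_rng(config.seed, "noise")
    if config.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, config.noise_sigma, size=shape)

    img = np.clip(img, 0.0, 1.0)
    labels = {
        name: LabelGrid(values=m.astype(np.uint8), class_name=name, voxel_size=vs)
        for name, m in masks.items()
    }
    return SyntheticDataset(image=VoxelGrid(values=img, voxel_size=vs), labels=labels, config=config)


def make_domain_pair(
    source_cfg: SceneConfig, target_cfg: SceneConfig
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Generate a (source, target) dataset pair for a transfer scenario.

    The configs may differ in imaging parameters (domain shift), in which
    organelle class is present (task shift), or both — the three scenarios of
    the transfer experiment.  Identical seeds would make the two volumes
    correlated realizations, leaking data between source and target, so they
    are rejected.
    """
    if source_cfg.seed == target_cfg.seed:
        raise ConfigurationError("source and target configs must use different seeds (data leak)")
    return generate_scene(source_cfg), generate_scene(target_cfg)


def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write image + per-class label TIFFs and the scene config YAML."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    img_path = out / "image.tif"
    write_volume(
        VoxelGrid((np.clip(ds.image.values, 0, 1) * 255).astype(np.uint8), ds.image.voxel_size),
        img_path,
    )
    paths["image"] = img_path
    for name, lab in ds.labels.items():
        p = out / f"label_{name}.tif"
        write_volume(lab, p)
        paths[f"label_{name}"] = p
    cfg = asdict(ds.config)
    cfg["class_params"] = {k: asdict(v) for k, v in ds.config.class_params.items()}
    cfg_path = out / "scene.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths["config"] = cfg_path
    return paths
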