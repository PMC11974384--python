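import numpy as np
import pytest

from vemseg.preprocess import (
    CoverageError,
    Patch,
    PatchSpec,
    clahe_slice,
    normalize,
    patch_count,
    rescale,
    stitch,
    subsample_fraction,
    tile,
)
from vemseg.volume_io import LabelGrid, VoxelGrid


# ---------------------------------------------------------------------------
# CLAHE


def test_clahe_constant_slice_unchanged():
    img = np.full((32, 32), 0.4)
    np.testing.assert_array_equal(clahe_slice(img), img)


def test_clahe_preserves_value_range(rng):
    img = rng.random((64, 64))
    out = clahe_slice(img, clip_limit=0.02, tile_grid=(4, 4))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_clahe_single_tile_no_clip_matches_global_equalization(rng):
    """Limiting case: one tile + clip 1.0 reduces CLAHE to plain histogram
    equalization, which has a closed-form empirical-CDF oracle."""
    img = rng.random((64, 64))
    out = clahe_slice(img, clip_limit=1.0, tile_grid=(1, 1))
    flat = np.sort(img.ravel())
    cdf = np.searchsorted(flat, img, side="right") / img.size
    cdf_min = 1.0 / img.size
    oracle = (cdf - cdf_min) / (1.0 - cdf_min)
    assert np.abs(out - oracle).max() <= 2.0 / 256  # within ~1 intensity level


def test_clahe_tile_grid_larger_than_image_raises():
    with pytest.raises(ValueError, match="tile_grid"):
        clahe_slice(np.zeros((8, 8)), tile_grid=(16, 16))


# ---------------------------------------------------------------------------
# normalize


def test_normalize_standardizes_globally(blob_scene):
    out = normalize(blob_scene.image)
    assert abs(out.values.mean()) < 1e-5
    assert abs(out.values.std() - 1) < 1e-5


def test_normalize_blur_zero_is_identity(rng):
    vals = rng.random((3, 32, 32))
    grid = VoxelGrid(vals)
    out = normalize(grid, blur_sigma=0.0, apply_clahe=False)
    expect = (vals - vals.mean()) / vals.std()
    np.testing.assert_allclose(out.values, expect, atol=1e-12)


def test_normalize_impulse_blur_matches_gaussian_kernel():
    vals = np.zeros((1, 33, 33))
    vals[0, 16, 16] = 1.0
    out = normalize(VoxelGrid(vals), blur_sigma=1.0, apply_clahe=False)
    # closed-form sampled Gaussian, truncated like the implementation (4 sigma)
    r = np.arange(-16, 17)
    k1 = np.exp(-(r**2) / 2.0)
    k1[np.abs(r) > 4] = 0.0
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    blurred = out.values[0]
    expect = (kernel - kernel.mean()) / kernel.std()
    np.testing.assert_allclose(blurred, expect, atol=1e-6)


def test_standardization_is_idempotent(rng):
    vals = rng.random((3, 16, 16))
    once = normalize(VoxelGrid(vals), blur_sigma=0.0, apply_clahe=False)
    twice = normalize(once, blur_sigma=0.0, apply_clahe=False)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


def test_normalize_zero_variance_raises():
    with pytest.raises(ValueError, match="zero-variance"):
        normalize(VoxelGrid(np.full((2, 16, 16), 0.5)), apply_clahe=False)


# ---------------------------------------------------------------------------
# rescale


def test_rescale_identity_at_equal_resolution(rng):
    vals = rng.random((4, 8, 8))
    out = rescale(VoxelGrid(vals), (40, 8, 8), (40, 8, 8))
    np.testing.assert_array_equal(out.values, vals)
    assert out.voxel_size == (40.0, 8.0, 8.0)


def test_rescale_constant_downscale():
    vals = np.full((1, 2, 2), 3.5)
    out = rescale(VoxelGrid(vals), (1, 1, 1), (1, 2, 2))
    assert out.values.shape == (1, 1, 1)
    np.testing.assert_allclose(out.values, 3.5)


def test_rescale_linear_ramp_matches_interp_oracle():
    ramp = np.arange(4, dtype=np.float64)[None, None, :]
    out = rescale(VoxelGrid(ramp), (1, 1, 2), (1, 1, 1))
    n_out = out.values.shape[2]
    oracle = np.interp(np.linspace(0, 3, n_out), np.arange(4), np.arange(4))
    np.testing.assert_allclose(out.values[0, 0], oracle, atol=1e-6)


def test_rescale_labels_stay_binary():
    lab = LabelGrid((np.arange(64).reshape(1, 8, 8) % 2).astype(np.uint8))
    out = rescale(lab, (1, 2, 2), (1, 1, 1))
    assert set(np.unique(out.values)) <= {0, 1}
    assert isinstance(out, LabelGrid)


def test_rescale_round_trip_close_on_smooth_input():
    z, y, x = np.meshgrid(np.arange(4), np.arange(16), np.arange(16), indexing="ij")
    vals = np.sin(x / 5.0) + np.cos(y / 7.0) + 0.1 * z
    up = rescale(VoxelGrid(vals), (1, 2, 2), (1, 1, 1))
    back = rescale(up, (1, 1, 1), (1, 2, 2))
    assert back.values.shape == vals.shape
    assert np.abs(back.values - vals).mean() < 0.01


def test_rescale_invalid_resolution_raises():
    with pytest.raises(ValueError):
        rescale(VoxelGrid(np.zeros((2, 2, 2))), (0, 1, 1), (1, 1, 1))


# ---------------------------------------------------------------------------
# tiling / stitching


def test_mouse_liver_geometry_patch_count():
    # 12000x8000 px, 180 slices, rescaled 8->32 nm in XY, (18,160,160) windows
    spec = PatchSpec(patch_shape=(18, 160, 160))
    assert patch_count((180, 2000, 3000), spec) == 2160


def test_single_patch_volume():
    spec = PatchSpec(patch_shape=(4, 8, 8))
    patches = tile(np.ones((4, 8, 8)), spec)
    assert len(patches) == 1 and patches[0].origin == (0, 0, 0)


def test_one_short_axis_drops_everything():
    spec = PatchSpec(patch_shape=(18, 160, 160))
    assert patch_count((18, 160, 159), spec) == 0
    assert tile(np.zeros((18, 160, 159)), spec) == []


def test_tile_stitch_round_trip(rng):
    vals = rng.random((4, 16, 24))
    spec = PatchSpec(patch_shape=(2, 8, 8))
    patches = tile(vals, spec)
    assert len(patches) == 2 * 2 * 3
    out = stitch(patches, vals.shape)
    np.testing.assert_allclose(out.values, vals, atol=1e-12)


def test_stitch_order_independent(rng):
    vals = rng.random((2, 8, 8))
    patches = tile(vals, PatchSpec(patch_shape=(2, 4, 4)))
    a = stitch(patches, vals.shape).values
    b = stitch(patches[::-1], vals.shape).values
    np.testing.assert_array_equal(a, b)


def test_stitch_overlap_is_mean():
    a = np.zeros((1, 2, 4))
    b = np.ones((1, 2, 4))
    out = stitch([((0, 0, 0), a), ((0, 0, 2), b)], (1, 2, 6))
    np.testing.assert_allclose(out.values[:, :, 2:4], 0.5)
    np.testing.assert_allclose(out.values[:, :, :2], 0.0)
    np.testing.assert_allclose(out.values[:, :, 4:], 1.0)


def test_stitch_random_overlaps_match_accumulation_oracle(rng):
    shape = (3, 10, 10)
    items = []
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for _ in range(30):
        oz, oy, ox = (int(rng.integers(0, s - 2)) for s in shape)
        data = rng.random((2, 3, 3))
        items.append(((oz, oy, ox), data))
        acc[oz : oz + 2, oy : oy + 3, ox : ox + 3] += data
        cnt[oz : oz + 2, oy : oy + 3, ox : ox + 3] += 1
    if (cnt == 0).any():  # ensure full coverage for the oracle comparison
        items.append(((0, 0, 0), np.zeros(shape)))
        acc += 0
        cnt += 1
    out = stitch(items, shape)
    np.testing.assert_allclose(out.values, acc / cnt, atol=1e-6)


def test_stitch_uncovered_voxels_report_gap():
    with pytest.raises(CoverageError, match="uncovered"):
        stitch([((0, 0, 0), np.ones((1, 2, 2)))], (1, 4, 4))


def test_reflect_tiling_covers_odd_volume(rng):
    vals = rng.random((3, 18, 21))
    spec = PatchSpec(patch_shape=(2, 8, 8), border_policy="reflect")
    patches = tile(vals, spec)
    out = stitch(patches, (4, 24, 24))  # padded extent
    np.testing.assert_allclose(out.values[:3, :18, :21], vals, atol=1e-12)


def test_patch_set_hdf5_round_trip(tmp_path, rng):
    from vemseg.preprocess import load_patches, save_patches

    patches = tile(rng.random((4, 16, 16)), PatchSpec(patch_shape=(2, 8, 8)))
    save_patches(patches, tmp_path / "patches.h5")
    back = load_patches(tmp_path / "patches.h5")
    assert len(back) == len(patches)
    for a, b in zip(patches, back):
        assert a.origin == b.origin
        np.testing.assert_array_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# subsampling


def test_subsample_fraction_full_and_quarter():
    patches = list(range(120))
    assert subsample_fraction(patches, 1.0, seed=0) == patches
    sub = subsample_fraction(patches, 0.25, seed=0)
    assert len(sub) == 30
    assert len(set(sub)) == 30


def test_subsample_deterministic_given_seed():
    patches = list(range(50))
    assert subsample_fraction(patches, 0.3, seed=7) == subsample_fraction(patches, 0.3, seed=7)
    assert subsample_fraction(patches, 0.3, seed=7) != subsample_fraction(patches, 0.3, seed=8)


def test_subsample_rejects_bad_input():
    with pytest.raises(ValueError):
        subsample_fraction([], 0.5, seed=0)
    with pytest.raises(ValueError):
        subsample_fraction([1, 2], 0.0, seed=0)
    with pytest.raises(ValueError):
        subsample_fraction([1, 2], 1.5, seed=0)
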