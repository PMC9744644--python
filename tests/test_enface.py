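"""Projection, quality scoring, and rigid registration."""

import numpy as np
import pytest

import foct
from foct.enface import (RigidTransform, apply_transform, project_enface,
                         quality_score, register_rigid)
from foct.io import EnFaceImage
from foct.synthetic import SceneParams, generate_volume


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class _FlatSurfaces:
    def __init__(self, shape, ilm, rpe):
        self.ilm_depth = np.full(shape, float(ilm))
        self.rpe_depth = np.full(shape, float(rpe))


def _const_volume(value=0.5, shape=(16, 8, 64), spacing=(10.0, 10.0, 10.0)):
    return foct.OctVolume(np.full(shape, value, np.float32), spacing)


@pytest.mark.parametrize("reducer", ["mean", "max"])
def test_constant_slab_projects_to_constant(reducer):
    vol = _const_volume(0.37)
    surf = _FlatSurfaces(vol.enface_shape, 10, 50)
    img = project_enface(vol, surf, band=(0.0, 200.0), reducer=reducer)
    np.testing.assert_allclose(img.data, 0.37, rtol=1e-6)


def test_max_reducer_finds_single_bright_voxel():
    vol = _const_volume(0.1)
    vol.data[:, :, 25] = 0.9
    surf = _FlatSurfaces(vol.enface_shape, 10, 50)
    img = project_enface(vol, surf, band=(0.0, 300.0), reducer="max")
    np.testing.assert_allclose(img.data, 0.9, rtol=1e-6)


def test_projection_linear_in_intensity_for_mean():
    vol, truth = generate_volume(SceneParams(grid_shape=(48, 32, 96), seed=3))
    img1 = project_enface(vol, truth, band=(0.0, 120.0), reducer="mean")
    vol2 = foct.OctVolume(2.5 * vol.data, vol.spacing_um)
    img2 = project_enface(vol2, truth, band=(0.0, 120.0), reducer="mean")
    np.testing.assert_allclose(img2.data, 2.5 * img1.data, rtol=1e-5)


def test_empty_slab_names_offending_column():
    vol = _const_volume()
    surf = _FlatSurfaces(vol.enface_shape, 10, 50)
    with pytest.raises(ValueError, match="x=0"):
        project_enface(vol, surf, band=(5.0, 5.0))


def test_projected_tubes_match_truth_support(small_default_volume):
    volume, truth = small_default_volume
    img = project_enface(volume, truth, band=(0.0, 60.0), reducer="mean")
    inside = img.data[truth.vessel_mask].mean()
    outside = img.data[~truth.vessel_mask].mean()
    assert inside > 1.2 * outside


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def test_quality_extremes_and_monotonicity():
    base = dict(grid_shape=(64, 32, 128), seed=5)
    # noise-free slab: infinite SNR clamps to 10 (with a warning)
    clean = SceneParams(speckle_sigma=0.0, band_artifact_amplitude=0.0,
                        blob_artifact_count=0, **base)
    with pytest.warns(UserWarning):
        assert quality_score(generate_volume(clean)[0]).score == 10
    # featureless noise: slab and vessels at the vitreous level
    flat = SceneParams(slab_level=0.005, rpe_level=0.005, sub_rpe_level=0.005,
                       vessel_contrast=1.0, band_artifact_amplitude=0.0,
                       blob_artifact_count=0, **base)
    assert quality_score(generate_volume(flat)[0]).score <= 2
    # decreasing speckle raises the score monotonically
    scores = [quality_score(generate_volume(
        SceneParams(speckle_sigma=s, **base))[0]).snr_db
        for s in (0.6, 0.3, 0.15)]
    assert scores[0] < scores[1] < scores[2]


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def textured_image():
    vol, truth = generate_volume(SceneParams(grid_shape=(96, 96, 96),
                                             extent_mm=(3.0, 3.0, 1.0), seed=9))
    img = project_enface(vol, truth, band=(0.0, 60.0), reducer="mean")
    return img


def test_identity_registration(textured_image):
    t = register_rigid(textured_image, textured_image)
    assert abs(t.rotation_deg) <= 0.05
    assert abs(t.shift_x_px) <= 0.1 and abs(t.shift_y_px) <= 0.1


def test_integer_shift_recovered(textured_image):
    rolled = EnFaceImage(np.roll(textured_image.data, (3, -2), axis=(0, 1)),
                         textured_image.spacing_um)
    t = register_rigid(rolled, textured_image)
    # aligning the original to the rolled copy needs the same (+3, -2) shift
    assert t.shift_x_px == pytest.approx(3.0, abs=0.5)
    assert t.shift_y_px == pytest.approx(-2.0, abs=0.5)


def test_rotation_recovered_within_half_degree(textured_image):
    rotated = apply_transform(textured_image, RigidTransform(4.0, 0.0, 0.0))
    t = register_rigid(textured_image, rotated)
    assert t.rotation_deg == pytest.approx(-4.0, abs=0.5)


def test_transform_roundtrip_and_inverse():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(6)
    smooth = gaussian_filter(rng.random((96, 96)), 5.0)
    image = EnFaceImage(smooth, (20.0, 20.0))
    sl = (slice(12, -12), slice(12, -12))
    # subpixel shift there and back: interpolation-level error only
    t = RigidTransform(0.0, 3.4, -2.6)
    back = apply_transform(apply_transform(image, t), t.inverse())
    rms = np.sqrt(np.mean((back.data[sl] - image.data[sl]) ** 2))
    assert rms < 1e-3
    # adding rotation stays within a (looser) resampling tolerance
    t = RigidTransform(6.0, 4.0, -3.0)
    back = apply_transform(apply_transform(image, t), t.inverse())
    rms = np.sqrt(np.mean((back.data[sl] - image.data[sl]) ** 2))
    assert rms < 1e-2 * np.ptp(image.data)


def test_identity_transform_is_noop(textured_image):
    out = apply_transform(textured_image, RigidTransform())
    assert np.abs(out.data - textured_image.data).max() <= 1e-7


def test_quarter_turn_preserves_symmetric_cross():
    n = 65
    img = np.zeros((n, n))
    img[n // 2 - 2: n // 2 + 3, :] = 1.0
    img[:, n // 2 - 2: n // 2 + 3] = 1.0
    image = EnFaceImage(img, (10.0, 10.0))
    out = apply_transform(image, RigidTransform(90.0, 0.0, 0.0))
    np.testing.assert_allclose(out.data, img, atol=1e-7)


def test_registration_consistency_over_range(textured_image):
    """register(A, apply(A, t)) recovers t^-1 for moderate motion."""
    for t in (RigidTransform(8.0, 6.0, -8.0), RigidTransform(-3.0, -10.0, 5.0)):
        moved = apply_transform(textured_image, t)
        rec = register_rigid(textured_image, moved)
        inv = t.inverse()
        assert rec.rotation_deg == pytest.approx(inv.rotation_deg, abs=0.5)
        assert rec.shift_x_px == pytest.approx(inv.shift_x_px, abs=0.5)
        assert rec.shift_y_px == pytest.approx(inv.shift_y_px, abs=0.5)


def test_flat_image_cannot_be_registered(textured_image):
    flat = EnFaceImage(np.zeros_like(textured_image.data),
                       textured_image.spacing_um)
    with pytest.raises(ValueError):
        register_rigid(flat, textured_image)
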