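"""Preprocessing branch: resampling, masking, normalization, cropping, registration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from longisym.errors import ConfigurationError, DegenerateInputError, InputError
from longisym.phantom import PhantomConfig, generate_cohort, _ellipsoid_mask
from longisym.preproc import (
    RegistrationSettings,
    brain_mask,
    crop_pair,
    downsample,
    estimate_rigid,
    normalize_intensity,
    preprocess_pair,
    resample,
)
from longisym.volume import RigidTransform, Volume


@pytest.fixture(scope="module")
def phantom_volume():
    cfg = PhantomConfig(noise_sd=0.0, misalign_max=(0.0, 0.0))
    _, recs = generate_cohort(cfg, {"progressor": 1, "non-progressor": 1})
    return recs[0].session1


class TestResample:
    def test_identity_transform_is_exact(self, phantom_volume):
        out = resample(phantom_volume, RigidTransform(), phantom_volume)
        np.testing.assert_allclose(out.data, phantom_volume.data, atol=1e-12)

    def test_roundtrip_error_small_on_smooth_volume(self):
        rng = np.random.default_rng(5)
        smooth = gaussian_filter(rng.random((16, 16, 16)), 2.0)
        vol = Volume(smooth)
        center = tuple(vol.world_center())
        t = RigidTransform((3.0, -2.0, 4.0), (1.0, 0.5, -1.5), center)
        back = resample(resample(vol, t, vol), t.inverse(), vol)
        interior = np.zeros(vol.shape, bool)
        interior[3:-3, 3:-3, 3:-3] = True  # border voxels leave the field of view
        err = np.abs(back.data - vol.data)[interior].max()
        assert err < 0.05 * np.ptp(vol.data)

    def test_constant_volume_stays_constant_inside_fov(self):
        vol = Volume(np.full((12, 12, 12), 3.5))
        t = RigidTransform((0, 0, 0), (2.0, 0.0, 0.0), tuple(vol.world_center()))
        out = resample(vol, t, vol)
        assert np.allclose(out.data[4:-4, 4:-4, 4:-4], 3.5, atol=1e-9)

    def test_unknown_interpolation_rejected(self, phantom_volume):
        with pytest.raises(ConfigurationError):
            resample(phantom_volume, RigidTransform(), interpolation="sinc")


class TestBrainMask:
    def test_recovers_ellipsoid_with_high_dice(self, phantom_volume):
        truth = _ellipsoid_mask(phantom_volume.shape, phantom_volume.spacing_mm)
        mask = np.asarray(brain_mask(phantom_volume).data, bool)
        dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_constant_volume_raises(self):
        with pytest.raises(DegenerateInputError):
            brain_mask(Volume(np.zeros((8, 8, 8))))

    def test_mask_is_binary_single_component(self, phantom_volume):
        from scipy import ndimage

        mask = brain_mask(phantom_volume).data
        assert set(np.unique(mask)) <= {0, 1}
        _, n = ndimage.label(mask)
        assert n == 1


class TestNormalizeIntensity:
    def test_percentile_formula(self):
        # In-mask values 0..100 -> 1st/99th percentiles at exactly 1 and 99.
        data = np.arange(101.0).reshape(101, 1, 1)
        mask = Volume(np.ones((101, 1, 1), dtype=np.uint8))
        out, (p1, p99) = normalize_intensity(Volume(data), mask)
        assert (p1, p99) == (1.0, 99.0)
        flat = out.data.ravel()
        assert flat[1] == 0.0
        assert flat[99] == 1.0
        assert np.isclose(flat[50], 49.0 / 98.0)

    def test_output_clipped_to_unit_interval_outside_mask_zero(self, phantom_volume):
        mask = brain_mask(phantom_volume)
        out, _ = normalize_intensity(phantom_volume, mask)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        assert np.all(out.data[~np.asarray(mask.data, bool)] == 0)

    def test_monotone_within_mask(self, phantom_volume):
        mask = brain_mask(phantom_volume)
        out, _ = normalize_intensity(phantom_volume, mask)
        m = np.asarray(mask.data, bool)
        x = phantom_volume.data[m]
        y = out.data[m]
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-12)

    def test_constant_within_mask_raises(self):
        vol = Volume(np.ones((6, 6, 6)))
        mask = Volume(np.ones((6, 6, 6), dtype=np.uint8))
        with pytest.raises(DegenerateInputError):
            normalize_intensity(vol, mask)


class TestDownsample:
    def test_fraction_one_is_identity(self, phantom_volume):
        out = downsample(phantom_volume, 1.0)
        np.testing.assert_array_equal(out.data, phantom_volume.data)

    def test_round_half_up_shape(self):
        vol = Volume(np.zeros((182, 218, 182)))
        out = downsample(vol, 0.25)
        assert out.shape == (46, 55, 46)

    def test_constant_volume_stays_constant(self):
        out = downsample(Volume(np.full((16, 16, 16), 2.0)), 0.5)
        np.testing.assert_allclose(out.data, 2.0, atol=1e-9)

    def test_too_small_result_raises(self):
        with pytest.raises(ConfigurationError):
            downsample(Volume(np.zeros((16, 16, 16))), 0.1)
        with pytest.raises(ConfigurationError):
            downsample(Volume(np.zeros((16, 16, 16))), 1.5)


class TestCropPair:
    def test_full_mask_keeps_shape(self, phantom_volume):
        mask = Volume(np.ones(phantom_volume.shape, dtype=np.uint8))
        pair = crop_pair(phantom_volume, phantom_volume, mask)
        assert pair.session1.shape == phantom_volume.shape

    def test_central_cube_bounding_box(self):
        data = np.random.default_rng(0).random((32, 32, 32))
        mask = np.zeros((32, 32, 32), dtype=np.uint8)
        mask[11:21, 11:21, 11:21] = 1
        pair = crop_pair(Volume(data), Volume(data), Volume(mask))
        assert pair.session1.shape == (10, 10, 10)
        assert pair.crop_box == ((11, 21), (11, 21), (11, 21))
        assert pair.session1.shape == pair.session2.shape

    def test_empty_mask_raises(self, phantom_volume):
        with pytest.raises(DegenerateInputError):
            crop_pair(phantom_volume, phantom_volume, Volume(np.zeros(phantom_volume.shape)))


class TestEstimateRigid:
    def test_identical_volumes_give_identity(self, phantom_volume):
        t = estimate_rigid(phantom_volume, phantom_volume)
        assert np.all(np.abs(t.params[:3]) < 1e-3)
        assert np.all(np.abs(t.params[3:]) < 1e-3)

    def test_known_translation_recovered(self, phantom_volume):
        center = tuple(phantom_volume.world_center())
        t = RigidTransform((0, 0, 0), (3.0, -2.0, 1.0), center)
        moved = resample(phantom_volume, t, phantom_volume, "cubic")
        est = estimate_rigid(moved, phantom_volume)
        err = np.abs(est.params[3:] - t.inverse().params[3:])
        assert err.max() < 0.5  # voxels (1 mm spacing)

    def test_known_rotation_recovered(self, phantom_volume):
        center = tuple(phantom_volume.world_center())
        t = RigidTransform((0.0, 5.0, 0.0), (0, 0, 0), center)
        moved = resample(phantom_volume, t, phantom_volume, "cubic")
        est = estimate_rigid(moved, phantom_volume)
        err = np.abs(est.params[:3] - t.inverse().params[:3])
        assert err.max() < 0.5  # degrees

    def test_noise_degrades_gracefully(self):
        cfg = PhantomConfig(noise_sd=0.05, misalign_max=(3.0, 3.0), seed=7)
        _, recs = generate_cohort(cfg, {"progressor": 1, "non-progressor": 1})
        for r in recs:
            est = estimate_rigid(r.session2, r.session1)
            err = np.abs(est.params[3:] - r.true_transform.inverse().params[3:])
            assert err.max() < 1.0  # voxels


def test_end_to_end_alignment_residual_small():
    """After registration + resampling, non-target voxels nearly cancel."""
    cfg = PhantomConfig(noise_sd=0.0, misalign_max=(2.0, 2.0), seed=11)
    atlas, recs = generate_cohort(cfg, {"progressor": 1})
    r = recs[0]
    est = estimate_rigid(r.session2, r.session1)
    aligned = resample(r.session2, est, r.session1, "cubic")
    from scipy import ndimage

    brain = atlas.labels.data > 0
    nontarget = brain & ~np.isin(atlas.labels.data, (3,))
    # Exclude the 2-voxel partial-volume rim, where interpolation alone
    # dominates the difference regardless of alignment quality.
    core = ndimage.binary_erosion(brain, iterations=2) & nontarget
    mad = np.abs(aligned.data - r.session1.data)[core].mean()
    assert mad < 0.02 * np.ptp(r.session1.data)


def test_preprocess_pair_contract():
    cfg = PhantomConfig(noise_sd=0.02, misalign_max=(1.0, 1.0), seed=3)
    _, recs = generate_cohort(cfg, {"progressor": 1})
    r = recs[0]
    pair = preprocess_pair(r.session1, r.session2)
    assert pair.session1.shape == pair.session2.shape
    mask = np.asarray(pair.brain_mask.data, bool)
    assert np.all(pair.session1.data[~mask] == 0)
    assert np.all(pair.session2.data[~mask] == 0)
    assert pair.session1.data.max() <= 1.0
    assert pair.normalization_percentiles is not None
    (a0, a1), _ = pair.crop_box[0], pair.crop_box[1]
    assert 0 <= a0 < a1 <= r.session1.shape[0]
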