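"""Void segmentation and volumetry."""

import numpy as np
import pytest

from tissueqc import voids
from tissueqc.voids import (
    MaskVolume,
    VoidSegmentationConfig,
    interpolate_masks,
    segment_total,
    segment_voids,
    speckle_reduce,
    void_volume_percent,
    void_volumetry,
)


class TestSpeckleReduce:
    def test_constant_image_is_fixed_point(self):
        img = np.full((32, 32), 50.0)
        assert np.allclose(speckle_reduce(img, 50, 1.0), img)

    def test_zero_iterations_is_identity(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        assert np.array_equal(speckle_reduce(img, 0, 1.0), img)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            speckle_reduce(np.ones((4, 4)), -1, 1.0)

    def test_interior_variance_halves_and_edges_survive(self, void_phantom):
        spec, bm, truth = void_phantom
        mid = len(bm.frames) // 2
        img = bm.as_array()[mid].astype(float)
        sr = speckle_reduce(img, 50, 1.0)
        # tissue interior patch (inside slab, outside void)
        patch = (slice(70, 110), slice(50, 90))
        assert sr[patch].var() <= 0.5 * img[patch].var()
        # gradient magnitude on the void boundary retains >= 50%
        cz, cx, cy, az, ax, ay, _ = spec.voids[0]
        y = (mid + 0.5) * spec.frame_spacing
        s = np.sqrt(max(0.0, 1 - ((y - cy) / ay) ** 2))
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        rr = ((cz + az * s * np.cos(theta)) / 5.0).astype(int)
        cc = ((cx + ax * s * np.sin(theta)) / 5.0).astype(int)

        def grad_mag(im):
            gy, gx = np.gradient(im)
            return np.hypot(gy, gx)[rr, cc].mean()

        assert grad_mag(sr) >= 0.5 * grad_mag(img)


class TestSegmentTotal:
    def test_two_mode_image_segmented_exactly(self):
        img = np.full((64, 64), 20.0)
        img[16:48, 10:50] = 200.0
        mask = segment_total(img)
        expected = np.zeros((64, 64), dtype=bool)
        expected[16:48, 10:50] = True
        # brute-force Otsu over all 256 thresholds agrees: any threshold
        # strictly between the modes yields the exact region
        assert np.array_equal(mask, expected)

    def test_dark_hole_is_flood_filled(self):
        img = np.full((64, 64), 20.0)
        img[8:56, 8:56] = 200.0
        img[25:35, 25:35] = 20.0  # interior hole
        mask = segment_total(img)
        assert mask[30, 30]

    def test_contrast_free_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = segment_total(np.full((16, 16), 7.0))
        assert not mask.any()


class TestSegmentVoids:
    def test_known_void_area_recovered(self, void_phantom):
        spec, bm, _ = void_phantom
        mid = len(bm.frames) // 2
        img = bm.as_array()[mid].astype(float)
        sr = speckle_reduce(img, 50, 1.0)
        total = segment_total(sr)
        vm = segment_voids(img, total, reduced=sr)
        cz, cx, cy, az, ax, ay, _ = spec.voids[0]
        y = (mid + 0.5) * spec.frame_spacing
        s2 = 1 - ((y - cy) / ay) ** 2
        true_area = np.pi * (az / 5.0) * (ax / 5.0) * s2
        assert vm.sum() == pytest.approx(true_area, rel=0.15)

    def test_voidfree_false_positives_bounded(self, voidfree_phantom):
        _, bm, _ = voidfree_phantom
        for img in bm.as_array()[::3].astype(float):
            sr = speckle_reduce(img, 50, 1.0)
            total = segment_total(sr)
            vm = segment_voids(img, total, reduced=sr)
            assert vm.sum() <= 0.005 * total.sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_voids(np.zeros((8, 8)), np.zeros((4, 4), dtype=bool))

    def test_dark_region_outside_total_excluded(self):
        img = np.full((96, 96), 200.0)
        img[: 20, :] = 5.0  # dark band outside the sample
        total = np.zeros((96, 96), dtype=bool)
        total[40:90, 20:80] = True
        vm = segment_voids(img, total)
        assert not vm[:20, :].any()


class TestInterpolateMasks:
    @staticmethod
    def _circle(r, n=64):
        yy, xx = np.mgrid[0:n, 0:n]
        return (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= r**2

    def test_identical_frames_reproduced(self):
        m = self._circle(10)
        vol = interpolate_masks([m, m], factor=4)
        assert vol.voxels.shape[0] == 5  # (n-1)*f + 1
        for s in vol.voxels:
            assert np.array_equal(s, m)

    def test_midslice_radius_between_circles(self):
        vol = interpolate_masks([self._circle(10), self._circle(20)], factor=2)
        mid = vol.voxels[1]
        r_eq = np.sqrt(mid.sum() / np.pi)
        assert r_eq == pytest.approx(15.0, abs=1.0)

    def test_factor_one_passthrough(self):
        a, b = self._circle(5), self._circle(9)
        vol = interpolate_masks([a, b], factor=1)
        assert vol.voxels.shape[0] == 2
        assert np.array_equal(vol.voxels[0], a)

    def test_slice_count_scaling(self):
        frames = [self._circle(5 + i) for i in range(4)]
        vol = interpolate_masks(frames, factor=20)
        assert vol.voxels.shape[0] == 3 * 20 + 1

    def test_original_frames_exact_at_positions(self):
        a, b = self._circle(8), self._circle(16)
        vol = interpolate_masks([a, b], factor=5)
        assert np.array_equal(vol.voxels[0], a)
        assert np.array_equal(vol.voxels[5], b)

    def test_single_frame_with_factor_rejected(self):
        with pytest.raises(ValueError):
            interpolate_masks([self._circle(5)], factor=3)

    def test_voxel_size_divides_elevational_spacing(self):
        vol = interpolate_masks([self._circle(5), self._circle(6)], 10, (5.0, 5.0, 200.0))
        assert vol.voxel_size == (5.0, 5.0, 20.0)


class TestVoidVolumePercent:
    def _mask(self, shape, n_true, kind):
        v = np.zeros(shape, dtype=bool)
        v.ravel()[:n_true] = True
        return MaskVolume(v, (10.0, 10.0, 10.0), kind=kind)

    def test_counted_fraction(self):
        total = self._mask((10, 40, 25), 10000, "total")
        void = self._mask((10, 40, 25), 500, "void")
        res = void_volume_percent(total, void)
        assert res.void_percent == pytest.approx(5.0)
        assert res.total_volume == pytest.approx(10000 * 1e3 * 1e-9)

    def test_voidfree_is_zero(self):
        total = self._mask((4, 4, 4), 30, "total")
        void = self._mask((4, 4, 4), 0, "void")
        assert void_volume_percent(total, void).void_percent == 0.0

    def test_zero_total_volume_errors(self):
        total = self._mask((4, 4, 4), 0, "total")
        void = self._mask((4, 4, 4), 0, "void")
        with pytest.raises(ZeroDivisionError):
            void_volume_percent(total, void)

    def test_void_outside_total_ignored(self):
        total = np.zeros((2, 4, 4), dtype=bool)
        total[:, :2, :] = True
        void = np.zeros_like(total)
        void[:, 3, :] = True  # entirely outside
        res = void_volume_percent(
            MaskVolume(total, (1, 1, 1), "total"), MaskVolume(void, (1, 1, 1), "void")
        )
        assert res.void_percent == 0.0


def test_end_to_end_monotone_in_true_void_size(void_phantom):
    """Enlarging the true void (same seed) must not decrease the estimate."""
    from tissueqc import bmode, synthetic as syn

    _, bm10, _ = void_phantom
    est10 = void_volumetry(bm10.as_array(), bm10.voxel_size)[0].void_percent
    spec20 = syn.RfPhantomSpec(seed=42).with_centered_void(20.0)
    vol, _ = syn.gen_rf_phantom(spec20)
    bm20 = bmode.reconstruct_volume(vol)
    est20 = void_volumetry(bm20.as_array(), bm20.voxel_size)[0].void_percent
    assert est20 >= est10
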