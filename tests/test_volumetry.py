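"""3D smoothing, segmentation, voxel and ROI volumetry."""

import math

import numpy as np
import pytest

from octmorph.errors import InvalidArgumentError
from octmorph.io import OCTVolume
from octmorph.volumetry import (
    SegmentationParams,
    compartment_mask,
    measure_objects,
    measure_roi_volume,
    segment_objects,
    smooth_volume,
)


def ball_volume(r_vox, size=None, intensity=100.0, voxel=1.0):
    n = size or (2 * r_vox + 7)
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    ball = (((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r_vox**2)
    return OCTVolume(ball.astype(np.float32) * intensity, (voxel,) * 3)


class TestSmoothVolume:
    def test_zero_smoothness_is_identity(self):
        vol = ball_volume(5)
        out = smooth_volume(vol, 0.0)
        assert np.array_equal(out.intensity, vol.intensity)
        assert out.intensity is not vol.intensity  # no aliasing

    def test_constant_volume_unchanged(self):
        vol = OCTVolume(np.full((10, 12, 14), 7.0), (3.0, 3.0, 3.0))
        out = smooth_volume(vol, 9.0)
        assert np.allclose(out.intensity, 7.0)

    def test_interior_impulse_mass_conserved(self):
        """Gaussian smoothing with reflective borders conserves the total
        intensity of an interior impulse (direct-sum oracle)."""
        arr = np.zeros((31, 31, 31))
        arr[15, 15, 15] = 1.0
        out = smooth_volume(OCTVolume(arr, (3.0, 3.0, 3.0)), 5.0)
        assert out.intensity.sum() == pytest.approx(1.0, rel=1e-6)

    def test_anisotropic_sigma_follows_voxel_size(self):
        arr = np.zeros((21, 21, 21))
        arr[10, 10, 10] = 1.0
        out = smooth_volume(OCTVolume(arr, (6.0, 3.0, 3.0)), 6.0).intensity
        # sigma is 1 voxel along b-scan axis, 2 along the others: the spread
        # one step away must be larger along the finer-sampled axes
        assert out[10, 12, 10] > out[12, 10, 10]


class TestSegmentAndMeasure:
    @pytest.mark.parametrize("r", [10, 20])
    def test_digitized_ball_volume_within_two_percent(self, r):
        vol = ball_volume(r)
        labels = segment_objects(vol, SegmentationParams(threshold=50, smoothness_um=0))
        m = measure_objects(labels, vol.voxel_size_um)
        analytic = 4 / 3 * math.pi * r**3
        assert m[0].volume_um3 == pytest.approx(analytic, rel=0.02)

    def test_single_voxel_volume_is_voxel_volume(self):
        arr = np.zeros((5, 5, 5), dtype=np.float32)
        arr[2, 2, 2] = 100.0
        vol = OCTVolume(arr, (3.0, 3.0, 3.0))
        labels = segment_objects(vol, SegmentationParams(threshold=50, smoothness_um=0))
        m = measure_objects(labels, vol.voxel_size_um)
        assert m[0].voxel_count == 1
        assert m[0].volume_um3 == pytest.approx(27.0)

    def test_empty_volume_yields_no_objects(self):
        vol = OCTVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        labels = segment_objects(vol, SegmentationParams(threshold=50, smoothness_um=0))
        assert measure_objects(labels, vol.voxel_size_um) == []
        assert labels.max() == 0

    def test_bridged_spheres_merge_under_26_connectivity(self):
        arr = np.zeros((20, 20, 40), dtype=np.float32)
        zz, yy, xx = np.mgrid[:20, :20, :40]
        arr[((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2) <= 36] = 100
        arr[((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 29) ** 2) <= 36] = 100
        vol = OCTVolume(arr, (1.0, 1.0, 1.0))
        params = SegmentationParams(threshold=50, smoothness_um=0)
        assert segment_objects(vol, params).max() == 2
        arr[10, 10, 10:30] = 100  # bridge
        bridged = OCTVolume(arr, (1.0, 1.0, 1.0))
        assert segment_objects(bridged, params).max() == 1

    def test_labels_ordered_by_descending_size(self):
        arr = np.zeros((10, 10, 60), dtype=np.float32)
        arr[4:6, 4:6, 2:4] = 100  # 8 voxels
        arr[4:7, 4:7, 20:25] = 100  # 45 voxels
        arr[4:6, 4:6, 40:42] = 100
        arr[4:5, 4:5, 50:51] = 100  # 1 voxel
        vol = OCTVolume(arr, (1.0, 1.0, 1.0))
        labels = segment_objects(vol, SegmentationParams(threshold=50, smoothness_um=0))
        m = measure_objects(labels, vol.voxel_size_um)
        counts = [o.voxel_count for o in m]
        assert counts == sorted(counts, reverse=True)
        assert m[0].voxel_count == 45

    def test_min_volume_filter_drops_small_components(self):
        arr = np.zeros((10, 10, 30), dtype=np.float32)
        arr[4:7, 4:7, 2:7] = 100
        arr[5, 5, 20] = 100  # single stray voxel
        vol = OCTVolume(arr, (1.0, 1.0, 1.0))
        labels = segment_objects(
            vol, SegmentationParams(threshold=50, smoothness_um=0, min_volume_um3=10)
        )
        assert labels.max() == 1

    def test_raising_threshold_never_grows_objects(self):
        rng = np.random.default_rng(17)
        vol = OCTVolume(rng.gamma(4, 25, size=(12, 20, 20)), (1.0, 1.0, 1.0))
        counts = []
        for thr in (60.0, 90.0, 120.0):
            labels = segment_objects(
                vol, SegmentationParams(threshold=thr, smoothness_um=2.0)
            )
            counts.append((labels > 0).sum())
        assert counts[0] >= counts[1] >= counts[2]

    def test_volume_invariant_under_axis_permutation(self):
        arr = np.zeros((10, 14, 18), dtype=np.float32)
        arr[2:7, 3:9, 4:12] = 100
        vol = OCTVolume(arr, (2.0, 3.0, 4.0))
        params = SegmentationParams(threshold=50, smoothness_um=0)
        m1 = measure_objects(segment_objects(vol, params), vol.voxel_size_um)
        perm = OCTVolume(arr.transpose(2, 0, 1), (4.0, 2.0, 3.0))
        m2 = measure_objects(segment_objects(perm, params), perm.voxel_size_um)
        assert m1[0].volume_um3 == pytest.approx(m2[0].volume_um3)

    def test_dark_polarity_without_mask_warns_and_finds_cavity(self):
        arr = np.full((16, 24, 24), 100.0, dtype=np.float32)
        zz, yy, xx = np.mgrid[:16, :24, :24]
        cavity = ((zz - 8) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 16
        arr[cavity] = 2.0
        vol = OCTVolume(arr, (1.0, 1.0, 1.0))
        params = SegmentationParams(threshold=50, smoothness_um=0, polarity="dark")
        with pytest.warns(UserWarning, match="tissue mask"):
            labels = segment_objects(vol, params)
        m = measure_objects(labels, vol.voxel_size_um, "chamber")
        assert len(m) == 1
        assert m[0].voxel_count == int(cavity.sum())

    def test_compartment_mask_selects_background_side(self):
        surface = np.full((4, 10), 5.0)
        mask = compartment_mask(surface, (4, 12, 10), (1.0, 1.0, 1.0), "above")
        assert mask[:, :5, :].all() and not mask[:, 5:, :].any()
        below = compartment_mask(surface, (4, 12, 10), (1.0, 1.0, 1.0), "below",
                                 margin_um=1.0)
        assert not below[:, :7, :].any() and below[:, 7:, :].all()


class TestRoiVolume:
    SQUARE = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)

    def test_square_roi_area_times_spacing(self):
        v = measure_roi_volume([(0, self.SQUARE)], (3.0, 3.0, 3.0))
        assert v == pytest.approx(30_000.0)

    def test_additive_over_bscans(self):
        rois = [(i, self.SQUARE) for i in range(10)]
        v = measure_roi_volume(rois, (3.0, 3.0, 3.0))
        assert v == pytest.approx(300_000.0)

    def test_circle_64gon_matches_regular_polygon_area(self):
        n, r = 64, 50.0
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        v = measure_roi_volume([(0, poly)], (1.0, 1.0, 1.0))
        exact_polygon = 0.5 * n * r**2 * math.sin(2 * math.pi / n)
        assert v == pytest.approx(exact_polygon, rel=1e-9)
        assert v == pytest.approx(math.pi * r**2, rel=2e-3)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(InvalidArgumentError):
            measure_roi_volume([(0, bowtie)], (3.0, 3.0, 3.0))

    def test_roi_route_agrees_with_voxel_route_on_sphere(self):
        """The two measurement routes agree within 10% on a digitized ball."""
        r = 30
        vol = ball_volume(r)
        labels = segment_objects(vol, SegmentationParams(threshold=50, smoothness_um=0))
        voxel_v = measure_objects(labels, vol.voxel_size_um)[0].volume_um3
        c = vol.shape[0] // 2
        rois = []
        for z in range(vol.shape[0]):
            rho2 = r**2 - (z - c) ** 2
            if rho2 <= 0:
                continue
            rho = math.sqrt(rho2)
            theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            rois.append(
                (z, np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
            )
        roi_v = measure_roi_volume(rois, vol.voxel_size_um)
        assert roi_v == pytest.approx(voxel_v, rel=0.10)
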