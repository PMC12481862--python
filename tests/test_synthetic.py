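"""Phantom generator: profiles, scenes, ground truth, determinism."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from octmorph.errors import InvalidArgumentError, PlacementError
from octmorph.synthetic import PhantomSpec, generate_phantom, generate_profile, save_phantom, load_ground_truth


class TestGenerateProfile:
    def test_flat_profile_is_constant(self):
        p = generate_profile("flat", dict(level=500.0), 100, 1500.0)
        assert p.n_points == 100
        assert np.all(p.y == 500.0)
        assert p.x[0] == 0.0 and p.x[-1] == 1500.0

    def test_polynomial_profile_refits_to_its_own_coefficients(self):
        coeffs = (400.0, 0.08, -2e-4, 5e-8)
        p = generate_profile("polynomial", dict(coefficients=coeffs), 200, 1500.0)
        refit = np.polynomial.Polynomial.fit(p.x, p.y, 3).convert().coef
        assert np.allclose(refit, coeffs, rtol=1e-9, atol=1e-9)

    def test_sinusoid_polyline_length_matches_arc_length_integral(self):
        A, lam = 30.0, 200.0
        p = generate_profile(
            "sinusoid", dict(baseline=500, amplitude=A, wavelength=lam), 501, 1500.0
        )
        length = np.sqrt(np.diff(p.x) ** 2 + np.diff(p.y) ** 2).sum()
        k = 2 * np.pi / lam
        oracle = quad(
            lambda x: np.sqrt(1 + (A * k * np.cos(k * x)) ** 2), 0, 1500, limit=400
        )[0]
        assert abs(length - oracle) / oracle < 1e-3

    def test_bumpy_profile_is_seeded_and_deterministic(self):
        p1 = generate_profile("bumpy", dict(n_bumps=4), 300, 900.0, seed=5)
        p2 = generate_profile("bumpy", dict(n_bumps=4), 300, 900.0, seed=5)
        p3 = generate_profile("bumpy", dict(n_bumps=4), 300, 900.0, seed=6)
        assert np.array_equal(p1.points, p2.points)
        assert not np.array_equal(p1.points, p3.points)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="flat", n_points=3),
            dict(kind="flat", extent_um=0.0),
            dict(kind="nonsense"),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        defaults = dict(kind="flat", params=None, n_points=100, extent_um=1500.0)
        defaults.update(kwargs)
        with pytest.raises(InvalidArgumentError):
            generate_profile(**defaults)


class TestGeneratePhantom:
    def test_unperturbed_surface_equals_baseline_trend(self):
        """No roughness, no objects: the ground-truth surface is exactly the
        polynomial trend (recomputed independently here)."""
        spec = PhantomSpec(
            n_outgrowths=0, n_detached=0, n_chambers=0, roughness_amplitude_um=0.0,
            baseline_curvature=(0.01, 2e-4, -1e-7),
        )
        _, truth = generate_phantom(spec)
        nx = spec.grid_shape()[2]
        x = np.arange(nx) * spec.pixel_size_lateral_um
        xc = x - x.mean()
        expected = spec.baseline_depth_um + 0.01 * xc + 2e-4 * xc**2 - 1e-7 * xc**3
        assert np.allclose(truth.surface_depth_um, expected[np.newaxis, :], atol=1e-9)

    def test_detached_volumes_are_analytic_sphere_volumes(self):
        spec = PhantomSpec(
            lateral_extent_um=600, depth_extent_um=600, n_bscans=110,
            baseline_depth_um=350, n_detached=3, detached_radii_um=(30, 50, 80),
            seed=3,
        )
        _, truth = generate_phantom(spec)
        detached = truth.objects_of("detached")
        assert sorted(o.radius_um for o in detached) == [30, 50, 80]
        for o in detached:
            assert o.volume_um3 == pytest.approx(4 / 3 * math.pi * o.radius_um**3)

    def test_object_counts_match_spec(self):
        spec = PhantomSpec(
            lateral_extent_um=600, depth_extent_um=600, n_bscans=110,
            baseline_depth_um=300, n_outgrowths=2,
            outgrowth_radius_range_um=(30, 60), n_detached=2, n_chambers=2,
            seed=4,
        )
        _, truth = generate_phantom(spec)
        for cls, n in (("outgrowth", 2), ("detached", 2), ("chamber", 2)):
            assert len(truth.objects_of(cls)) == n

    def test_bit_identical_for_identical_spec(self):
        spec = PhantomSpec(roughness_amplitude_um=20.0, n_outgrowths=1,
                           outgrowth_radius_range_um=(40, 80), seed=11)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        assert np.array_equal(v1.intensity, v2.intensity)
        assert np.array_equal(t1.surface_depth_um, t2.surface_depth_um)

    def test_depth_attenuation_matches_exponential_factor(self):
        """Mean intensity in a deep tissue slab is lower than in a shallow
        slab by exp(-mu * depth difference); closed-form oracle, 5% band."""
        mu = 0.005
        spec = PhantomSpec(
            baseline_depth_um=120.0, baseline_curvature=(0, 0, 0),
            attenuation_per_um=mu, speckle_shape=16.0, seed=9,
            lateral_extent_um=900.0, n_bscans=10,
        )
        vol, truth = generate_phantom(spec)
        dy = spec.pixel_size_axial_um
        surf_px = int(round(120.0 / dy))
        shallow = vol.intensity[:, surf_px + 10 : surf_px + 20, :].mean()
        deep = vol.intensity[:, surf_px + 60 : surf_px + 70, :].mean()
        expected = math.exp(-mu * 50 * dy)
        assert deep / shallow == pytest.approx(expected, rel=0.05)

    def test_impossible_detached_placement_names_the_class(self):
        spec = PhantomSpec(
            baseline_depth_um=60.0, n_detached=1, detached_radii_um=(100.0,), seed=1
        )
        with pytest.raises(PlacementError, match="detached"):
            generate_phantom(spec)

    def test_untraceable_intensities_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PhantomSpec(tissue_mean_intensity=10.0, background_mean_intensity=20.0).validate()

    def test_bursa_sheet_adds_bright_band_above_surface(self):
        base = PhantomSpec(speckle_shape=64.0, seed=2)
        with_bursa = PhantomSpec(speckle_shape=64.0, seed=2, bursa=True)
        v0, t = generate_phantom(base)
        v1, _ = generate_phantom(with_bursa)
        surf_px = (t.surface_depth_um / 3.0).astype(int)
        band = v1.intensity[0, surf_px[0, 100] - 13, 100]
        assert band > base.tissue_mean_intensity  # elevated sheet
        assert v0.intensity[0, surf_px[0, 100] - 13, 100] < base.tissue_mean_intensity / 2


class TestPhantomIO:
    def test_save_and_reload_ground_truth(self, tmp_path):
        spec = PhantomSpec(
            lateral_extent_um=300, depth_extent_um=300, n_bscans=40,
            baseline_depth_um=150, n_detached=1, detached_radii_um=(25.0,), seed=8,
        )
        vol, truth = generate_phantom(spec)
        save_phantom(vol, truth, tmp_path, "ph")
        loaded = load_ground_truth(tmp_path, "ph")
        assert np.allclose(loaded.surface_depth_um, truth.surface_depth_um, atol=1e-5)
        assert loaded.spec == spec
        o1, o2 = truth.objects_of("detached")[0], loaded.objects_of("detached")[0]
        assert o2.radius_um == pytest.approx(o1.radius_um)
        assert o2.volume_um3 == pytest.approx(o1.volume_um3)

    def test_spec_config_round_trip(self, tmp_path):
        spec = PhantomSpec(roughness_amplitude_um=25.0, n_outgrowths=3, seed=42,
                           bursa=True)
        spec.to_config(tmp_path / "spec.cfg")
        assert PhantomSpec.from_config(tmp_path / "spec.cfg") == spec
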