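import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from gravicreep import (
    CorrelationResult,
    NucleolusCloud,
    NucleusGeometry,
    SedimentationSeries,
    align_gravity_axis,
    asymmetry_z0,
    correlation_with_ci,
    creep_velocity,
    delta_z,
    density_profile,
    fisher_ci,
    fit_ellipsoid,
    fit_power_law,
    force_time_collapse,
    normalize_to_sphere,
    radius_from_profile,
    sample_powerlaw_volumes,
)
from gravicreep.errors import InsufficientDataError
from gravicreep.spatial import mean_body_z, radius_to_volume
from gravicreep.synthetic import synth_cohort, synth_intensity_profile, synth_nucleolus_cloud


def _sliced_geometry(semi_axes, center=(0.0, 0.0, 0.0), step=2.0):
    a, b, c = semi_axes
    zs = np.arange(-c + step, c, step)
    frac = np.sqrt(np.clip(1 - (zs / c) ** 2, 1e-12, None))
    return NucleusGeometry(
        plane_z=zs + center[2],
        plane_center=np.tile(np.asarray(center[:2], float), (zs.size, 1)),
        plane_semi=np.column_stack([a * frac, b * frac]),
    )


class TestFitEllipsoid:
    def test_sphere_recovered_exactly(self):
        geom = fit_ellipsoid(_sliced_geometry((200.0, 200.0, 200.0)))
        np.testing.assert_allclose(geom.ellipsoid_semi_axes, 200.0, atol=1e-3)

    def test_ellipsoid_recovered_within_one_percent(self):
        geom = fit_ellipsoid(_sliced_geometry((220.0, 200.0, 160.0), center=(5.0, -3.0, 7.0)))
        np.testing.assert_allclose(geom.ellipsoid_semi_axes, (220.0, 200.0, 160.0), rtol=0.01)
        np.testing.assert_allclose(geom.ellipsoid_center, (5.0, -3.0, 7.0), atol=1.0)

    def test_cross_section_areas_reproduced(self):
        raw = _sliced_geometry((220.0, 200.0, 160.0))
        geom = fit_ellipsoid(raw)
        a, b, c = geom.ellipsoid_semi_axes
        z0 = geom.ellipsoid_center[2]
        pred = np.pi * a * b * np.clip(1 - ((raw.plane_z - z0) / c) ** 2, 0, None)
        np.testing.assert_allclose(pred, raw.plane_area, rtol=0.01)

    def test_too_few_planes_rejected(self):
        geom = _sliced_geometry((200.0, 200.0, 200.0))
        small = NucleusGeometry(
            plane_z=geom.plane_z[:3],
            plane_center=geom.plane_center[:3],
            plane_semi=geom.plane_semi[:3],
        )
        with pytest.raises(InsufficientDataError):
            fit_ellipsoid(small)


class TestNormalizeToSphere:
    def test_spherical_nucleus_is_identity(self):
        geom = fit_ellipsoid(_sliced_geometry((200.0, 200.0, 200.0)))
        rng = np.random.default_rng(0)
        pos = rng.normal(0, 50, (40, 3))
        cloud = NucleolusCloud(positions=pos, radii=np.ones(40))
        out = normalize_to_sphere(cloud, geom)
        np.testing.assert_allclose(out.positions, pos, atol=1e-3)
        np.testing.assert_allclose(out.radii, cloud.radii)

    def test_surface_point_maps_to_sphere_surface(self):
        axes = (220.0, 200.0, 160.0)
        geom = fit_ellipsoid(_sliced_geometry(axes))
        p = np.array([[220.0, 0.0, 0.0], [0.0, 0.0, -160.0]])
        out = normalize_to_sphere(
            NucleolusCloud(positions=p, radii=np.ones(2)), geom
        )
        r = np.linalg.norm(out.positions - geom.ellipsoid_center, axis=1)
        target = np.prod(geom.ellipsoid_semi_axes) ** (1 / 3)
        np.testing.assert_allclose(r, target, rtol=0.01)
        assert out.nucleus_radius == pytest.approx(target)

    def test_z_ordering_preserved(self):
        geom = fit_ellipsoid(_sliced_geometry((220.0, 200.0, 160.0)))
        rng = np.random.default_rng(1)
        pos = rng.uniform(-100, 100, (50, 3))
        out = normalize_to_sphere(NucleolusCloud(positions=pos, radii=np.ones(50)), geom)
        for axis in range(3):
            assert np.array_equal(
                np.argsort(pos[:, axis]), np.argsort(out.positions[:, axis])
            )

    def test_frame_mismatch_rejected(self):
        geom = fit_ellipsoid(_sliced_geometry((200.0, 200.0, 200.0)))
        cloud = NucleolusCloud(
            positions=np.zeros((1, 3)), radii=np.ones(1), frame="sphere-normalized",
            nucleus_center=np.zeros(3), nucleus_radius=200.0,
        )
        with pytest.raises(ValueError):
            normalize_to_sphere(cloud, geom)


def _sphere_cloud(mean_offset, n=200, R=200.0, seed=2):
    """Cloud in a sphere-normalized frame with a controlled mean offset."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(0, 20, (n, 3)) - np.mean(rng.normal(0, 20, (n, 3)), axis=0)
    pos = pos - pos.mean(axis=0) + np.asarray(mean_offset, float)
    return NucleolusCloud(
        positions=pos, radii=np.ones(n), frame="sphere-normalized",
        nucleus_center=np.zeros(3), nucleus_radius=R,
    )


class TestAlignGravityAxis:
    def test_mean_already_down_keeps_orientation(self):
        cloud = _sphere_cloud([0.0, 0.0, -50.0])
        out = align_gravity_axis(cloud)
        np.testing.assert_allclose(
            out.positions[:, :2], cloud.positions[:, :2], atol=1e-9
        )
        assert out.positions[:, 2].mean() == pytest.approx(150.0, abs=1e-9)

    def test_mean_along_x_rotated_onto_axis(self):
        out = align_gravity_axis(_sphere_cloud([50.0, 0.0, 0.0]))
        m = out.positions.mean(axis=0)
        assert abs(m[0]) < 1e-9 and abs(m[1]) < 1e-9
        assert m[2] == pytest.approx(150.0, abs=1e-9)

    def test_matches_independent_rotation_oracle(self):
        offset = np.array([30.0, -20.0, 10.0])
        cloud = _sphere_cloud(offset, seed=5)
        out = align_gravity_axis(cloud)
        # oracle: scipy align_vectors for the same axis pair
        rot, _ = Rotation.align_vectors([[0.0, 0.0, -1.0]], [offset / np.linalg.norm(offset)])
        expected = rot.apply(cloud.positions)
        expected[:, 2] += 200.0
        np.testing.assert_allclose(out.positions, expected, atol=1e-8)

    def test_degenerate_axis_flagged(self):
        out = align_gravity_axis(_sphere_cloud([0.0, 0.0, 0.0]))
        assert out.degenerate_axis


class TestAsymmetry:
    def test_constructed_offset(self):
        out = align_gravity_axis(_sphere_cloud([0.0, 0.0, -50.0]))
        assert asymmetry_z0(out) == pytest.approx(50.0, abs=1e-9)

    def test_symmetric_cloud_near_zero(self):
        sc = synth_nucleolus_cloud(n_bodies=4000, target_z0=0.0, seed=8)
        aligned = align_gravity_axis(
            normalize_to_sphere(sc.cloud, fit_ellipsoid(sc.geometry))
        )
        # alignment always produces z0 = |mean offset| >= 0; for a uniform
        # cloud it concentrates near 0 at rate ~ R/sqrt(n)
        assert asymmetry_z0(aligned) < 3 * 200.0 / np.sqrt(4000)

    def test_generator_target_recovered(self):
        sc = synth_nucleolus_cloud(n_bodies=500, target_z0=50.0, seed=3)
        aligned = align_gravity_axis(
            normalize_to_sphere(sc.cloud, fit_ellipsoid(sc.geometry))
        )
        assert asymmetry_z0(aligned) == pytest.approx(50.0, abs=5.0)


class TestPipelineEquivariance:
    def test_translation_leaves_statistics_unchanged(self):
        sc = synth_nucleolus_cloud(n_bodies=400, target_z0=40.0, seed=9)
        aligned = align_gravity_axis(
            normalize_to_sphere(sc.cloud, fit_ellipsoid(sc.geometry))
        )
        shift = np.array([120.0, -60.0, 35.0])
        moved_cloud = NucleolusCloud(
            positions=sc.cloud.positions + shift, radii=sc.cloud.radii
        )
        moved_geom = NucleusGeometry(
            plane_z=sc.geometry.plane_z + shift[2],
            plane_center=sc.geometry.plane_center + shift[:2],
            plane_semi=sc.geometry.plane_semi,
        )
        aligned2 = align_gravity_axis(
            normalize_to_sphere(moved_cloud, fit_ellipsoid(moved_geom))
        )
        assert asymmetry_z0(aligned2) == pytest.approx(asymmetry_z0(aligned), abs=1e-6)
        p1 = density_profile(aligned).normalized_counts
        p2 = density_profile(aligned2).normalized_counts
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestDensityProfile:
    def test_single_body_single_bin(self):
        cloud = NucleolusCloud(
            positions=[[0.0, 0.0, 30.0]], radii=[1.0], frame="gravity-aligned",
            nucleus_center=np.array([0.0, 0.0, 200.0]), nucleus_radius=200.0,
        )
        prof = density_profile(cloud)
        assert prof.normalized_counts[1] == 1.0
        assert prof.normalized_counts.sum() == pytest.approx(1.0)

    def test_uniform_cloud_flat_interior(self):
        rng = np.random.default_rng(4)
        n = 10_000
        z = rng.uniform(0.0, 400.0, n)
        pos = np.column_stack([np.zeros(n), np.zeros(n), z])
        cloud = NucleolusCloud(
            positions=pos, radii=np.ones(n), frame="gravity-aligned",
            nucleus_center=np.array([0.0, 0.0, 200.0]), nucleus_radius=200.0,
        )
        prof = density_profile(cloud)
        p = 1.0 / prof.normalized_counts.size
        sigma = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(prof.normalized_counts - p) < 3 * sigma + 1e-12)

    def test_sedimented_cloud_mass_at_bottom(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0.0, 15.0, 500)
        cloud = NucleolusCloud(
            positions=np.column_stack([np.zeros(500), np.zeros(500), z]),
            radii=np.ones(500), frame="gravity-aligned",
            nucleus_center=np.array([0.0, 0.0, 200.0]), nucleus_radius=200.0,
        )
        prof = density_profile(cloud)
        assert prof.normalized_counts[0] == pytest.approx(1.0)


class TestDeltaZ:
    def _aligned(self, zshift, seed):
        return align_gravity_axis(_sphere_cloud([0.0, 0.0, -50.0 - zshift], seed=seed))

    def test_identical_cohort_zero(self):
        ref = mean_body_z(self._aligned(0.0, 1))
        out = delta_z(ref, [self._aligned(0.0, 1)])
        assert out["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_constructed_displacement(self):
        ref = mean_body_z(self._aligned(0.0, 2))
        out = delta_z(ref, [self._aligned(30.0, 2)])
        assert out["mean"] == pytest.approx(30.0, abs=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            delta_z(100.0, [])

    def test_synthetic_cohort_recovery(self):
        co = synth_cohort(
            viscosity=1.7, scatter_um=3.0, include_clouds=True, n_nuclei=4,
            n_bodies=150, schedule={100.0: (1200.0, 3000.0)}, seed=12,
        )
        s = co.series[0]
        for j, t in enumerate(s.times):
            clouds = co.clouds[(100.0, float(t))]
            est = delta_z(co.reference_mean_z, clouds)
            tol = max(3 * est["sem"], 3.0) + 3.0 * 200.0 / np.sqrt(150 * 4)
            assert est["mean"] == pytest.approx(s.delta_z[j], abs=tol)


class TestCreepVelocity:
    def test_exact_line(self):
        t = np.array([60.0, 120.0, 300.0, 600.0])
        s = SedimentationSeries(100.0, t, 0.05 * t, r_median=1.0)
        out = creep_velocity(s)
        assert out["velocity"] == pytest.approx(0.05, rel=1e-12)

    def test_velocity_doubles_with_gravity(self):
        co = synth_cohort(viscosity=1.7, schedule={10.0: (600.0, 1200.0, 2400.0),
                                                   20.0: (600.0, 1200.0, 2400.0)}, seed=0)
        v = {s.g_multiple: creep_velocity(s)["velocity"] for s in co.series}
        assert v[20.0] / v[10.0] == pytest.approx(2.0, rel=1e-9)

    def test_ci_coverage_on_noisy_series(self):
        rng = np.random.default_rng(6)
        t = np.linspace(100.0, 2000.0, 8)
        v_true = 0.03
        hits = 0
        for k in range(100):
            d = v_true * t + rng.normal(0, 5.0, t.size)
            out = creep_velocity(SedimentationSeries(100.0, t, d, r_median=1.0))
            hits += out["ci95"][0] <= v_true <= out["ci95"][1]
        assert hits >= 90

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            creep_velocity(SedimentationSeries(1.0, [0.0, 1.0], [0.0, 1.0], r_median=1.0))


class TestForceTimeCollapse:
    def test_single_exact_series(self):
        co = synth_cohort(viscosity=2.5, schedule={100.0: (600.0, 1200.0)}, seed=0)
        out = force_time_collapse(co.series)
        assert out["viscosity"] == pytest.approx(2.5, rel=1e-9)

    def test_full_sweep_recovers_viscosity(self):
        co = synth_cohort(viscosity=1.7, seed=1)
        out = force_time_collapse(co.series)
        assert out["viscosity"] == pytest.approx(1.7, rel=0.02)
        for eta in out["per_condition"].values():
            assert eta == pytest.approx(1.7, rel=0.02)

    def test_collapse_overlays_at_common_u(self):
        """Matched u = g*t gives identical expected delta-z regardless of g."""
        co = synth_cohort(
            viscosity=1.7,
            schedule={10.0: (12000.0,), 100.0: (1200.0,), 1000.0: (120.0,)},
            seed=2,
        )
        dzs = [s.delta_z[0] for s in co.series]
        assert max(dzs) - min(dzs) < 0.05 * max(dzs) + 1e-12

    def test_inconsistent_density_metadata_rejected(self):
        s1 = SedimentationSeries(10.0, [60.0, 120.0], [1.0, 2.0], 1.0, delta_rho=50.0)
        s2 = SedimentationSeries(10.0, [60.0, 120.0], [1.0, 2.0], 1.0, delta_rho=80.0)
        with pytest.raises(ValueError):
            force_time_collapse([s1, s2])


class TestPowerLawFit:
    def test_exponent_recovered_at_large_n(self):
        v = sample_powerlaw_volumes(100_000, -1.5, 1.0, 4000.0, seed=7)
        fit = fit_power_law(v, 1.0, 4000.0)
        assert fit.exponent == pytest.approx(-1.5, abs=0.05)
        assert fit.ci95[0] < fit.exponent < fit.ci95[1]

    def test_scale_invariance(self):
        v = sample_powerlaw_volumes(5000, -1.5, 1.0, 4000.0, seed=8)
        f1 = fit_power_law(v, 1.0, 4000.0)
        f2 = fit_power_law(10.0 * v, 10.0, 40000.0)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-6)

    def test_mle_matches_grid_search(self):
        from gravicreep.spatial import _powerlaw_loglik

        v = sample_powerlaw_volumes(2000, -1.8, 0.5, 500.0, seed=9)
        fit = fit_power_law(v, 0.5, 500.0)
        grid = np.arange(-3.0, 0.0, 1e-4)
        logs = np.log(v)
        ll = [_powerlaw_loglik(a, logs, 0.5, 500.0) for a in grid]
        assert fit.exponent == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_exponent_sweep_recovery(self):
        for alpha in (-1.2, -1.5, -2.0):
            v = sample_powerlaw_volumes(30_000, alpha, 1.0, 4000.0, seed=10)
            fit = fit_power_law(v, 1.0, 4000.0)
            assert fit.exponent == pytest.approx(alpha, abs=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_power_law([1.0, 2.0, 3.0], 0.5, 10.0)


class TestRadiusFromProfile:
    def test_exact_gaussian_closed_form(self):
        sigma = 2.0
        x = np.linspace(-10, 10, 301)
        y = np.exp(-(x**2) / (2 * sigma**2))
        assert radius_from_profile(x, y) == pytest.approx(sigma * np.sqrt(2 * np.log(2)), rel=1e-6)

    def test_amplitude_invariance(self):
        x, y, truth = synth_intensity_profile(2.355, amplitude=1.0)
        x2, y2, _ = synth_intensity_profile(2.355, amplitude=7.0)
        assert radius_from_profile(x, y) == pytest.approx(radius_from_profile(x2, y2), rel=1e-9)

    def test_noisy_median_within_three_percent(self):
        rs = []
        for k in range(100):
            x, y, truth = synth_intensity_profile(3.0, noise_sd=0.05, seed=k)
            rs.append(radius_from_profile(x, y))
        assert np.median(rs) == pytest.approx(3.0, rel=0.03)


class TestCorrelation:
    def test_perfect_correlation_degenerate(self):
        x = np.arange(10.0)
        res = correlation_with_ci(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.degenerate

    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.46, 43, (0.19, 0.67)), (0.67, 205, (0.59, 0.74))],
    )
    def test_reported_interval_pairs(self, r, n, expected):
        lo, hi = fisher_ci(r, n)
        assert round(lo, 2) == expected[0]
        assert round(hi, 2) == expected[1]
        res = CorrelationResult.from_r(r, n)
        assert res.ci95 == (lo, hi)

    def test_matches_data_driven_computation(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = correlation_with_ci(x, y)
        r_ref = stats.pearsonr(x, y).statistic
        assert res.r == pytest.approx(r_ref, rel=1e-12)
        assert res.ci95 == fisher_ci(res.r, 60)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_ci(np.ones(10), np.arange(10.0))

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation_with_ci([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
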