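import numpy as np
import pytest
from scipy import stats

from phasemc.core import ConfigurationError, RngStream
from phasemc.sources import (AxiconSpec, BeamSpec, PlanoConvexLensSpec,
                             SlitPairSpec, TargetPlane, apply_helical_delay,
                             bundle_compression, initial_amplitude,
                             sample_gaussian_xy, sample_huygens_direction,
                             sample_slit_pair, sample_square_aperture,
                             trace_axicon, trace_planoconvex)


class TestInitialAmplitude:
    def test_zero_power(self, beam_488):
        beam = BeamSpec(wavelength=0.488, power=0.0, profile="plane", area=1e6)
        assert initial_amplitude(beam, 100) == 0.0

    def test_direct_substitution(self):
        # 1 mW over 1 mm² with a single packet: E₀ = √(P/A)
        beam = BeamSpec(wavelength=0.488, power=1e-3, profile="plane", area=1e6)
        assert initial_amplitude(beam, 1) == pytest.approx(np.sqrt(1e-3 / 1e6))

    def test_in_phase_packets_recover_power_density(self, beam_488):
        """N in-phase packets in one bin give intensity N²E₀² = P/A."""
        from phasemc.detect import FieldAccumulator

        n = 250
        e0 = initial_amplitude(beam_488, n)
        acc = FieldAccumulator(origin=(0.0, 0.0), bin_size=(1.0, 1.0), counts=(1, 1))
        acc.add_fields(np.full((n, 2), 0.5), np.full(n, e0, dtype=complex))
        intensity = acc.intensity("raw").values[0, 0]
        assert intensity == pytest.approx(beam_488.power / beam_488.area, rel=1e-12)

    def test_zero_area_rejected(self):
        beam = BeamSpec(wavelength=0.488, power=1e-3, profile="plane", area=None)
        with pytest.raises(ConfigurationError):
            initial_amplitude(beam, 10)


class TestSlitSampling:
    def test_positions_inside_slits(self, slit_pair_488, beam_488, rng):
        rays = sample_slit_pair(slit_pair_488, beam_488, rng, 100000)
        x = rays.points[:, 0]
        half_w = slit_pair_488.slit_width / 2
        d2 = slit_pair_488.separation / 2
        in_left = np.abs(x + d2) <= half_w
        in_right = np.abs(x - d2) <= half_w
        assert np.all(in_left | in_right)
        assert np.all(rays.optical_path == 0.0)

    def test_slit_choice_is_balanced(self, slit_pair_488, beam_488, rng):
        n = 100000
        rays = sample_slit_pair(slit_pair_488, beam_488, rng, n)
        frac = np.mean(rays.points[:, 0] > 0)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_within_slit_uniformity(self, slit_pair_488, beam_488, rng):
        """Positions inside one slit pass a KS test against the uniform CDF."""
        rays = sample_slit_pair(slit_pair_488, beam_488, rng, 100000)
        x = rays.points[:, 0]
        d2, half_w = slit_pair_488.separation / 2, slit_pair_488.slit_width / 2
        left = x[np.abs(x + d2) <= half_w]
        u = (left + d2 + half_w) / slit_pair_488.slit_width
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_square_aperture_centred(self, beam_488, rng):
        from phasemc.sources import SquareApertureSpec

        spec = SquareApertureSpec(side=100.0, screen_distance=28490.0)
        rays = sample_square_aperture(spec, beam_488, rng, 100000)
        assert np.all(np.abs(rays.points[:, :2]) <= 50.0)
        sem = 100.0 / np.sqrt(12 * 100000)
        assert np.all(np.abs(rays.points[:, :2].mean(axis=0)) < 3 * sem)


class TestHuygensDirections:
    target = TargetPlane(z=1000.0, half_extent=(50.0, 50.0))

    def test_unit_norm_and_forward(self, rng):
        origins = np.random.default_rng(0).uniform(-10, 10, (10000, 3)) * [1, 1, 0]
        d, _ = sample_huygens_direction(origins, self.target, rng)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        assert np.all(d[:, 2] > 0)  # no backward wavelets

    def test_landing_points_uniform_on_target(self, rng):
        """Straight flights land uniformly over the target rectangle."""
        origins = np.zeros((50000, 3))
        d, targets = sample_huygens_direction(origins, self.target, rng)
        t = (self.target.z - origins[:, 2]) / d[:, 2]
        landing = origins[:, :2] + t[:, None] * d[:, :2]
        np.testing.assert_allclose(landing, targets[:, :2], atol=1e-9)
        for axis in range(2):
            u = (landing[:, axis] + 50.0) / 100.0
            assert stats.kstest(u, "uniform").pvalue > 0.01


class TestPlanoConvexTracing:
    def test_on_axis_ray(self, silica_lens):
        for orientation in ("convex_first", "flat_first"):
            spec = PlanoConvexLensSpec(radius=5000.0, thickness=2200.0, roc=4600.0,
                                       n_lens=1.4631, orientation=orientation)
            rays = trace_planoconvex(np.array([[0.0, 0.0]]), spec)
            assert rays.valid[0]
            assert rays.optical_path[0] == pytest.approx(spec.n_lens * spec.thickness)
            np.testing.assert_allclose(rays.direction[0], [0, 0, 1], atol=1e-12)

    def test_paraxial_focal_length_flat_first(self):
        """Snell ray-trace continuations cross the axis at f = R/(n−1) ± 1%."""
        spec = PlanoConvexLensSpec(radius=5000.0, thickness=2200.0, roc=4600.0,
                                   n_lens=1.4631, orientation="flat_first")
        h = np.array([[50.0, 0.0], [100.0, 0.0]])
        rays = trace_planoconvex(h, spec)
        t_cross = -rays.points[:, 0] / rays.direction[:, 0]
        z_cross = rays.points[:, 2] + t_cross * rays.direction[:, 2]
        f = 4600.0 / 0.4631
        np.testing.assert_allclose(z_cross - spec.thickness, f, rtol=0.01)

    def test_working_distance_convex_first(self, silica_lens):
        h = np.array([[50.0, 0.0], [100.0, 0.0]])
        rays = trace_planoconvex(h, silica_lens)
        t_cross = -rays.points[:, 0] / rays.direction[:, 0]
        z_cross = rays.points[:, 2] + t_cross * rays.direction[:, 2]
        f = 4600.0 / 0.4631
        bfd = f - 2200.0 / 1.4631
        np.testing.assert_allclose(z_cross - silica_lens.thickness, bfd, rtol=0.01)

    def test_aperture_miss_flagged(self, silica_lens):
        rays = trace_planoconvex(np.array([[4900.0, 0.0]]), silica_lens)
        assert not rays.valid[0]

    def test_bundle_compression(self, silica_lens, axicon_5deg):
        m = bundle_compression(silica_lens)
        t, R, n = 2200.0, 4600.0, 1.4631
        assert m == pytest.approx(1 - t * (n - 1) / (n * R))
        flat = PlanoConvexLensSpec(radius=5000.0, thickness=2200.0, roc=4600.0,
                                   n_lens=1.4631, orientation="flat_first")
        assert bundle_compression(flat) == 1.0
        assert bundle_compression(axicon_5deg) == 1.0


class TestAxiconTracing:
    def test_deflection_matches_snell(self, axicon_5deg):
        """Exit rays are bent toward the axis by β = arcsin(n·sinα) − α."""
        rays = trace_axicon(np.array([[3000.0, 0.0]]), axicon_5deg)
        d = rays.direction[0]
        beta = np.arctan2(-d[0], d[2])
        expected = np.arcsin(axicon_5deg.n_lens * np.sin(axicon_5deg.alpha)) - axicon_5deg.alpha
        assert beta == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx((axicon_5deg.n_lens - 1) * axicon_5deg.alpha,
                                         rel=0.01)

    def test_apex_ray_undeviated(self, axicon_5deg):
        rays = trace_axicon(np.array([[0.0, 0.0]]), axicon_5deg)
        np.testing.assert_allclose(rays.direction[0], [0, 0, 1], atol=1e-15)
        assert rays.valid[0]

    def test_azimuthal_invariance(self, axicon_5deg):
        """A ring of rays exits on the cone at the same radius with equal OPL."""
        phi = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        r = 4000.0
        xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        rays = trace_axicon(xy, axicon_5deg)
        np.testing.assert_allclose(np.hypot(rays.points[:, 0], rays.points[:, 1]), r)
        assert np.ptp(rays.optical_path) < 1e-9
        expected_z = axicon_5deg.thickness - r * np.tan(axicon_5deg.alpha)
        np.testing.assert_allclose(rays.points[:, 2], expected_z)

    def test_outside_radius_discarded(self, axicon_5deg):
        rays = trace_axicon(np.array([[13000.0, 0.0]]), axicon_5deg)
        assert not rays.valid[0]


class TestHelicalDelay:
    def test_zero_order_is_identity(self, axicon_5deg):
        rays = trace_axicon(np.array([[1000.0, 1000.0]]), axicon_5deg)
        before = rays.optical_path.copy()
        apply_helical_delay(rays, axicon_5deg, 0.488)
        np.testing.assert_array_equal(rays.optical_path, before)

    def test_first_order_half_turn_gives_half_wave(self):
        spec = AxiconSpec(alpha=np.deg2rad(5.0), radius=12700.0, n_lens=1.4631,
                          helical_order=1, thickness=2200.0)
        rays = trace_axicon(np.array([[-1000.0, 0.0]]), spec)  # azimuth π
        before = rays.optical_path.copy()
        apply_helical_delay(rays, spec, 0.488)
        assert rays.optical_path[0] - before[0] == pytest.approx(0.488 / 2)

    def test_first_order_vortex_null(self):
        """A first-order helical axicon leaves an on-axis intensity minimum."""
        from phasemc import cli

        cfg = cli.fixture_config("bessel_axicon")
        cfg.element = AxiconSpec(alpha=np.deg2rad(5.0), radius=12700.0,
                                 n_lens=1.4631, helical_order=1, thickness=2200.0)
        cfg.n_packets = 2_000_000
        res = cli.run_experiment(cfg)
        v = res.image.values
        centre = v[v.shape[0] // 2, v.shape[1] // 2]
        assert centre < 0.2 * v.max()


class TestGaussianSampling:
    def test_amplitude_profile_width(self, rng):
        """Launch density carries the field amplitude: σ = w/√2 per axis."""
        e2_width = 1000.0
        xy = sample_gaussian_xy(e2_width, rng, 200000)
        w = e2_width / 2
        assert xy.std(axis=0) == pytest.approx(w / np.sqrt(2), rel=0.01)

    def test_aperture_rejection(self, rng):
        xy = sample_gaussian_xy(1000.0, rng, 50000, max_radius=400.0)
        assert np.all(np.hypot(xy[:, 0], xy[:, 1]) <= 400.0)


class TestSeedContract:
    def test_different_seeds_same_statistics(self, slit_pair_488, beam_488):
        """Two seeds give different streams but matching summary statistics."""
        n = 200000
        a = sample_slit_pair(slit_pair_488, beam_488, RngStream(1), n)
        b = sample_slit_pair(slit_pair_488, beam_488, RngStream(2), n)
        assert not np.allclose(a.points[:100], b.points[:100])
        sem = slit_pair_488.separation / 2 / np.sqrt(n)
        assert abs(a.points[:, 0].mean() - b.points[:, 0].mean()) < 6 * sem
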