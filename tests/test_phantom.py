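import dataclasses

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as stn
from scipy.integrate import quad

from paraft import (
    ParaboloidSource,
    PhantomSpec,
    analytical_signal,
    arc_integral,
    fov_time_axis,
    make_image_coords,
    open_dataset,
    rasterize,
    ring_geometry,
    sample_phantom,
    simulate_dynamic_dataset,
)
from paraft.coords import image_grid_vectors
from paraft.phantom import (
    DynamicSpectralSpec,
    _arc_integral_vec,
    gas_waveform,
    so2_timecourse,
)

FOV = 0.025


class TestSamplePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = sample_phantom(fov=FOV, seed=42)
        b = sample_phantom(fov=FOV, seed=42)
        assert a == b

    def test_forced_single_source(self):
        r = 0.1 * FOV
        spec = sample_phantom(
            n_sources_range=(1, 1), radius_range=(r, r), fov=FOV, seed=0
        )
        assert len(spec.sources) == 1
        assert spec.sources[0].radius == pytest.approx(r)

    @pytest.mark.parametrize("seed", range(10))
    def test_constraints_hold_across_seeds(self, seed):
        spec = sample_phantom(fov=FOV, seed=seed)
        half = FOV / 2
        for s in spec.sources:
            assert abs(s.center[0]) + s.radius <= half
            assert abs(s.center[1]) + s.radius <= half
        for i, a in enumerate(spec.sources):
            for b in spec.sources[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                assert d > a.radius + b.radius

    def test_batch_of_fifty_valid_specs(self):
        specs = [sample_phantom(fov=FOV, seed=s) for s in range(50)]
        assert len(specs) == 50
        assert all(isinstance(s, PhantomSpec) for s in specs)

    def test_overlapping_spec_rejected(self):
        s1 = ParaboloidSource((0.0, 0.0), 0.002, 1.0)
        s2 = ParaboloidSource((0.001, 0.0), 0.002, 1.0)
        with pytest.raises(ValueError):
            PhantomSpec(sources=(s1, s2), fov=FOV)


class TestRasterize:
    def test_profile_values_and_linearity(self):
        coords = make_image_coords(101, FOV)
        yc, xc = image_grid_vectors(coords)
        s1 = ParaboloidSource((0.0, 0.0), 0.003, 1.7)
        s2 = ParaboloidSource((0.008, 0.008), 0.002, 0.9)
        spec = PhantomSpec(sources=(s1, s2), fov=FOV)
        img = rasterize(spec, coords).pixels
        # peak of source 1 sits on the exact grid center
        assert img[50, 50] == pytest.approx(1.7)
        # additivity over disjoint sources
        i1 = rasterize(PhantomSpec((s1,), FOV), coords).pixels
        i2 = rasterize(PhantomSpec((s2,), FOV), coords).pixels
        np.testing.assert_allclose(img, i1 + i2, atol=1e-15)
        assert img.min() >= 0.0

    def test_zero_on_source_boundary(self):
        s = ParaboloidSource((0.0, 0.0), 0.004, 1.0)
        # evaluate the profile exactly at |r - c| = R via the arc integral at D=0
        assert arc_integral(s, (0.0, 0.0), s.radius) == 0.0


class TestArcIntegral:
    SRC = ParaboloidSource((0.003, -0.001), 0.002, 1.3)
    DET = (0.02, 0.01)

    def test_disjoint_circle_is_zero(self):
        D = np.hypot(self.SRC.center[0] - self.DET[0], self.SRC.center[1] - self.DET[1])
        assert arc_integral(self.SRC, self.DET, 1.2 * (D + self.SRC.radius)) == 0.0
        assert arc_integral(self.SRC, self.DET, 0.5 * (D - self.SRC.radius)) == 0.0

    def test_concentric_closed_form(self):
        s = ParaboloidSource((0.0, 0.0), 0.004, 2.0)
        rho = s.radius / 2
        expected = 2 * np.pi * rho * s.amplitude * 0.75
        assert arc_integral(s, (0.0, 0.0), rho) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("frac", [-0.5, 0.0, 0.5, 0.9])
    def test_matches_adaptive_quadrature(self, frac):
        src, det = self.SRC, self.DET
        D = np.hypot(src.center[0] - det[0], src.center[1] - det[1])
        rho = D + frac * src.radius
        thc = np.arctan2(src.center[1] - det[1], src.center[0] - det[0])

        def integrand(th):
            x = det[0] + rho * np.cos(th)
            y = det[1] + rho * np.sin(th)
            s2 = (x - src.center[0]) ** 2 + (y - src.center[1]) ** 2
            return src.amplitude * max(0.0, 1 - s2 / src.radius**2) * rho

        oracle, _ = quad(
            integrand, thc - np.pi, thc + np.pi,
            points=[thc - 0.3, thc, thc + 0.3], limit=800,
            epsabs=1e-16, epsrel=1e-12,
        )
        assert arc_integral(src, det, rho) == pytest.approx(oracle, rel=1e-8)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            arc_integral(self.SRC, self.DET, -1e-3)

    @given(stn.floats(min_value=0.2, max_value=3.0))
    def test_continuous_at_tangency_radii(self, d_over_r):
        # D = R degenerates: the inner "tangency" collapses to the disc
        # center, where the integral vanishes quadratically instead
        assume(abs(d_over_r - 1.0) > 0.05)
        A, R = 1.0, 0.002
        D = d_over_r * R
        eps = 1e-6 * R
        from paraft.phantom import _arc_integral_derivative_vec

        for rt in (abs(D - R), D + R):
            lo = _arc_integral_vec(A, R, D, np.array([max(rt - eps, 0.0)]))[0]
            hi = _arc_integral_vec(A, R, D, np.array([rt + eps]))[0]
            # continuity: the change across +-eps is bounded by the local
            # slope (finite on both sides of a tangency radius) plus the
            # eps^(3/2) growth of the sliver just past tangency
            slope = np.abs(
                _arc_integral_derivative_vec(
                    A, R, D, np.array([max(rt - 1e-3 * R, 0.0), rt + 1e-3 * R])
                )
            ).max()
            # 1.2x: the probed slope can slightly undershoot the interval max
            assert abs(hi - lo) <= 1.2 * (2 * eps * slope) + 1e-8 * A * R


class TestAnalyticalSignal:
    def test_empty_source_list_gives_silence(self, small_geometry, small_time_axis):
        spec = PhantomSpec(sources=(), fov=FOV)
        sig = analytical_signal(spec, small_geometry, small_time_axis)
        assert np.all(sig.samples == 0.0)

    def test_linear_in_amplitudes(self, small_geometry, small_time_axis):
        spec = sample_phantom(fov=FOV, seed=7)
        doubled = PhantomSpec(
            sources=tuple(
                dataclasses.replace(s, amplitude=2 * s.amplitude) for s in spec.sources
            ),
            fov=FOV,
        )
        s1 = analytical_signal(spec, small_geometry, small_time_axis).samples
        s2 = analytical_signal(doubled, small_geometry, small_time_axis).samples
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12, atol=1e-18)

    def test_matches_finite_difference_of_arc_integral(self, small_geometry, small_time_axis):
        spec = sample_phantom(n_sources_range=(1, 1), fov=FOV, seed=3)
        src = spec.sources[0]
        sig = analytical_signal(spec, small_geometry, small_time_axis).samples
        vs = small_geometry.speed_of_sound
        rho = vs * small_time_axis.values
        h = vs * small_time_axis.spacing / 100.0
        fd = np.empty_like(sig)
        for d in range(small_geometry.n_detectors):
            D = float(
                np.hypot(
                    src.center[0] - small_geometry.positions[d, 0],
                    src.center[1] - small_geometry.positions[d, 1],
                )
            )
            g_p = _arc_integral_vec(src.amplitude, src.radius, D, rho + h)
            g_m = _arc_integral_vec(src.amplitude, src.radius, D, np.maximum(rho - h, 0))
            fd[d] = (g_p - g_m) / (2 * h) / (2 * np.pi)
        rel = np.linalg.norm(sig - fd) / np.linalg.norm(fd)
        assert rel < 1e-5

    def test_signal_integrates_to_zero(self, small_geometry):
        """Derivative of a compactly supported function sums to ~0 over the
        record. The sum is a Riemann quadrature whose error is dominated by
        the square-root kinks at the tangency radii, so the asymptotic
        property needs dense time sampling to be resolved."""
        spec = sample_phantom(fov=FOV, seed=11)
        ta = fov_time_axis(small_geometry, FOV, n_samples=32768)
        sig = analytical_signal(spec, small_geometry, ta)
        duration = ta.values[-1] - ta.values[0]
        sums = np.abs(sig.samples.sum(axis=1) * sig.dt)
        assert np.all(sums < 1e-6 * np.abs(sig.samples).max(axis=1) * duration)


def _tiny_dynamic_spec(**overrides):
    hbtot = sample_phantom(
        n_sources_range=(2, 2),
        radius_range=(0.1 * FOV, 0.15 * FOV),
        fov=FOV,
        seed=5,
    )
    kwargs = dict(total_hemoglobin=hbtot, n_cycles=2, frame_period=10.0, seed=9)
    kwargs.update(overrides)
    return DynamicSpectralSpec(**kwargs)


class TestDynamicDataset:
    def test_static_oxygenation_gives_identical_frames_per_wavelength(self, tmp_path):
        dyn = _tiny_dynamic_spec(so2_baseline=0.7, so2_hyperoxic=0.7, noise_sigma=0.0)
        geom = ring_geometry(16, arc_deg=360.0)
        coords = make_image_coords(16, FOV)
        path = simulate_dynamic_dataset(dyn, geom, coords, tmp_path / "d.h5", n_samples=64)
        with open_dataset(path) as store:
            f0 = store.get_frame(0).samples
            f6 = store.get_frame(6).samples  # same wavelength, next cycle
            np.testing.assert_array_equal(f0, f6)

    def test_fixed_seed_store_is_byte_identical(self, tmp_path):
        dyn = _tiny_dynamic_spec(noise_sigma=0.3, noise_relative=True)
        geom = ring_geometry(16, arc_deg=360.0)
        coords = make_image_coords(16, FOV)
        p1 = simulate_dynamic_dataset(dyn, geom, coords, tmp_path / "a.h5", n_samples=64)
        p2 = simulate_dynamic_dataset(dyn, geom, coords, tmp_path / "b.h5", n_samples=64)
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_so2_truth_follows_exponential_transition_model(self, tmp_path):
        dyn = _tiny_dynamic_spec(n_cycles=6)
        geom = ring_geometry(16, arc_deg=360.0)
        coords = make_image_coords(16, FOV)
        path = simulate_dynamic_dataset(dyn, geom, coords, tmp_path / "d.h5", n_samples=64)
        with open_dataset(path) as store:
            truth = store.truth()
        times = truth["times"]
        expected = so2_timecourse(
            times, dyn.so2_baseline, dyn.so2_hyperoxic, dyn.transition_rate, dyn.switch_times
        )
        tissue = truth["hbtot"] > 0
        iy, ix = np.argwhere(tissue)[0]
        np.testing.assert_allclose(truth["so2"][:, iy, ix], expected, rtol=1e-12)
        np.testing.assert_array_equal(
            truth["waveform"], gas_waveform(times, dyn.switch_times)
        )

    def test_wavelength_outside_spectra_rejected(self, tmp_path):
        dyn = _tiny_dynamic_spec(wavelengths=(650.0, 800.0))
        geom = ring_geometry(16, arc_deg=360.0)
        coords = make_image_coords(16, FOV)
        with pytest.raises(ValueError):
            simulate_dynamic_dataset(dyn, geom, coords, tmp_path / "d.h5", n_samples=64)
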