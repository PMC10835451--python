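import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from rsomqc import synthetic_rsom as syn
from rsomqc.data_model import MotionGraph, ScanKind, SystemConfig
from rsomqc.snr_gate import compute_snr


class TestMakeBaseMotion:
    def test_all_zero_amplitudes(self):
        spec = syn.MotionModelSpec(pulse_amp=0, breath_amp=0, jump_rate=0,
                                   jump_amp=0, drift_std=0, seed=1)
        g = syn.make_base_motion(spec, duration=1.0, dt=0.01)
        assert np.all(g.displacement == 0.0)

    def test_pure_sinusoid(self):
        spec = syn.MotionModelSpec(pulse_amp=10.0, pulse_freq=1.0, breath_amp=0,
                                   jump_rate=0, jump_amp=0, drift_std=0, seed=1)
        # dt = 1/8 s samples the quarter-period exactly
        g = syn.make_base_motion(spec, duration=2.0, dt=0.125)
        assert len(g) == 16
        assert np.abs(g.displacement).max() == pytest.approx(10.0)
        # exactly two periods: displacement returns to 0 at t = 0, 0.5, 1, ...
        zeros = g.displacement[::4]
        np.testing.assert_allclose(zeros, 0.0, atol=1e-9)
        # two maxima, two minima
        assert np.sum(np.isclose(g.displacement, 10.0)) == 2
        assert np.sum(np.isclose(g.displacement, -10.0)) == 2

    def test_deterministic(self):
        spec = syn.MotionModelSpec(jump_rate=5.0, jump_amp=3.0, drift_std=0.5, seed=7)
        a = syn.make_base_motion(spec, 2.0, 0.002)
        b = syn.make_base_motion(spec, 2.0, 0.002)
        np.testing.assert_array_equal(a.displacement, b.displacement)

    def test_bad_duration(self):
        spec = syn.MotionModelSpec()
        with pytest.raises(syn.SimulationError):
            syn.make_base_motion(spec, duration=0.0, dt=0.01)
        with pytest.raises(syn.SimulationError):
            syn.make_base_motion(spec, duration=0.005, dt=0.01)


class TestNormalizeAndScale:
    def _graph(self):
        rng = np.random.default_rng(5)
        return MotionGraph(rng.normal(2.0, 3.0, 400), dt=0.002)

    def test_normalize_exact(self):
        g = syn.normalize_motion(self._graph(), 5.0)
        assert g.displacement.std() == pytest.approx(5.0, abs=1e-12)

    def test_normalize_roundtrip(self):
        g = self._graph()
        back = syn.normalize_motion(syn.normalize_motion(g, 5.0),
                                    float(g.displacement.std()))
        np.testing.assert_allclose(back.displacement, g.displacement, rtol=1e-9)

    def test_normalize_constant_errors(self):
        with pytest.raises(syn.SimulationError):
            syn.normalize_motion(MotionGraph(np.full(10, 3.0), 0.1), 5.0)

    def test_scale_paper_ladder_extremes(self):
        # base std 5 um scaled by 3 -> 15 um; base max 40 um scaled by 0.1 -> 4 um
        base = syn.normalize_motion(self._graph(), 5.0)
        assert syn.scale_motion(base, 3.0).displacement.std() == pytest.approx(15.0)
        g = self._graph()
        base_max = syn.scale_motion(g, 40.0 / np.abs(g.displacement).max())
        scaled = syn.scale_motion(base_max, 0.1)
        assert np.abs(scaled.displacement).max() == pytest.approx(4.0)

    def test_scale_zero(self):
        assert np.all(syn.scale_motion(self._graph(), 0.0).displacement == 0.0)

    @settings(max_examples=30, deadline=None)
    @given(w=st.floats(-5, 5, allow_nan=False))
    def test_scale_linearity(self, w):
        g = self._graph()
        s = syn.scale_motion(g, w)
        assert s.displacement.std() == pytest.approx(abs(w) * g.displacement.std())
        assert np.abs(s.displacement).max() == pytest.approx(
            abs(w) * np.abs(g.displacement).max())


class TestSimulateScan:
    def _cfg(self, **kw):
        return SystemConfig(n_fast=kw.pop("n_fast", 4), n_slow=kw.pop("n_slow", 3), **kw)

    def test_surface_peak_at_expected_sample(self):
        # absorber at 150 um with dz = 1.5 um -> envelope peak at sample 100
        phantom = syn.PhantomSpec(surface_mean_depth=150.0, surface_amplitude=1.0)
        scan = syn.simulate_scan(phantom, self._cfg(), noise_std=0.0, n_samples=256)
        env = np.abs(hilbert(scan.amplitudes[0, 0].astype(float)))
        assert int(np.argmax(env)) == 100

    def test_constant_motion_shifts_peak(self):
        phantom = syn.PhantomSpec(surface_mean_depth=150.0, surface_amplitude=1.0)
        cfg = self._cfg()
        motion = MotionGraph(np.full(cfg.n_alines + 1, 15.0), dt=1.0 / cfg.pulse_rate)
        scan = syn.simulate_scan(phantom, cfg, motion=motion, noise_std=0.0,
                                 n_samples=256)
        env = np.abs(hilbert(scan.amplitudes[0, 0].astype(float)))
        assert int(np.argmax(env)) == 110

    def test_no_absorbers_no_noise_zero_cube(self):
        phantom = syn.PhantomSpec(surface_mean_depth=150.0, surface_amplitude=0.0)
        scan = syn.simulate_scan(phantom, self._cfg(), noise_std=0.0, n_samples=128)
        assert np.all(scan.amplitudes == 0.0)

    def test_absorber_outside_window_errors(self):
        phantom = syn.PhantomSpec(surface_mean_depth=500.0, surface_amplitude=1.0)
        with pytest.raises(syn.SimulationError):
            syn.simulate_scan(phantom, self._cfg(), n_samples=128)  # window 190 um

    def test_deterministic(self):
        phantom = syn.standard_phantom()
        cfg = syn.standard_config(n_fast=8, n_slow=4)
        a = syn.simulate_scan(phantom, cfg, noise_std=0.05, seed=9, n_samples=512)
        b = syn.simulate_scan(phantom, cfg, noise_std=0.05, seed=9, n_samples=512)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_forward_model_fidelity_with_motion(self, make_motion):
        """Envelope-peak depth tracks surface + motion within one sample."""
        cfg = syn.standard_config(n_fast=16, n_slow=4)
        phantom = syn.PhantomSpec(surface_mean_depth=150.0, surface_amplitude=1.0)
        motion = make_motion(cfg, 6.0, seed=4)
        scan = syn.simulate_scan(phantom, cfg, motion=motion, noise_std=0.0,
                                 n_samples=256)
        moff = motion.resampled(cfg.aline_times()).displacement.reshape(
            cfg.n_slow, cfg.n_fast).T
        dz = cfg.dz
        for i in range(cfg.n_fast):
            for j in range(cfg.n_slow):
                env = np.abs(hilbert(scan.amplitudes[i, j].astype(float)))
                peak_depth = np.argmax(env) * dz
                assert abs(peak_depth - (150.0 + moff[i, j])) <= dz


class TestSutureScan:
    def test_kind_and_shape(self, std_config):
        scan = syn.make_suture_scan(std_config, suture_depth=240.0, noise_std=0.0)
        assert scan.kind is ScanKind.SUTURE
        assert scan.amplitudes.shape[1] == 1

    def test_focus_maximizes_amplitude(self, std_config):
        at_focus = syn.make_suture_scan(std_config, std_config.focal_depth)
        off_focus = syn.make_suture_scan(std_config, std_config.focal_depth + 100.0)
        assert np.abs(at_focus.amplitudes).max() > np.abs(off_focus.amplitudes).max()

    def test_snr_close_to_closed_form(self, std_config):
        amp, sigma = 1.0, 0.01  # 40 dB
        scan = syn.make_suture_scan(std_config, std_config.focal_depth,
                                    amplitude=amp, noise_std=sigma, seed=3)
        m = compute_snr(scan)
        assert m.snr_db == pytest.approx(20.0 * np.log10(amp / sigma), abs=0.5)

    def test_duration_metadata(self):
        cfg = SystemConfig(n_fast=266, n_slow=1, pulse_rate=500.0)
        scan = syn.make_suture_scan(cfg, 300.0)
        assert scan.meta["duration_s"] == pytest.approx(266 / 500.0)

    def test_depth_outside_window(self, std_config):
        with pytest.raises(syn.SimulationError):
            syn.make_suture_scan(std_config, suture_depth=1e5)


class TestPointScan:
    def test_kind(self, std_config):
        cfg = syn.standard_config(n_fast=1, n_slow=32)
        scan = syn.make_point_scan(cfg, depth=300.0, motion=None)
        assert scan.kind is ScanKind.POINT
        assert scan.amplitudes.shape[0] == 1


class TestMakeCohort:
    def test_zero_targets(self, std_phantom):
        cfg = syn.standard_config(n_fast=8, n_slow=4)
        cohort = syn.make_cohort(2, [(0.0, 0.0), (0.0, 0.0)], cfg, std_phantom, seed=1)
        for _, g in cohort:
            assert np.all(g.displacement == 0.0)

    def test_targets_hit_within_5pct(self, std_phantom):
        cfg = syn.standard_config(n_fast=16, n_slow=8)
        targets = [(7.0, 75.0), (3.0, 10.0)]
        cohort = syn.make_cohort(2, targets, cfg, std_phantom, seed=2)
        for (scan, g), (t_std, t_max) in zip(cohort, targets):
            dev = g.displacement - g.displacement.mean()
            assert dev.std() == pytest.approx(t_std, rel=0.05)
            assert np.abs(dev).max() == pytest.approx(t_max, rel=0.05)

    def test_deterministic(self, std_phantom):
        cfg = syn.standard_config(n_fast=8, n_slow=4)
        a = syn.make_cohort(1, [(2.0, 6.0)], cfg, std_phantom, seed=5)
        b = syn.make_cohort(1, [(2.0, 6.0)], cfg, std_phantom, seed=5)
        np.testing.assert_array_equal(a[0][0].amplitudes, b[0][0].amplitudes)
        np.testing.assert_array_equal(a[0][1].displacement, b[0][1].displacement)

    def test_infeasible_target(self, std_phantom):
        cfg = syn.standard_config(n_fast=8, n_slow=4)
        with pytest.raises(syn.SimulationError):
            syn.make_cohort(1, [(10.0, 5.0)], cfg, std_phantom)

    def test_length_mismatch(self, std_phantom):
        cfg = syn.standard_config(n_fast=8, n_slow=4)
        with pytest.raises(syn.SimulationError):
            syn.make_cohort(2, [(1.0, 2.0)], cfg, std_phantom)


class TestCalibrationBaseMotion:
    def test_hits_paper_base_statistics(self):
        g = syn.calibration_base_motion(2.05, 0.002, seed=11)
        dev = g.displacement - g.displacement.mean()
        assert dev.std() == pytest.approx(5.0, rel=1e-3)
        assert np.abs(dev).max() == pytest.approx(40.0, rel=1e-3)

    def test_deterministic(self):
        a = syn.calibration_base_motion(2.05, 0.002, seed=3)
        b = syn.calibration_base_motion(2.05, 0.002, seed=3)
        np.testing.assert_array_equal(a.displacement, b.displacement)
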