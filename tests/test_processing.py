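"""Time-domain processing chain: phase, baseline, window, FFT, peaks."""

import numpy as np
import pytest

from fenoscore.hyscore_sim import TimeDomainTrace2D
from fenoscore.processing import (apodize_blackman, fft2d_spectrum,
                                  load_trace, phase_trace, pick_peaks, process,
                                  save_spectrum, save_trace, subtract_baseline)


def _trace(values, t_start=48.0, t_step=24.0, tau=120.0):
    return TimeDomainTrace2D(values=np.asarray(values, complex),
                             t_start_ns=t_start, t_step_ns=t_step, tau_ns=tau,
                             field_mT=175.0, mw_freq_GHz=9.78)


def _cosine_trace(nu_MHz=5.0, n=128, t_start=0.0, t_step=24.0):
    t = (t_start + t_step * np.arange(n)) * 1e-3  # us
    c = np.cos(2 * np.pi * nu_MHz * t)
    return _trace(np.outer(c, c), t_start=t_start, t_step=t_step, tau=0.0)


class TestPhase:
    def test_real_trace_unchanged(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(16, 16)).astype(complex)
        out = phase_trace(_trace(v))
        np.testing.assert_allclose(out.values.imag, 0.0, atol=1e-12)
        assert abs(np.sum(out.values.real ** 2)
                   - np.sum(v.real ** 2)) < 1e-9

    def test_rotated_real_trace_recovered(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(8, 8))
        rotated = v * np.exp(1j * np.pi / 4)
        out = phase_trace(_trace(rotated))
        assert np.sum(out.values.imag ** 2) < 1e-24

    def test_global_minimum_vs_phase_scan(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        out = phase_trace(_trace(v))
        got = np.sum(out.values.imag ** 2)
        # brute-force scan over the phase circle
        best = min(np.sum((v * np.exp(-1j * ph)).imag ** 2)
                   for ph in np.linspace(0, np.pi, 3601))
        assert got <= best + 1e-9

    def test_all_zero_passthrough_warns(self):
        with pytest.warns(UserWarning):
            out = phase_trace(_trace(np.zeros((4, 4))))
        assert not out.values.any()


class TestBaseline:
    def test_quadratic_surface_annihilated(self):
        x = np.arange(32, dtype=float)
        surface = np.add.outer(1 + 2 * x + 3 * x ** 2, 4 - x + 0.5 * x ** 2)
        out = subtract_baseline(_trace(surface), degree=2)
        assert np.abs(out.values).max() < 1e-6

    def test_cosine_survives_quadratic_drift(self):
        n = 128
        x = np.arange(n, dtype=float)
        cos = np.cos(2 * np.pi * 8.0 * x / n)
        modulation = np.outer(cos, cos)
        drift = np.add.outer(0.01 * x ** 2 - x, 0.5 * x + 0.003 * x ** 2)
        out = subtract_baseline(_trace(modulation + drift), degree=2)
        amp_in = np.abs(np.fft.fft2(modulation))[8, 8]
        amp_out = np.abs(np.fft.fft2(out.values))[8, 8]
        assert amp_out == pytest.approx(amp_in, rel=0.01)

    def test_degree_zero_removes_means(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(16, 16))
        out = subtract_baseline(_trace(v), degree=0)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)

    def test_too_short_dimension(self):
        with pytest.raises(ValueError):
            subtract_baseline(_trace(np.ones((3, 3))), degree=2)


class TestBlackman:
    def test_corner_elements_vanish(self):
        out = apodize_blackman(_trace(np.ones((64, 64))))
        assert abs(out.values[0, 0]) < 1e-12
        assert abs(out.values[-1, -1]) < 1e-12

    def test_centre_of_odd_window_is_unity(self):
        out = apodize_blackman(_trace(np.ones((65, 65))))
        assert out.values[32, 32].real == pytest.approx(1.0, abs=1e-12)

    def test_separable_outer_product(self):
        from scipy.signal.windows import blackman
        out = apodize_blackman(_trace(np.ones((32, 48))))
        w1, w2 = blackman(32, sym=True), blackman(48, sym=True)
        np.testing.assert_allclose(out.values.real, np.outer(w1, w2), atol=1e-12)

    def test_exact_variant_nonzero_endpoints(self):
        out = apodize_blackman(_trace(np.ones((64, 64))), variant="exact")
        assert abs(out.values[0, 0]) > 1e-8


class TestFFT:
    def test_pure_cosine_lands_within_one_bin(self):
        tr = _cosine_trace(nu_MHz=5.0)
        spec = fft2d_spectrum(tr, 1024)
        mag, nu1, nu2 = spec.positive_quadrant()
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        assert abs(nu1[i] - 5.0) <= spec.bin_width
        assert abs(nu2[j] - 5.0) <= spec.bin_width

    def test_all_zero_input(self):
        spec = fft2d_spectrum(_trace(np.zeros((16, 16))), 64)
        assert not spec.magnitude.any()

    def test_axis_extent_is_nyquist(self):
        spec = fft2d_spectrum(_cosine_trace(), 1024)
        nyquist = 1e3 / (2 * 24.0)
        assert spec.nu2_axis[-1] == pytest.approx(nyquist - spec.bin_width)
        assert spec.nu1_axis[0] == pytest.approx(-nyquist)
        assert spec.bin_width == pytest.approx(1e3 / (1024 * 24.0))

    def test_insufficient_zero_fill(self):
        with pytest.raises(ValueError):
            fft2d_spectrum(_cosine_trace(n=128), 64)

    def test_zero_fill_preserves_energy(self):
        tr = _cosine_trace(n=64)
        for zf in (64, 256, 1024):
            F = np.fft.fft2(np.pad(tr.values, ((0, zf - 64), (0, zf - 64))))
            energy_time = np.sum(np.abs(tr.values) ** 2)
            energy_freq = np.sum(np.abs(F) ** 2) / zf ** 2
            assert energy_freq == pytest.approx(energy_time, rel=1e-9)


class TestFullChain:
    def test_deterministic(self, zfs, single_coupling):
        import fenoscore as f
        from fenoscore.spinham import OrientationWeight
        from conftest import TEST_ORIENTATION
        cfg = f.SimulationConfig(n_points=64)
        ow = [OrientationWeight(direction=TEST_ORIENTATION, weight=1.0)]
        tr = f.simulate_time_domain([single_coupling], zfs, cfg, orientations=ow)
        s1 = process(tr)
        s2 = process(tr)
        np.testing.assert_array_equal(s1.magnitude, s2.magnitude)

    def test_stage_order_matters(self):
        # baseline-then-window differs from window-then-baseline on a
        # drifting trace: guards against silent reordering of the chain
        n = 64
        x = np.arange(n, dtype=float)
        drift = np.add.outer(x ** 2 * 0.01, x * 0.3)
        cos = np.outer(np.cos(2 * np.pi * 6 * x / n), np.cos(2 * np.pi * 6 * x / n))
        tr = _trace(cos + drift)
        a = apodize_blackman(subtract_baseline(tr))
        b = subtract_baseline(apodize_blackman(tr))
        assert np.abs(a.values - b.values).max() > 1e-3

    def test_decay_only_energy_near_zero_frequency(self):
        t = 24.0 * np.arange(64) * 1e-3
        env = np.exp(-t / 0.4)
        tr = _trace(np.outer(env, env), t_start=0.0)
        spec = process(tr)
        mag, nu1, nu2 = spec.positive_quadrant()
        total = mag.sum()
        low = mag[(nu1 >= 0) & (nu1 < 2.0)][:, nu2 < 2.0].sum()
        assert low > 0.5 * total

    def test_spectrum_magnitude_nonnegative_and_unsymmetrised(self, zfs,
                                                              single_coupling):
        import fenoscore as f
        from fenoscore.spinham import OrientationWeight
        from conftest import TEST_ORIENTATION
        cfg = f.SimulationConfig(n_points=64)
        ow = [OrientationWeight(direction=TEST_ORIENTATION, weight=1.0)]
        tr = f.simulate_time_domain([single_coupling], zfs, cfg, noise_sd=0.05,
                                    seed=3, orientations=ow)
        spec = process(tr)
        assert (spec.magnitude >= 0).all()
        mag, nu1, nu2 = spec.positive_quadrant()
        sub = mag[:len(nu2), :]
        assert np.abs(sub - sub.T).max() > 0  # noise is not symmetrised away


class TestPeakPicking:
    def test_single_synthetic_peak_mirror_pair(self):
        tr = _cosine_trace(nu_MHz=7.0)
        spec = fft2d_spectrum(tr, 1024)
        peaks = pick_peaks(spec, 0.5)
        assert len(peaks) >= 1
        top = peaks[0]
        assert top.nu1 == pytest.approx(7.0, abs=2 * spec.bin_width)
        assert top.nu2 == pytest.approx(7.0, abs=2 * spec.bin_width)

    def test_two_separated_peaks_ordered_by_amplitude(self):
        t = 24.0 * np.arange(128) * 1e-3
        v = (np.outer(np.cos(2 * np.pi * 4 * t), np.cos(2 * np.pi * 9 * t))
             + 0.4 * np.outer(np.cos(2 * np.pi * 13 * t), np.cos(2 * np.pi * 17 * t)))
        spec = fft2d_spectrum(_trace(v, t_start=0.0, tau=0.0), 1024)
        peaks = pick_peaks(spec, 0.1)
        assert peaks[0].amplitude >= peaks[-1].amplitude
        found = {(round(p.nu1), round(p.nu2)) for p in peaks[:8]}
        assert {(4, 9), (13, 17)} <= found

    def test_centroids_within_half_bin(self):
        # exact on-bin injected frequency must be recovered sub-bin
        nu = 1e3 / (1024 * 24.0) * 123  # exactly bin 123
        tr = _cosine_trace(nu_MHz=nu)
        spec = fft2d_spectrum(tr, 1024)
        top = pick_peaks(spec, 0.5)[0]
        assert abs(top.nu1 - nu) < 0.5 * spec.bin_width
        assert abs(top.nu2 - nu) < 0.5 * spec.bin_width

    def test_threshold_domain(self):
        spec = fft2d_spectrum(_cosine_trace(), 1024)
        with pytest.raises(ValueError):
            pick_peaks(spec, 1.5)


class TestHdf5Roundtrip:
    def test_trace_and_spectrum_io(self, tmp_path, zfs):
        import fenoscore as f
        cfg = f.SimulationConfig(n_points=16)
        tr = f.simulate_time_domain([], zfs, cfg, decay_ns=400.0)
        p = tmp_path / "trace.h5"
        save_trace(tr, p)
        back = load_trace(p)
        np.testing.assert_array_equal(back.values, tr.values)
        assert back.tau_ns == tr.tau_ns and back.field_mT == tr.field_mT
        spec = process(back)
        save_spectrum(spec, tmp_path / "spec.h5")
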