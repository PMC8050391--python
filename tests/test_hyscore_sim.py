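"""Nuclear frequencies, modulation depths and four-pulse echo simulation."""

import math

import numpy as np
import pytest

import fenoscore as f
from fenoscore.hyperfine import HyperfineCoupling, NucleusSpec
from fenoscore.hyscore_sim import (SimulationConfig, UnsupportedIsotopeError,
                                   _effective_field_vectors,
                                   _nucleus_echo_surface, footprint_grid,
                                   modulation_depth, nuclear_frequencies,
                                   nuclear_frequencies_fullspin, simulate_peaks,
                                   simulate_time_domain)
from fenoscore.spinham import OrientationWeight, larmor_frequency
from fenoscore.structure import AtomRecord
from fenoscore.synth import ToySiteSpec, make_toy_site

from conftest import TEST_ORIENTATION


def _coupling(T_total=2.0, theta_deg=0.0, phi_deg=0.0, isotope="1H"):
    """Coupling object with a prescribed axial tensor orientation."""
    atom = AtomRecord("H", "Hx", "FNO", 1, "A", np.array([0.0, 0, 3.0]))
    spec = NucleusSpec(isotope=isotope, atom=atom, r_Fe=3.0, r_N=3.5, r_O=4.0)
    th = math.radians(theta_deg)
    return HyperfineCoupling(
        nucleus=spec, T_Fe=T_total / 1.4, T_N=0.0, T_O=0.0, T_total=T_total,
        theta_deg=theta_deg, phi_deg=phi_deg,
        euler_zyz=(math.radians(phi_deg), th, 0.0))


def _twospin_oracle(c, orientation, B, geff, g_intrinsic):
    """Dense 4x4 diagonalization of the effective 2-spin problem.

    Written independently of the implementation path: builds the full
    electron-Zeeman + hyperfine + nuclear-Zeeman matrix with a large
    electron frequency and reads the nuclear splittings off the spectrum.
    """
    n = np.asarray(orientation, float)
    n = n / np.linalg.norm(n)
    ge = np.asarray(geff.as_array())
    gi = np.asarray(g_intrinsic)
    gn = math.sqrt(float(np.sum((ge * n) ** 2)))
    A = c.tensor_molecular()
    a = (ge ** 2 / gi * n) @ A / gn
    nuL = larmor_frequency(c.nucleus.isotope, B)
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]])
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    sv = (sx, sy, sz)
    nu_e = 1e6  # MHz; electron splitting >> everything else
    H = nu_e * np.kron(sz, np.eye(2))
    for k in range(3):
        H += a[k] * np.kron(sz, sv[k])
        H += -nuL * n[k] * np.kron(np.eye(2), sv[k])
    ev = np.linalg.eigvalsh(H)
    nu_beta = float(ev[1] - ev[0])   # lower electron manifold
    nu_alpha = float(ev[3] - ev[2])
    return nu_alpha, nu_beta


def _overlap_depth_oracle(c, orientation, B, geff, g_intrinsic):
    """k from eigenvector overlaps: 4 |M00|^2 |M01|^2."""
    w_a, w_b = _effective_field_vectors(c, orientation, B, geff, g_intrinsic)
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]])
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    Ha = w_a[0] * sx + w_a[1] * sy + w_a[2] * sz
    Hb = w_b[0] * sx + w_b[1] * sy + w_b[2] * sz
    _, Va = np.linalg.eigh(Ha)
    _, Vb = np.linalg.eigh(Hb)
    M = Va.conj().T @ Vb
    return 4.0 * abs(M[0, 0]) ** 2 * abs(M[0, 1]) ** 2


class TestNuclearFrequencies:
    def test_uncoupled_limit_is_larmor(self, zfs, geff):
        c = _coupling(T_total=0.0)
        na, nb = nuclear_frequencies(c, [0, 0, 1.0], 175.0, geff, zfs.g_intrinsic)
        nuL = larmor_frequency("1H", 175.0)
        assert na == pytest.approx(nuL, rel=1e-9)
        assert nb == pytest.approx(nuL, rel=1e-9)

    def test_matches_twospin_diagonalization_oracle(self, zfs, geff):
        c = _coupling(T_total=2.0, theta_deg=0.0)
        for n in ([0, 0, 1.0], [1.0, 0, 0], TEST_ORIENTATION):
            got = nuclear_frequencies(c, n, 175.0, geff, zfs.g_intrinsic)
            want = _twospin_oracle(c, n, 175.0, geff, zfs.g_intrinsic)
            np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_weak_coupling_sum_rule(self, zfs, geff):
        c = _coupling(T_total=0.5, theta_deg=30.0)
        n = TEST_ORIENTATION
        na, nb = nuclear_frequencies(c, n, 175.0, geff, zfs.g_intrinsic)
        # the sum rule holds against the Larmor frequency of the
        # g_eff-projected effective field seen by the nucleus
        w_a, w_b = _effective_field_vectors(c, n, 175.0, geff, zfs.g_intrinsic)
        nuL_vec = np.linalg.norm(0.5 * (w_a + w_b))
        assert na + nb == pytest.approx(2 * nuL_vec, rel=0.02)

    def test_nonspinhalf_rejected(self, zfs, geff):
        c = _coupling(isotope="14N")
        with pytest.raises(UnsupportedIsotopeError):
            nuclear_frequencies(c, [0, 0, 1.0], 175.0, geff, zfs.g_intrinsic)


class TestFullSpinEquivalence:
    def test_effective_spin_matches_full_diagonalization(self, zfs, geff,
                                                         eight_couplings):
        rng = np.random.default_rng(2024)
        dirs = rng.normal(size=(12, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        c = eight_couplings[3]
        for n in dirs:
            eff = sorted(nuclear_frequencies(c, n, 175.0, geff, zfs.g_intrinsic))
            full = sorted(nuclear_frequencies_fullspin(c, n, 175.0, zfs))
            for e, fu in zip(eff, full):
                assert e == pytest.approx(fu, rel=0.02)


class TestModulationDepth:
    def test_zero_along_tensor_axis_when_field_parallel(self, zfs, geff):
        # orientation along the tensor unique axis of an axial tensor and
        # along a g principal axis: no pseudo-secular mixing
        c = _coupling(T_total=2.0, theta_deg=0.0)
        k = modulation_depth(c, [0, 0, 1.0], 175.0, geff, zfs.g_intrinsic)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_limit_zero(self, zfs, geff):
        c = _coupling(T_total=0.0)
        k = modulation_depth(c, TEST_ORIENTATION, 175.0, geff, zfs.g_intrinsic)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_matches_eigenvector_overlap_oracle(self, zfs, geff):
        for th in (30.0, 45.0, 70.0):
            c = _coupling(T_total=2.0, theta_deg=th)
            for n in ([0, 0, 1.0], TEST_ORIENTATION):
                got = modulation_depth(c, n, 175.0, geff, zfs.g_intrinsic)
                want = _overlap_depth_oracle(c, n, 175.0, geff, zfs.g_intrinsic)
                assert got == pytest.approx(want, abs=1e-9)


class TestSimulatePeaks:
    def test_mirror_symmetry(self, zfs, eight_couplings):
        cfg = SimulationConfig(n_orientations=100)
        peaks = simulate_peaks(eight_couplings[:2], zfs, cfg)
        seen = {(round(p.nu1, 9), round(p.nu2, 9), round(p.amplitude, 12))
                for p in peaks}
        for p in peaks:
            assert (round(p.nu2, 9), round(p.nu1, 9),
                    round(p.amplitude, 12)) in seen

    def test_all_proton_peaks_in_positive_quadrant(self, zfs, eight_couplings):
        for field in (173.0, 200.0):
            cfg = SimulationConfig(field_mT=field, n_orientations=100)
            peaks = simulate_peaks(eight_couplings, zfs, cfg)
            assert peaks
            assert all(p.quadrant == "(+,+)" for p in peaks)

    def test_superposition_of_single_proton_runs(self, zfs, eight_couplings):
        cfg = SimulationConfig(n_orientations=100)
        combined = simulate_peaks(eight_couplings, zfs, cfg)
        singles = []
        for c in eight_couplings:
            singles.extend(simulate_peaks([c], zfs, cfg))
        key = lambda p: (round(p.nu1, 9), round(p.nu2, 9), p.nucleus_id)
        assert {key(p) for p in combined} == {key(p) for p in singles}

    def test_proton_removal_removes_exactly_its_footprint(self, zfs,
                                                          eight_couplings):
        cfg = SimulationConfig(n_orientations=100)
        key = lambda p: (round(p.nu1, 9), round(p.nu2, 9), p.nucleus_id)
        full = {key(p) for p in simulate_peaks(eight_couplings, zfs, cfg)}
        reduced = {key(p) for p in simulate_peaks(eight_couplings[1:], zfs, cfg)}
        removed = {k for k in full - reduced}
        assert removed
        assert all(k[2] == eight_couplings[0].nucleus.atom.name for k in removed)
        assert reduced <= full

    def test_empty_couplings_rejected(self, zfs):
        with pytest.raises(ValueError):
            simulate_peaks([], zfs, SimulationConfig())

    def test_footprint_grid_quadrant(self, zfs, eight_couplings):
        cfg = SimulationConfig(n_orientations=100)
        peaks = simulate_peaks(eight_couplings, zfs, cfg)
        grid, axis = footprint_grid(peaks, cfg)
        assert grid.shape == (cfg.zero_fill // 2, cfg.zero_fill // 2)
        assert grid.max() > 0
        assert axis[0] == 0.0


class TestEchoSurface:
    def test_matches_mims_three_pulse_structure(self):
        """Unmodulated (collinear-field) nucleus gives a flat surface."""
        t = np.linspace(0.048, 3.096, 60)
        surf = _nucleus_echo_surface(np.array([0, 0, -7.0]),
                                     np.array([0, 0, -8.0]), t, t, 0.12)
        # both manifold fields along z: k = 0, no modulation
        assert np.ptp(np.abs(surf)) < 1e-9

    def test_modulated_surface_contains_cross_frequency(self, zfs, geff,
                                                        single_coupling):
        n = TEST_ORIENTATION
        w_a, w_b = _effective_field_vectors(single_coupling, n, 175.0, geff,
                                            zfs.g_intrinsic)
        na, nb = np.linalg.norm(w_a), np.linalg.norm(w_b)
        t = 0.048 + 0.024 * np.arange(128)
        surf = _nucleus_echo_surface(w_a, w_b, t, t, 0.12)
        surf = surf / surf[0, 0]
        F = np.abs(np.fft.fft2(surf - surf.mean(), s=(1024, 1024)))
        freqs = np.fft.fftfreq(1024, d=0.024)
        ia = int(round(na / (freqs[1] - freqs[0])))
        ib = int(round(nb / (freqs[1] - freqs[0])))
        # cross peak (na, nb) prominent relative to background median
        assert F[ia - 1:ia + 2, ib - 1:ib + 2].max() > 50 * np.median(F)


class TestTimeDomain:
    def test_zero_couplings_constant(self, zfs):
        cfg = SimulationConfig(n_points=32)
        tr = simulate_time_domain([], zfs, cfg)
        assert np.ptp(np.abs(tr.values)) == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism(self, zfs, single_coupling):
        cfg = SimulationConfig(n_points=32, n_orientations=100)
        ow = [OrientationWeight(direction=TEST_ORIENTATION, weight=1.0)]
        t1 = simulate_time_domain([single_coupling], zfs, cfg, noise_sd=0.05,
                                  seed=7, orientations=ow)
        t2 = simulate_time_domain([single_coupling], zfs, cfg, noise_sd=0.05,
                                  seed=7, orientations=ow)
        np.testing.assert_array_equal(t1.values, t2.values)
        t3 = simulate_time_domain([single_coupling], zfs, cfg, noise_sd=0.05,
                                  seed=8, orientations=ow)
        assert not np.array_equal(t1.values, t3.values)

    def test_negative_parameters_rejected(self, zfs):
        with pytest.raises(ValueError):
            simulate_time_domain([], zfs, SimulationConfig(), decay_ns=-1.0)
        with pytest.raises(ValueError):
            simulate_time_domain([], zfs, SimulationConfig(), noise_sd=0.1,
                                 seed=None)

    def test_decay_envelope_applied(self, zfs):
        cfg = SimulationConfig(n_points=16)
        tr = simulate_time_domain([], zfs, cfg, decay_ns=500.0)
        t = cfg.time_axis_ns()
        expect = np.exp(-t / 500.0)
        np.testing.assert_allclose(np.abs(tr.values[:, 0]),
                                   np.abs(tr.values[0, 0]) * expect / expect[0],
                                   rtol=1e-9)
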