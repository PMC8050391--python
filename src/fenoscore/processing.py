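"""Time-domain to frequency-domain HYSCORE processing.

The chain is fixed, in this order: global phase correction (minimise the
imaginary component), per-row/per-column polynomial baseline removal
(degree 2), diagonal Blackman apodization over the acquired length,
zero-filling of both dimensions (to 1024 points by default), 2D Fourier
transform, and display of |Re(FT)|.  Spectra are never symmetrised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal.windows import blackman

from .hyscore_sim import CrossPeak, TimeDomainTrace2D


@dataclass
class HyscoreSpectrum:
    """|Re(FT)| magnitude map with signed nu1 axis and nonnegative nu2 axis."""

    magnitude: np.ndarray
    nu1_axis: np.ndarray   # MHz, includes the negative half for the (-,+) quadrant
    nu2_axis: np.ndarray   # MHz, nonnegative
    field_mT: float = 0.0
    mw_freq_GHz: float = 0.0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")
        if np.any(np.diff(self.nu1_axis) <= 0) or np.any(np.diff(self.nu2_axis) <= 0):
            raise ValueError("frequency axes must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.nu2_axis[1] - self.nu2_axis[0])

    def positive_quadrant(self):
        """(magnitude, nu1, nu2) restricted to nu1 >= 0."""
        sel = self.nu1_axis >= 0
        return self.magnitude[sel], self.nu1_axis[sel], self.nu2_axis


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def phase_trace(t: TimeDomainTrace2D) -> TimeDomainTrace2D:
    """Apply the global phase that minimises total imaginary energy.

    For sum_k (Im z_k e^{-i phi})^2 the minimiser is phi = arg(sum z^2)/2
    (closed form; of the two stationary phases the one maximising the
    real energy is chosen).
    """
    z = t.values
    if not np.any(z):
        warnings.warn("all-zero trace; phase correction is a no-op", stacklevel=2)
        return _clone(t, z.copy(), "phase(identity)")
    w = np.sum(z * z)
    phi = 0.5 * np.angle(w) if np.abs(w) > 0 else 0.0
    out = z * np.exp(-1j * phi)
    if np.sum(out.real ** 2) < np.sum((z * np.exp(-1j * (phi + np.pi / 2))).real ** 2):
        out = z * np.exp(-1j * (phi + np.pi / 2))
    return _clone(t, out, f"phase({phi:.6f} rad)")


def subtract_baseline(t: TimeDomainTrace2D, degree: int = 2) -> TimeDomainTrace2D:
    """Fit-and-subtract a polynomial of ``degree`` along rows, then columns."""
    n1, n2 = t.values.shape
    if min(n1, n2) <= degree + 1:
        raise ValueError(f"dimension too short for degree-{degree} baseline fit")
    out = t.values.copy()
    x2 = np.arange(n2, dtype=float)
    V2 = np.vander(x2, degree + 1)
    out -= (V2 @ np.linalg.lstsq(V2, out.T, rcond=None)[0]).T
    x1 = np.arange(n1, dtype=float)
    V1 = np.vander(x1, degree + 1)
    out -= V1 @ np.linalg.lstsq(V1, out, rcond=None)[0]
    return _clone(t, out, f"baseline(degree={degree})")


def apodize_blackman(t: TimeDomainTrace2D, variant: str = "truncated") -> TimeDomainTrace2D:
    """Multiply by the separable (diagonal) Blackman window w(i) w(j).

    The window spans the acquired length (applied before zero-filling).
    ``variant`` selects the common truncated Blackman (a0 = 0.42, the
    default) or the "exact" coefficient set.
    """
    n1, n2 = t.values.shape
    if variant == "truncated":
        w1, w2 = blackman(n1, sym=True), blackman(n2, sym=True)
    elif variant == "exact":
        w1, w2 = _exact_blackman(n1), _exact_blackman(n2)
    else:
        raise ValueError(f"unknown Blackman variant {variant!r}")
    return _clone(t, t.values * np.outer(w1, w2), f"blackman({variant})")


def _exact_blackman(n: int) -> np.ndarray:
    a0, a1, a2 = 7938 / 18608, 9240 / 18608, 1430 / 18608
    x = np.arange(n) / (n - 1)
    return a0 - a1 * np.cos(2 * np.pi * x) + a2 * np.cos(4 * np.pi * x)


def fft2d_spectrum(t: TimeDomainTrace2D, zero_fill: int = 1024,
                   provenance=None) -> HyscoreSpectrum:
    """Zero-fill, 2D FFT, |Re|, quadrant arrangement.

    nu1 runs over the full signed range (so the (-,+) quadrant is
    visible); nu2 keeps the nonnegative half.  The frequency bin width
    is 1/(zero_fill * t_step).
    """
    n1, n2 = t.values.shape
    if zero_fill < max(n1, n2):
        raise ValueError("zero_fill must be >= the acquired length")
    padded = np.zeros((zero_fill, zero_fill), dtype=complex)
    padded[:n1, :n2] = t.values
    F = np.fft.fft2(padded)
    # first-order phase correction: nuclear coherence in each dimension
    # effectively starts evolving at -(t_start + tau/2) relative to the
    # sampled grid origin; without this ramp the |Re| peak shapes split
    delay_us = (t.t_start_ns + 0.5 * t.tau_ns) * 1e-3
    freqs = np.fft.fftfreq(zero_fill, d=t.t_step_ns * 1e-3)  # MHz
    ramp = np.exp(-2j * np.pi * freqs * delay_us)
    F = F * np.outer(ramp, ramp)
    mag = np.abs(F.real)
    dnu = 1e3 / (zero_fill * t.t_step_ns)  # MHz
    half = zero_fill // 2
    # axis 0 -> signed nu1 via fftshift, axis 1 -> nonnegative nu2 half
    mag = np.fft.fftshift(mag, axes=0)[:, :half]
    nu1 = dnu * (np.arange(zero_fill) - half)
    nu2 = dnu * np.arange(half)
    return HyscoreSpectrum(magnitude=mag, nu1_axis=nu1, nu2_axis=nu2,
                           field_mT=t.field_mT, mw_freq_GHz=t.mw_freq_GHz,
                           provenance=(provenance or []) + [f"fft(zero_fill={zero_fill})"])


def process(t: TimeDomainTrace2D, zero_fill: int = 1024,
            baseline_degree: int = 2,
            blackman_variant: str = "truncated") -> HyscoreSpectrum:
    """Full fixed-order chain: phase -> baseline -> Blackman -> FFT -> |Re|."""
    log: list[str] = []
    s = phase_trace(t)
    log.extend(s.provenance.get("processing", []))
    s = subtract_baseline(s, baseline_degree)
    log.extend(s.provenance.get("processing", [])[-1:])
    s = apodize_blackman(s, blackman_variant)
    log.extend(s.provenance.get("processing", [])[-1:])
    return fft2d_spectrum(s, zero_fill, provenance=log)


def _clone(t: TimeDomainTrace2D, values: np.ndarray, step: str) -> TimeDomainTrace2D:
    prov = dict(t.provenance)
    prov["processing"] = list(prov.get("processing", [])) + [step]
    return TimeDomainTrace2D(values=values, t_start_ns=t.t_start_ns,
                             t_step_ns=t.t_step_ns, tau_ns=t.tau_ns,
                             field_mT=t.field_mT, mw_freq_GHz=t.mw_freq_GHz,
                             provenance=prov)


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def pick_peaks(s: HyscoreSpectrum, threshold: float = 0.2,
               quadrant: str = "(+,+)"):
    """Local maxima above ``threshold`` x max, with sub-bin centroid refinement.

    Returns CrossPeak objects sorted by decreasing amplitude; the mirror
    partner (nu2, nu1) of each returned peak is the diagonally reflected
    member of its pair.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    mag, nu1, nu2 = s.positive_quadrant()
    mmax = mag.max()
    if mmax <= 0:
        return []
    peaks = []
    core = mag[1:-1, 1:-1]
    neigh = [mag[i:i + core.shape[0], j:j + core.shape[1]]
             for i in (0, 1, 2) for j in (0, 1, 2) if not (i == 1 and j == 1)]
    is_max = np.all([core >= nb for nb in neigh], axis=0) & (core >= threshold * mmax)
    for i, j in zip(*np.nonzero(is_max)):
        ii, jj = i + 1, j + 1
        # 3x3 centroid refinement
        sub = mag[ii - 1:ii + 2, jj - 1:jj + 2]
        tot = sub.sum()
        di = float((sub.sum(axis=1) @ np.array([-1.0, 0.0, 1.0])) / tot)
        dj = float((sub.sum(axis=0) @ np.array([-1.0, 0.0, 1.0])) / tot)
        peaks.append(CrossPeak(nu1=float(nu1[ii] + di * s.bin_width),
                               nu2=float(nu2[jj] + dj * s.bin_width),
                               amplitude=float(mag[ii, jj])))
    peaks.sort(key=lambda p: -p.amplitude)
    return peaks


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_trace(t: TimeDomainTrace2D, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("time_data", data=t.values)
        d.attrs["tau_ns"] = t.tau_ns
        d.attrs["t_start_ns"] = t.t_start_ns
        d.attrs["t_step_ns"] = t.t_step_ns
        d.attrs["field_mT"] = t.field_mT
        d.attrs["mw_GHz"] = t.mw_freq_GHz


def load_trace(path) -> TimeDomainTrace2D:
    with h5py.File(path, "r") as f:
        d = f["time_data"]
        return TimeDomainTrace2D(
            values=d[...], tau_ns=float(d.attrs["tau_ns"]),
            t_start_ns=float(d.attrs["t_start_ns"]),
            t_step_ns=float(d.attrs["t_step_ns"]),
            field_mT=float(d.attrs["field_mT"]),
            mw_freq_GHz=float(d.attrs["mw_GHz"]))


def save_spectrum(s: HyscoreSpectrum, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=s.magnitude)
        f.create_dataset("nu1_MHz", data=s.nu1_axis)
        f.create_dataset("nu2_MHz", data=s.nu2_axis)
        f.attrs["field_mT"] = s.field_mT
        f.attrs["mw_GHz"] = s.mw_freq_GHz
        f.attrs["provenance"] = "\n".join(s.provenance)
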