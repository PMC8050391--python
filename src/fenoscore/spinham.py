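"""S = 3/2 electron spin model for the {FeNO}7 centre.

Zero-field splitting dominates the X-band Zeeman interaction
(D ~ 10 cm^-1 versus h*nu ~ 0.33 cm^-1), so the EPR-visible transitions
occur within the ground |ms = +-1/2> Kramers doublet.  For a nearly axial
centre the doublet behaves as a fictitious spin-1/2 with effective
g-values near (4, 4, 2); a small rhombicity E/D splits the perpendicular
pair, which is how E/D is read off a CW spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import CONSTANTS, PhysicalConstants

S_ELECTRON = 1.5


class ResonanceSearchError(RuntimeError):
    """No intra-doublet resonance found in the field search window."""


@dataclass
class ZFSParameters:
    """Zero-field splitting D (cm^-1), rhombicity E/D and intrinsic g."""

    D: float = 10.0
    E_over_D: float = 0.008
    g_intrinsic: tuple = (2.0023, 2.0023, 2.01)

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be > 0 (ground +-1/2 doublet regime)")
        if not (0.0 <= self.E_over_D <= 1.0 / 3.0):
            raise ValueError("E/D must lie in [0, 1/3]")
        self.g_intrinsic = tuple(float(g) for g in self.g_intrinsic)

    @property
    def E(self) -> float:
        return self.D * self.E_over_D

    @property
    def doublet_gap(self) -> float:
        """Zero-field gap between the two Kramers doublets, cm^-1."""
        return 2.0 * self.D * math.sqrt(1.0 + 3.0 * self.E_over_D ** 2)


@dataclass
class EffectiveGSet:
    """Ground-doublet effective g-values (x, y, z order) and doublet gap."""

    g_eff: tuple
    doublet_gap: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self.g_eff, dtype=float)


@dataclass
class OrientationWeight:
    direction: np.ndarray
    weight: float


# ---------------------------------------------------------------------------
# spin operators and Hamiltonian
# ---------------------------------------------------------------------------

def spin_matrices(S: float):
    """(Sx, Sy, Sz) in the |S, m> basis, m descending."""
    dim = int(round(2 * S + 1))
    m = S - np.arange(dim)
    Sz = np.diag(m)
    ladder = np.sqrt(S * (S + 1) - m[1:] * (m[1:] + 1))
    Sp = np.zeros((dim, dim), dtype=complex)
    for i, v in enumerate(ladder):
        Sp[i, i + 1] = v
    Sm = Sp.conj().T
    Sx = 0.5 * (Sp + Sm)
    Sy = -0.5j * (Sp - Sm)
    return Sx, Sy, Sz


_SX, _SY, _SZ = spin_matrices(S_ELECTRON)


def zfs_zeeman_hamiltonian(p: ZFSParameters, B_mT: float, direction,
                           constants: PhysicalConstants = CONSTANTS) -> np.ndarray:
    """4x4 Hamiltonian D[Sz^2 - S(S+1)/3] + E(Sx^2 - Sy^2) + Zeeman, cm^-1.

    ``direction`` is the unit field direction in the ZFS principal frame.
    """
    n = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("field direction must be a unit vector")
    H = (p.D * (_SZ @ _SZ - S_ELECTRON * (S_ELECTRON + 1) / 3.0 * np.eye(4))
         + p.E * (_SX @ _SX - _SY @ _SY))
    # Zeeman: beta_e * B * g_i * n_i * S_i / (h c) in cm^-1
    beta_cm = constants.beta_e * (B_mT * 1e-3) / (constants.h * constants.c_cm)
    gx, gy, gz = p.g_intrinsic
    H = H + beta_cm * (gx * n[0] * _SX + gy * n[1] * _SY + gz * n[2] * _SZ)
    return np.asarray((H + H.conj().T) / 2.0)


def doublet_splitting(p: ZFSParameters, B_mT: float, direction,
                      constants: PhysicalConstants = CONSTANTS) -> float:
    """Ground Kramers doublet splitting at field B, cm^-1."""
    ev = np.linalg.eigvalsh(zfs_zeeman_hamiltonian(p, B_mT, direction, constants))
    return float(ev[1] - ev[0])


# ---------------------------------------------------------------------------
# effective g-values
# ---------------------------------------------------------------------------

def effective_g_perturbative(p: ZFSParameters) -> np.ndarray:
    """First-order effective g of the ground doublet: (2g(1+3lam), 2g(1-3lam), g)."""
    gx, gy, gz = p.g_intrinsic
    lam = p.E_over_D
    return np.array([2.0 * gx * (1.0 + 1.5 * lam),
                     2.0 * gy * (1.0 - 1.5 * lam),
                     gz])


def effective_g(p: ZFSParameters, mw_freq_GHz: float = 9.78,
                constants: PhysicalConstants = CONSTANTS,
                B_window_mT=(0.5, 2000.0)) -> EffectiveGSet:
    """Numeric effective g-values of the ground doublet.

    For each principal direction the resonance field of the intra-doublet
    transition at ``mw_freq_GHz`` is located by root finding and converted
    to g_eff = h nu / (beta_e B_res).
    """
    nu_cm = mw_freq_GHz * 1e9 / constants.c_cm
    if p.D < 10 * nu_cm:
        warnings.warn("D is not >> h*nu; effective-spin picture is marginal",
                      stacklevel=2)
    dirs = np.eye(3)
    geff = []
    for i in range(3):
        def f(B):
            return doublet_splitting(p, B, dirs[i], constants) - nu_cm
        lo, hi = B_window_mT
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise ResonanceSearchError(
                f"no resonance along axis {i} in {B_window_mT} mT")
        B_res = brentq(f, lo, hi, xtol=1e-8)
        g = (mw_freq_GHz * 1e9 * constants.h) / (constants.beta_e * B_res * 1e-3)
        geff.append(g)
    return EffectiveGSet(g_eff=tuple(geff), doublet_gap=p.doublet_gap)


def rhombicity_from_geff(g_plus: float, g_minus: float,
                         D: float = 10.0, mw_freq_GHz: float = 9.78,
                         refine: bool = True):
    """Invert the perpendicular effective-g splitting for E/D.

    First-order inversion E/D = (2/3)(g+ - g-)/(g+ + g-); optionally
    refined by solving the numeric effective-g model for the E/D whose
    perpendicular splitting matches the observed one.
    Returns (first_order, refined) — refined is None when refine=False.
    """
    if not (g_plus > g_minus > 0):
        raise ValueError("require g_plus > g_minus > 0")
    first_order = (2.0 / 3.0) * (g_plus - g_minus) / (g_plus + g_minus)
    refined = None
    if refine:
        g_perp = (g_plus + g_minus) / 4.0  # intrinsic perpendicular g estimate
        target = g_plus - g_minus

        def split(ed):
            p = ZFSParameters(D=D, E_over_D=ed, g_intrinsic=(g_perp, g_perp, g_perp))
            gs = sorted(effective_g(p, mw_freq_GHz).as_array()[:2])
            return (gs[1] - gs[0]) - target

        refined = float(brentq(split, 1e-6, 0.2, xtol=1e-7))
    return first_order, refined


# ---------------------------------------------------------------------------
# nuclear Larmor frequencies
# ---------------------------------------------------------------------------

def larmor_frequency(isotope: str, B_mT: float,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Nuclear Larmor frequency nu = g_n beta_n B / h, in MHz."""
    if B_mT <= 0:
        raise ValueError("field must be positive")
    gn = constants.nuclear_g(isotope)
    return gn * constants.beta_n * (B_mT * 1e-3) / constants.h / 1e6


# ---------------------------------------------------------------------------
# orientation selection
# ---------------------------------------------------------------------------

def golden_spiral_grid(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (n x 3)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, 1.0))
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def resonance_field_mT(g_eff: EffectiveGSet, direction,
                       mw_freq_GHz: float = 9.78,
                       constants: PhysicalConstants = CONSTANTS) -> float:
    """Field satisfying h nu = g_eff(n) beta_e B for the given direction."""
    n = np.asarray(direction, dtype=float)
    g = math.sqrt(float(np.sum((g_eff.as_array() * n) ** 2)))
    B_T = (mw_freq_GHz * 1e9 * constants.h) / (g * constants.beta_e)
    return B_T * 1e3


def orientation_selection(p: ZFSParameters, B0_mT: float,
                          mw_freq_GHz: float = 9.78,
                          linewidth_mT: float = 5.0,
                          n_grid: int = 400,
                          constants: PhysicalConstants = CONSTANTS):
    """Orientation weights at a fixed field/frequency position.

    Weight of each grid direction is a Gaussian in (B_res(n) - B0) with
    the given linewidth; weights are normalised to sum to 1.  An empty
    selection (all weights ~ 0) yields uniform weights with a warning.
    """
    if n_grid < 100:
        raise ValueError("orientation grid must have >= 100 points")
    geff = effective_g(p, mw_freq_GHz, constants)
    dirs = golden_spiral_grid(n_grid)
    bres = np.array([resonance_field_mT(geff, d, mw_freq_GHz, constants)
                     for d in dirs])
    if math.isinf(linewidth_mT):
        w = np.ones(len(dirs))
    else:
        w = np.exp(-0.5 * ((bres - B0_mT) / linewidth_mT) ** 2)
    if w.sum() < 1e-12:
        warnings.warn("empty orientation selection; falling back to uniform",
                      stacklevel=2)
        w = np.ones(len(dirs))
    w = w / w.sum()
    return [OrientationWeight(direction=d, weight=float(wi))
            for d, wi in zip(dirs, w)]
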