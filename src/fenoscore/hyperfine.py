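"""Point-dipole hyperfine tensors for protons near an {FeNO}7 centre.

The S = 3/2 iron-nitrosyl ground state arises from antiferromagnetic
coupling of high-spin Fe(III) (S = 5/2) to NO- (S = 1).  A proton near
the centre feels dipolar fields from all three spin carriers; in the
coupled representation the three site couplings combine with spin
projection factors +7/5 (Fe) and -1/5 (each NO atom).  Each proton's
coupling is an axial, traceless tensor (-T, -T, +2T) whose unique axis
points along the Fe-H vector, oriented in a molecular frame whose z axis
is the Fe-NO bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .structure import AtomRecord, GeometryError, SelectionError, Structure

FE_PROJECTION = 7.0 / 5.0
NO_PROJECTION = -1.0 / 5.0
MIN_DISTANCE_A = 0.5


class UnphysicalDistanceError(ValueError):
    """Distance too short for the point-dipole treatment."""


@dataclass
class NucleusSpec:
    """A coupled nucleus and its distances (A) to Fe and the NO atoms."""

    isotope: str
    atom: AtomRecord
    r_Fe: float
    r_N: float
    r_O: float

    def __post_init__(self):
        for label, r in (("Fe", self.r_Fe), ("N", self.r_N), ("O", self.r_O)):
            if r <= MIN_DISTANCE_A:
                raise UnphysicalDistanceError(
                    f"r({label}) = {r:.3f} A <= {MIN_DISTANCE_A} A")


@dataclass
class MagneticFrame:
    """Right-handed orthonormal frame: origin Fe, z along Fe->N(NO).

    x is chosen so the NO oxygen lies in the x-z half-plane at positive x.
    ``degenerate`` flags a collinear Fe-N-O fallback where x is arbitrary.
    """

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    degenerate: bool = False

    def to_frame(self, v: np.ndarray) -> np.ndarray:
        """Express a lab-frame vector in frame coordinates."""
        return np.array([self.x @ v, self.y @ v, self.z @ v])


@dataclass
class HyperfineCoupling:
    """Axial dipolar coupling and orientation for one proton."""

    nucleus: NucleusSpec
    T_Fe: float
    T_N: float
    T_O: float
    T_total: float
    theta_deg: float
    phi_deg: float
    euler_zyz: tuple  # (alpha, beta, gamma) radians; gamma fixed to 0

    @property
    def tensor_principal(self) -> np.ndarray:
        T = self.T_total
        return np.array([-T, -T, 2.0 * T])

    def tensor_molecular(self) -> np.ndarray:
        """3x3 tensor in the molecular (Fe-NO) frame, MHz."""
        R = rotation_zyz(*self.euler_zyz)
        return R @ np.diag(self.tensor_principal) @ R.T

    def as_dict(self) -> dict:
        return {
            "isotope": self.nucleus.isotope,
            "atom": self.nucleus.atom.name,
            "r_Fe_A": self.nucleus.r_Fe,
            "r_N_A": self.nucleus.r_N,
            "r_O_A": self.nucleus.r_O,
            "T_Fe_MHz": self.T_Fe,
            "T_N_MHz": self.T_N,
            "T_O_MHz": self.T_O,
            "T_total_MHz": self.T_total,
            "theta_deg": self.theta_deg,
            "phi_deg": self.phi_deg,
            "euler_zyz_rad": list(self.euler_zyz),
        }


def rotation_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active rotation matrix, z-y'-z'' Euler convention (radians)."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


# ---------------------------------------------------------------------------
# elementary couplings
# ---------------------------------------------------------------------------

def point_dipole_T(r: float, isotope: str = "1H",
                   constants: PhysicalConstants = CONSTANTS) -> float:
    """Point-dipole coupling T = (mu0/4pi) ge gn be bn / (h r^3), in MHz.

    ``r`` is in Angstrom.  For 1H at 1.0 A this evaluates to 79.06 MHz.
    """
    if r <= MIN_DISTANCE_A:
        raise UnphysicalDistanceError(f"r = {r:.3f} A <= {MIN_DISTANCE_A} A")
    gn = constants.nuclear_g(isotope)
    r_m = r * 1e-10
    T_hz = (constants.mu0_over_4pi * constants.g_e * gn
            * constants.beta_e * constants.beta_n) / (constants.h * r_m ** 3)
    return T_hz / 1e6


def spin_projected_T(T_Fe: float, T_N: float, T_O: float) -> float:
    """Combine site couplings with the {FeNO}7 spin projection factors."""
    return FE_PROJECTION * T_Fe + NO_PROJECTION * (T_N + T_O)


# ---------------------------------------------------------------------------
# molecular frame and orientations
# ---------------------------------------------------------------------------

def _find_no_group(site: Structure):
    fes = site.select(lambda a: a.element.upper() == "FE")
    if len(fes) != 1:
        raise SelectionError(f"site must contain exactly one Fe, found {len(fes)}")
    fe = fes[0]
    ns = site.select(lambda a: a.element.upper() == "N")
    os_ = site.select(lambda a: a.element.upper() == "O")
    if not ns or not os_:
        raise SelectionError("site must contain the NO group (one N, one O)")
    # NO nitrogen: the N closest to Fe that has an O within bonding range
    def no_pair(n):
        cand = [o for o in os_ if np.linalg.norm(o.position - n.position) < 1.6]
        return min(cand, key=lambda o: np.linalg.norm(o.position - n.position)) if cand else None
    pairs = [(n, no_pair(n)) for n in ns]
    pairs = [(n, o) for n, o in pairs if o is not None]
    if not pairs:
        raise SelectionError("no N-O bonded pair found in site")
    n, o = min(pairs, key=lambda p: np.linalg.norm(p[0].position - fe.position))
    return fe, n, o


def magnetic_frame(site: Structure) -> MagneticFrame:
    """Frame with origin at Fe and z along the Fe->N(NO) bond.

    The NO oxygen fixes the x axis (positive-x half of the x-z plane);
    this convention is arbitrary but self-consistent — only geometry
    relative to the frame matters downstream.
    """
    fe, n, o = _find_no_group(site)
    z = n.position - fe.position
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise GeometryError("Fe and NO nitrogen coincide")
    z = z / nz
    vo = o.position - fe.position
    x = vo - (vo @ z) * z
    degenerate = False
    if np.linalg.norm(x) < 1e-8:
        # linear Fe-N-O: any x perpendicular to z works; flag it
        degenerate = True
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ z) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        x = seed - (seed @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return MagneticFrame(origin=fe.position.copy(), x=x, y=y, z=z,
                         degenerate=degenerate)


def proton_orientation(coupling_atom: AtomRecord, frame: MagneticFrame):
    """Polar angles of the Fe->H vector in the magnetic frame.

    theta is the deviation from z (the Fe-NO bond); phi is the angle
    between the proton and the x-z plane (arcsin of the y component).
    Returns (theta_deg, phi_deg, euler_zyz) with the z-y'-z'' Euler set
    (azimuth, theta, 0) that carries the axial tensor's unique axis onto
    the Fe->H direction.
    """
    v = frame.to_frame(coupling_atom.position - frame.origin)
    r = np.linalg.norm(v)
    if r < 1e-8:
        raise GeometryError("proton coincides with Fe")
    u = v / r
    theta = math.degrees(math.acos(np.clip(u[2], -1.0, 1.0)))
    phi = math.degrees(math.asin(np.clip(u[1], -1.0, 1.0)))
    azimuth = math.atan2(u[1], u[0]) if (abs(u[0]) > 1e-12 or abs(u[1]) > 1e-12) else 0.0
    return theta, phi, (azimuth, math.radians(theta), 0.0)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_couplings(site: Structure, selection=None, r_jitter: float = 0.0,
                    isotope: str = "1H",
                    constants: PhysicalConstants = CONSTANTS):
    """HyperfineCoupling per selected proton (optionally with +-r jitter).

    ``selection`` is a list of atom names; None selects every hydrogen.
    When ``r_jitter`` > 0 the return value is a dict with keys
    ``"central"``, ``"minus"`` and ``"plus"`` holding coupling lists
    evaluated at r, r - jitter and r + jitter (the crystallographic
    position-precision envelope); otherwise a flat list is returned.
    """
    fe, n_no, o_no = _find_no_group(site)
    frame = magnetic_frame(site)
    hydrogens = site.select(lambda a: a.is_hydrogen)
    if selection is None:
        chosen = hydrogens
    else:
        by_name = {a.name: a for a in site.atoms}
        chosen = []
        for name in selection:
            if name not in by_name:
                raise SelectionError(f"atom {name!r} not found in site")
            a = by_name[name]
            if not a.is_hydrogen:
                raise SelectionError(f"atom {name!r} is not a hydrogen")
            chosen.append(a)

    def one(atom: AtomRecord, dr: float):
        r_fe = float(np.linalg.norm(atom.position - fe.position)) + dr
        r_n = float(np.linalg.norm(atom.position - n_no.position)) + dr
        r_o = float(np.linalg.norm(atom.position - o_no.position)) + dr
        spec = NucleusSpec(isotope=isotope, atom=atom, r_Fe=r_fe, r_N=r_n, r_O=r_o)
        T_fe = point_dipole_T(r_fe, isotope, constants)
        T_n = point_dipole_T(r_n, isotope, constants)
        T_o = point_dipole_T(r_o, isotope, constants)
        theta, phi, euler = proton_orientation(atom, frame)
        return HyperfineCoupling(
            nucleus=spec, T_Fe=T_fe, T_N=T_n, T_O=T_o,
            T_total=spin_projected_T(T_fe, T_n, T_o),
            theta_deg=theta, phi_deg=phi, euler_zyz=euler)

    central = [one(a, 0.0) for a in chosen]
    if r_jitter <= 0:
        return central
    return {
        "central": central,
        "minus": [one(a, -r_jitter) for a in chosen],
        "plus": [one(a, +r_jitter) for a in chosen],
    }
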