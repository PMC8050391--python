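"""Synthetic-data generators for every pipeline stage.

Everything here is generated, deterministic under a fixed seed, and
stamps provenance into its outputs: toy {FeNO}7 sites with protons at
prescribed spherical positions, synthetic four-pulse HYSCORE traces,
synthetic initial-rate kinetics tables, miniature multi-chain PDB
fixtures, and a synthetic stand-in for a deposited multi-chain
dioxygenase crystal structure (for exercising the geometry pipeline
offline).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .hyscore_sim import SimulationConfig, TimeDomainTrace2D, simulate_time_domain
from .kinetics import RateDataset, RateObservation, competitive_rate
from .spinham import ZFSParameters
from .structure import AtomRecord, GeometryError, Structure, write_pdb


@dataclass
class ToySiteSpec:
    """Geometry of a toy iron-nitrosyl site.

    Defaults (Fe-N 1.7 A, N-O 1.15 A, Fe-N-O 150 deg) are typical of
    S = 3/2 {FeNO}7 model chemistry.  ``protons`` lists
    (r_Fe_A, theta_deg, phi_deg) triples in the magnetic frame
    (z along Fe-NO, phi the angle to the x-z plane).
    """

    fe_n_distance: float = 1.7
    n_o_distance: float = 1.15
    fe_n_o_angle: float = 150.0
    protons: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.fe_n_distance <= 0 or self.n_o_distance <= 0:
            raise ValueError("distances must be positive")
        if not (0.0 < self.fe_n_o_angle <= 180.0):
            raise ValueError("Fe-N-O angle must be in (0, 180]")


@dataclass
class NoiseSpec:
    decay_t1_ns: float = 1000.0
    decay_t2_ns: float = 1000.0
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.decay_t1_ns, self.decay_t2_ns, self.gaussian_sd) < 0:
            raise ValueError("noise parameters must be nonnegative")


def _spec_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# toy {FeNO}7 sites
# ---------------------------------------------------------------------------

def make_toy_site(spec: ToySiteSpec) -> Structure:
    """Fe at the origin, NO along +z, protons at requested polar positions.

    The NO oxygen is placed in the +x half of the x-z plane, so the
    magnetic frame recovered downstream is the identity and
    proton orientations round-trip exactly.
    """
    atoms = [AtomRecord("Fe", "FE", "FNO", 1, "A", np.zeros(3))]
    n_pos = np.array([0.0, 0.0, spec.fe_n_distance])
    atoms.append(AtomRecord("N", "N", "FNO", 1, "A", n_pos))
    alpha = math.radians(180.0 - spec.fe_n_o_angle)
    o_pos = n_pos + spec.n_o_distance * np.array(
        [math.sin(alpha), 0.0, math.cos(alpha)])
    atoms.append(AtomRecord("O", "O", "FNO", 1, "A", o_pos))
    for idx, (r, theta_deg, phi_deg) in enumerate(spec.protons, start=1):
        th = math.radians(theta_deg)
        ph = math.radians(phi_deg)
        if abs(math.sin(th)) < 1e-12:
            if abs(phi_deg) > 1e-9:
                raise GeometryError("phi must be 0 for a proton on the z axis")
            u = np.array([0.0, 0.0, math.copysign(1.0, math.cos(th))])
        else:
            if abs(math.sin(ph)) > abs(math.sin(th)) + 1e-12:
                raise GeometryError(
                    f"proton {idx}: |phi| may not exceed theta "
                    "(the y-elevation cannot exceed the polar angle)")
            az = math.asin(np.clip(math.sin(ph) / math.sin(th), -1.0, 1.0))
            u = np.array([math.sin(th) * math.cos(az),
                          math.sin(th) * math.sin(az),
                          math.cos(th)])
        atoms.append(AtomRecord("H", f"H{idx}", "FNO", 1, "A", r * u))
    st = Structure(atoms=atoms, source_id=f"toy-site-{_spec_hash(spec)}")
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if np.linalg.norm(atoms[i].position - atoms[j].position) < 0.5:
                raise GeometryError(
                    f"atoms {atoms[i].name}/{atoms[j].name} overlap (<0.5 A)")
    return st


# ---------------------------------------------------------------------------
# HYSCORE datasets
# ---------------------------------------------------------------------------

def make_hyscore_dataset(couplings, p: ZFSParameters, cfg: SimulationConfig,
                         noise: NoiseSpec) -> TimeDomainTrace2D:
    """Synthetic acquisition: echo modulation x decay + Gaussian noise."""
    decay = 0.5 * (noise.decay_t1_ns + noise.decay_t2_ns)
    trace = simulate_time_domain(couplings, p, cfg, decay_ns=decay,
                                 noise_sd=noise.gaussian_sd,
                                 seed=noise.seed if noise.gaussian_sd > 0 else None)
    trace.provenance.update({
        "generator": "make_hyscore_dataset",
        "noise_spec": _spec_hash(noise),
        "sim_config": _spec_hash(cfg),
    })
    return trace


# ---------------------------------------------------------------------------
# kinetics tables
# ---------------------------------------------------------------------------

DEFAULT_S_GRID = (7.0, 12.0, 20.0, 35.0, 60.0, 100.0, 175.0, 300.0, 600.0, 1000.0)
DEFAULT_I_LEVELS = (0.0, 167.0, 500.0, 1500.0)


def make_kinetics_dataset(truth=(6.55, 6.7, 280.0),
                          S_grid=DEFAULT_S_GRID,
                          I_levels=DEFAULT_I_LEVELS,
                          noise_sd: float = 0.03,
                          seed: int = 0,
                          enzyme_conc: float = 5.0) -> RateDataset:
    """Initial-rate table from the competitive model with multiplicative noise.

    ``truth`` is (Vmax uM/s, KM uM, KI uM); the defaults correspond to a
    kcat of 1.31 1/s at 5.0 uM enzyme with the inhibitor-series design
    (0/167/500/1500 uM) spanning substrate 7-1000 uM.  Rates are drawn
    as v0 x (1 + N(0, noise_sd)), truncated at zero.
    """
    Vmax, KM, KI = truth
    rng = np.random.default_rng(seed)
    obs = []
    for I in I_levels:
        for S in S_grid:
            v = float(competitive_rate(S, I, Vmax, KM, KI))
            if noise_sd > 0:
                v = max(v * (1.0 + rng.normal(0.0, noise_sd)), 0.0)
            obs.append(RateObservation(S=S, I=I, v0=v, enzyme_conc=enzyme_conc))
    return RateDataset(observations=obs)


# ---------------------------------------------------------------------------
# miniature multi-chain PDB fixtures
# ---------------------------------------------------------------------------

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _ca_template(n_res: int = 10) -> np.ndarray:
    """Idealised alpha-helical C-alpha trace (rise 1.5 A, radius 2.3 A)."""
    i = np.arange(n_res)
    ang = math.radians(100.0) * i
    return np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])


def make_mini_pdb(n_chains: int, perturbation_sd: float = 0.0, seed: int = 0,
                  n_res: int = 10):
    """Multi-chain C-alpha fixture: rigid copies + per-atom Gaussian jitter.

    ``perturbation_sd`` is the RMS of each atom's displacement vector
    (per coordinate sd/sqrt(3)), so the expected pairwise RMSD between
    chains is ~ sqrt(2) * sd for small sd.  Returns (Structure, pdb_text).
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    rng = np.random.default_rng(seed)
    template = _ca_template(n_res)
    coord_sd = perturbation_sd / math.sqrt(3.0)
    atoms = []
    for c in range(n_chains):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3) + np.array([40.0 * c, 0.0, 0.0])
        coords = template @ R.T + t
        if coord_sd > 0:
            coords = coords + rng.normal(0.0, coord_sd, size=coords.shape)
        for ri, pos in enumerate(coords, start=1):
            atoms.append(AtomRecord("C", "CA", "ALA", ri, _CHAIN_IDS[c], pos))
    st = Structure(atoms=atoms, source_id=f"mini-pdb-{seed}")
    import tempfile
    from pathlib import Path
    import os
    fd, tmp = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_pdb(st, tmp)
        text = Path(tmp).read_text()
    finally:
        os.unlink(tmp)
    return st, text


# ---------------------------------------------------------------------------
# synthetic stand-in for a deposited multi-chain structure
# ---------------------------------------------------------------------------

SITE_GEOMETRY_DEFAULTS = {
    # reported first-coordination-sphere geometry of the inhibitor complex
    "Fe-O/S": 2.16, "Fe-O(carb)": 2.17, "Fe-Cl": 2.36,
    "Fe-His90": 2.15, "Fe-His92": 2.16, "Fe-His142": 2.16,
    "Fe-O/S-Ca": 92.5, "H90-Fe-Cl": 175.7, "H92-Fe-O/S": 171.1,
    "O(carb)-Fe-O/S": 101.1, "C1-C2-C3": 114.6,
    "Cl...Tyr-OH": 2.7,
}


def _build_site_atoms(chain_id: str, geom: dict) -> list:
    """One active site built to the target distances/angles (chain frame)."""
    d = geom
    fe = np.zeros(3)
    cl = np.array([0.0, 0.0, d["Fe-Cl"]])
    a_h90 = math.radians(d["H90-Fe-Cl"])
    h90 = d["Fe-His90"] * np.array([math.sin(a_h90), 0.0, math.cos(a_h90)])
    o3 = np.array([d["Fe-O/S"], 0.0, 0.0])
    a_h92 = math.radians(d["H92-Fe-O/S"])
    h92 = d["Fe-His92"] * np.array([math.cos(a_h92), math.sin(a_h92), 0.0])
    a_oc = math.radians(d["O(carb)-Fe-O/S"])
    o1 = d["Fe-O(carb)"] * np.array([math.cos(a_oc), -math.sin(a_oc), 0.0])
    h142 = d["Fe-His142"] * _unit(np.array([-math.cos(a_oc), math.sin(a_oc), -0.6]))
    tyr_oh = cl + d["Cl...Tyr-OH"] * _unit(np.array([0.8, 0.5, 0.6]))
    # ligand carbon chain: C3 bonded to the hydroxyl O at the target
    # Fe-O/S-Ca angle; C2/C1 solved to satisfy bond lengths, the
    # C1-C2-C3 angle and the C1-carboxylate bond
    a_ca = math.radians(d["Fe-O/S-Ca"])
    c3 = o3 + 1.43 * np.array([-math.cos(a_ca), 0.0, -math.sin(a_ca)])

    # exact construction: |C1-C3| follows from the C1-C2-C3 angle and the
    # two 1.52 A bonds (law of cosines); C1 then lies on the circle where
    # sphere(O1, 1.31) meets sphere(C3, d13), C2 on the circle where the
    # two 1.52 A bond spheres meet.  The point farthest from the metal is
    # chosen on each circle (deterministic, keeps the chain outside the
    # first coordination sphere).
    ang123 = math.radians(d["C1-C2-C3"])
    d13 = 1.52 * math.sqrt(2.0 * (1.0 - math.cos(ang123)))
    c1 = _farthest_on_circle(o1, 1.31, c3, d13, fe)
    c2 = _farthest_on_circle(c3, 1.52, c1, 1.52, fe)
    o2 = c1 + 1.26 * _unit(c1 - fe)

    mk = lambda el, name, res, num, pos: AtomRecord(el, name, res, num, chain_id, pos)
    return [
        mk("Fe", "FE", "FE", 200, fe),
        mk("Cl", "CL", "CL", 202, cl),
        mk("N", "NE2", "HIS", 90, h90),
        mk("N", "NE2", "HIS", 92, h92),
        mk("N", "NE2", "HIS", 142, h142),
        mk("O", "OH", "TYR", 159, tyr_oh),
        mk("O", "O3", "LIG", 201, o3),
        mk("O", "O1", "LIG", 201, o1),
        mk("O", "O2", "LIG", 201, o2),
        mk("C", "C1", "LIG", 201, c1),
        mk("C", "C2", "LIG", 201, c2),
        mk("C", "C3", "LIG", 201, c3),
    ]


def _unit(v):
    return v / np.linalg.norm(v)


def _farthest_on_circle(ca, ra, cb, rb, away_from):
    """Point on the intersection circle of two spheres farthest from a point.

    Spheres (ca, ra) and (cb, rb) must intersect; 360 deterministic
    samples of the circle are scanned.
    """
    axis = cb - ca
    dist = float(np.linalg.norm(axis))
    if not (abs(ra - rb) < dist < ra + rb):
        raise GeometryError("spheres do not intersect in a circle")
    axis = axis / dist
    # circle centre offset along the axis and radius (standard two-sphere)
    h = (dist ** 2 + ra ** 2 - rb ** 2) / (2.0 * dist)
    rc = math.sqrt(max(ra ** 2 - h ** 2, 0.0))
    centre = ca + h * axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ axis) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = _unit(seed - (seed @ axis) * axis)
    v = np.cross(axis, u)
    ts = np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False)
    pts = centre + rc * (np.outer(np.cos(ts), u) + np.outer(np.sin(ts), v))
    return pts[int(np.argmax(np.linalg.norm(pts - away_from, axis=1)))]


def _angle(a, b, c):
    u, v = a - b, c - b
    return math.acos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                             -1.0, 1.0))


def make_synthetic_assembly(n_chains: int = 12, ca_jitter_sd: float = 0.2,
                            seed: int = 0, n_res: int = 20,
                            geometry: dict | None = None) -> Structure:
    """SYNTHETIC stand-in for a deposited 12-chain dioxygenase structure.

    This is generated data, not deposited coordinates: each chain carries
    an idealised C-alpha trace plus an active site constructed to the
    target first-coordination-sphere geometry (defaults:
    :data:`SITE_GEOMETRY_DEFAULTS`).  The first chain ("A") and the
    reference chain "B" are exact; remaining chains receive per-atom
    C-alpha jitter (RMS displacement ``ca_jitter_sd``) so pairwise RMSDs
    are small but nonzero, emulating the near-uniformity of a real
    asymmetric unit.  Intended for offline validation of the geometry
    pipeline.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    geom = dict(SITE_GEOMETRY_DEFAULTS)
    if geometry:
        geom.update(geometry)
    rng = np.random.default_rng(seed)
    template = _ca_template(n_res) + np.array([15.0, 0.0, 0.0])
    coord_sd = ca_jitter_sd / math.sqrt(3.0)
    atoms = []
    for c in range(n_chains):
        cid = _CHAIN_IDS[c]
        R = Rotation.random(random_state=rng).as_matrix()
        t = np.array([60.0 * c, 0.0, 0.0])
        site = _build_site_atoms(cid, geom)
        jitter = 0.0 if cid in ("A", "B") else coord_sd
        for a in site:
            a.position = a.position @ R.T + t
            atoms.append(a)
        ca = template @ R.T + t
        if jitter > 0:
            ca = ca + rng.normal(0.0, jitter, size=ca.shape)
        for ri, pos in enumerate(ca, start=1):
            atoms.append(AtomRecord("C", "CA", "ALA", ri, cid, pos))
    return Structure(atoms=atoms, source_id=f"synthetic-assembly-{seed}")
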