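"""Coordinate parsing and metal-site geometry.

Reads macromolecular coordinates (PDB/mmCIF via gemmi) or small-molecule
XYZ clusters into a flat list of atom records, and computes the geometric
quantities used to characterise a nonheme iron active site: metal-ligand
distances, coordination angles, active-site contacts and pairwise
C-alpha RMSDs between the chains of an asymmetric unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import gemmi
import numpy as np


class FormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class ElementError(ValueError):
    """Raised for an unrecognised chemical element symbol."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty or ambiguous."""


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident atoms etc.)."""


# Residues treated as protein when deciding what counts as a "protein chain".
_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass
class AtomRecord:
    """One atom: element, label, residue context and Cartesian position (A)."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise GeometryError(f"non-finite or malformed position for atom {self.name}")
        if gemmi.Element(self.element).atomic_number == 0:
            raise ElementError(f"unrecognised element symbol {self.element!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """Ordered atom collection with chain bookkeeping."""

    atoms: list
    source_id: str = ""

    @property
    def chains(self) -> set:
        return {a.chain_id for a in self.atoms}

    def protein_chains(self) -> list:
        """Chain ids containing at least one standard amino-acid residue."""
        out = []
        for cid in sorted(self.chains):
            if any(a.chain_id == cid and a.residue_name in _AMINO3 for a in self.atoms):
                out.append(cid)
        return out

    def select(self, pred: Callable[[AtomRecord], bool]) -> list:
        return [a for a in self.atoms if pred(a)]

    def chain(self, chain_id: str) -> list:
        return [a for a in self.atoms if a.chain_id == chain_id]


@dataclass
class MetalSiteGeometry:
    """Labelled distances/angles around one metal centre (lengths in A)."""

    metal: AtomRecord
    ligand_distances: dict = field(default_factory=dict)
    angles_deg: dict = field(default_factory=dict)
    contacts: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.ligand_distances.items():
            if v <= 0:
                raise GeometryError(f"nonpositive distance for {k}")
        for k, v in self.angles_deg.items():
            if not (0.0 <= v <= 180.0):
                raise GeometryError(f"angle {k} outside [0, 180]")

    def as_dict(self) -> dict:
        return {
            "metal": {
                "element": self.metal.element,
                "chain": self.metal.chain_id,
                "residue_number": self.metal.residue_number,
            },
            "distances_A": dict(self.ligand_distances),
            "angles_deg": dict(self.angles_deg),
            "contacts_A": dict(self.contacts),
        }


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB, mmCIF or XYZ file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by first encountered).  Hydrogens are retained when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".pdb": "pdb", ".ent": "pdb", ".cif": "mmcif", ".mmcif": "mmcif",
               ".xyz": "xyz"}.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix of {path.name}")
    fmt = fmt.lower()
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt in ("pdb", "mmcif"):
        return _parse_gemmi(path, fmt)
    raise FormatError(f"unknown format {fmt!r}")


def _parse_gemmi(path: Path, fmt: str) -> Structure:
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except Exception as exc:  # gemmi raises RuntimeError with a line message
        raise FormatError(f"unreadable {fmt} file {path.name}: {exc}") from exc
    st.setup_entities()
    atoms: list[AtomRecord] = []
    model = st[0] if len(st) else None
    if model is None:
        raise FormatError(f"{path.name}: no coordinate model found")
    for chain in model:
        for res in chain:
            # altloc resolution: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                el = at.element.name
                if el in ("X", ""):
                    raise ElementError(f"{path.name}: unknown element for atom {at.name}")
                atoms.append(AtomRecord(
                    element=el, name=at.name, residue_name=res.name,
                    residue_number=res.seqid.num, chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                ))
    if not atoms:
        raise FormatError(f"{path.name}: file contains no atoms")
    return Structure(atoms=atoms, source_id=path.stem)


def _parse_xyz(path: Path) -> Structure:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path.name}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise FormatError(f"{path.name}: line 1 is not an atom count") from None
    body = lines[2:2 + n]
    if len(body) < n:
        raise FormatError(f"{path.name}: expected {n} atom rows, found {len(body)}")
    atoms = []
    for i, ln in enumerate(body, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path.name}: malformed XYZ row at line {i}")
        el = parts[0].capitalize()
        if gemmi.Element(el).atomic_number == 0:
            raise ElementError(f"{path.name}: unknown element {parts[0]!r} at line {i}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise FormatError(f"{path.name}: non-numeric coordinate at line {i}") from None
        atoms.append(AtomRecord(element=el, name=f"{el}{i - 2}", residue_name="XYZ",
                                residue_number=1, chain_id="A", position=np.array(xyz)))
    return Structure(atoms=atoms, source_id=path.stem)


def write_pdb(s: Structure, path) -> None:
    """Serialise to minimal PDB (ATOM/HETATM records, 3-decimal coordinates)."""
    lines = []
    serial = 0
    for a in s.atoms:
        serial += 1
        record = "ATOM  " if a.residue_name in _AMINO3 else "HETATM"
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"{record}{serial:5d} {name[:4]}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# elementary measurements
# ---------------------------------------------------------------------------

def atom_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance between two atoms, in Angstrom."""
    return float(np.linalg.norm(a.position - b.position))


def bond_angle(a: AtomRecord, vertex: AtomRecord, c: AtomRecord) -> float:
    """Angle a-vertex-c in degrees, in [0, 180]."""
    u = a.position - vertex.position
    v = c.position - vertex.position
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-8 or nv < 1e-8:
        raise GeometryError("degenerate angle: coincident atoms")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


# ---------------------------------------------------------------------------
# metal-site report
# ---------------------------------------------------------------------------

def _ligand_label(metal: AtomRecord, lig: AtomRecord, s: Structure) -> str:
    if lig.element.upper() == "CL":
        return "Fe-Cl"
    if lig.residue_name == "HIS":
        return f"Fe-His{lig.residue_number}"
    if lig.residue_name not in _AMINO3 and lig.element.upper() in ("O", "S"):
        # inhibitor/substrate oxygen or sulfur: distinguish carboxylate O
        if lig.element.upper() == "O" and _is_carboxylate_oxygen(lig, s):
            return "Fe-O(carb)"
        return "Fe-O/S"
    return f"Fe-{lig.residue_name}{lig.residue_number}:{lig.name}"


def _is_carboxylate_oxygen(o: AtomRecord, s: Structure) -> bool:
    """True if this O is bonded to a carbon that carries a second oxygen."""
    for c in s.atoms:
        if c.element.upper() != "C" or c.chain_id != o.chain_id:
            continue
        if atom_distance(o, c) < 1.6:
            n_o = sum(
                1 for x in s.atoms
                if x.element.upper() == "O" and x is not o
                and x.chain_id == c.chain_id and atom_distance(x, c) < 1.6
            )
            if n_o >= 1:
                return True
    return False


def metal_site_report(s: Structure, chain: str, metal_element: str = "FE",
                      cutoff: float = 3.0) -> MetalSiteGeometry:
    """Distances/angles around the unique metal atom of a chain.

    Ligands are non-hydrogen atoms within ``cutoff`` (A) of the metal.
    Missing ligands are simply absent from the report (never zero).  The
    angle set mirrors the standard characterisation of a 3-His nonheme
    iron site with a bound bidentate ligand and an axial halide.
    """
    metals = [a for a in s.chain(chain)
              if a.element.upper() == metal_element.upper()]
    if len(metals) != 1:
        raise SelectionError(
            f"expected exactly one {metal_element} atom in chain {chain}, "
            f"found {len(metals)}")
    metal = metals[0]

    ligands = [a for a in s.atoms
               if a is not metal and not a.is_hydrogen
               and 0.0 < atom_distance(metal, a) <= cutoff]

    distances: dict[str, float] = {}
    by_label: dict[str, AtomRecord] = {}
    his_d = {}
    for lig in ligands:
        # His: use the coordinating ring nitrogen (NE2 under the
        # delta-protonation convention); skip His carbons inside cutoff.
        if lig.residue_name == "HIS" and lig.name not in ("NE2", "ND1"):
            continue
        label = _ligand_label(metal, lig, s)
        d = atom_distance(metal, lig)
        if label in distances and d >= distances[label]:
            continue
        distances[label] = round(d, 6)
        by_label[label] = lig
        if label.startswith("Fe-His"):
            his_d[label] = d
    if his_d:
        distances["Fe-His(Ave)"] = round(float(np.mean(list(his_d.values()))), 6)

    angles: dict[str, float] = {}
    os_atom = by_label.get("Fe-O/S")
    cl = by_label.get("Fe-Cl")
    ocarb = by_label.get("Fe-O(carb)")

    if os_atom is not None:
        c_alpha = _nearest(s, os_atom, element="C", dmax=1.8)
        if c_alpha is not None:
            angles["Fe-O/S-Ca"] = round(bond_angle(metal, os_atom, c_alpha), 3)
    for hislab, key in (("Fe-His90", "H90-Fe-Cl"),):
        if hislab in by_label and cl is not None:
            angles[key] = round(bond_angle(by_label[hislab], metal, cl), 3)
    if "Fe-His92" in by_label and os_atom is not None:
        angles["H92-Fe-O/S"] = round(bond_angle(by_label["Fe-His92"], metal, os_atom), 3)
    if ocarb is not None and os_atom is not None:
        angles["O(carb)-Fe-O/S"] = round(bond_angle(ocarb, metal, os_atom), 3)

    # backbone angle of the bound three-carbon ligand, when named C1/C2/C3
    lig_chain = {a.name: a for a in s.atoms
                 if a.residue_name not in _AMINO3 and a.chain_id == metal.chain_id
                 and a.name in ("C1", "C2", "C3")}
    if len(lig_chain) == 3:
        angles["C1-C2-C3"] = round(
            bond_angle(lig_chain["C1"], lig_chain["C2"], lig_chain["C3"]), 3)

    contacts: dict[str, float] = {}
    if cl is not None:
        tyr_oh = [a for a in s.atoms
                  if a.residue_name == "TYR" and a.name == "OH"]
        if tyr_oh:
            nearest = min(tyr_oh, key=lambda a: atom_distance(cl, a))
            contacts[f"Cl...Tyr{nearest.residue_number}-OH"] = round(
                atom_distance(cl, nearest), 6)

    return MetalSiteGeometry(metal=metal, ligand_distances=distances,
                             angles_deg=angles, contacts=contacts)


def _nearest(s: Structure, ref: AtomRecord, element: str, dmax: float):
    cands = [a for a in s.atoms
             if a is not ref and a.element.upper() == element.upper()
             and atom_distance(ref, a) <= dmax]
    if not cands:
        return None
    return min(cands, key=lambda a: atom_distance(ref, a))


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal least-squares rigid superposition of P onto Q."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Pc.T).T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def chain_rmsd(s: Structure, chain_a: str, chain_b: str,
               atom_filter: Callable[[AtomRecord], bool] | None = None) -> float:
    """Kabsch-superposed RMSD between two chains.

    Atoms are paired 1:1 by (residue number, atom name) after filtering;
    at least 3 common atoms are required.
    """
    if atom_filter is None:
        atom_filter = lambda a: a.name == "CA"
    map_a = {(a.residue_number, a.name): a for a in s.chain(chain_a) if atom_filter(a)}
    map_b = {(a.residue_number, a.name): a for a in s.chain(chain_b) if atom_filter(a)}
    keys = sorted(set(map_a) & set(map_b))
    if len(keys) < 3:
        raise SelectionError(
            f"chains {chain_a}/{chain_b}: only {len(keys)} common atoms "
            "(need >= 3 for superposition)")
    P = np.array([map_a[k].position for k in keys])
    Q = np.array([map_b[k].position for k in keys])
    return _kabsch_rmsd(P, Q)


def all_pairs_max_rmsd(s: Structure,
                       atom_filter: Callable[[AtomRecord], bool] | None = None,
                       chains: Sequence[str] | None = None) -> float:
    """Maximum pairwise chain RMSD over all unordered chain pairs."""
    cids = list(chains) if chains is not None else s.protein_chains()
    if len(cids) < 2:
        raise SelectionError("need at least two chains for pairwise RMSD")
    worst = 0.0
    for i in range(len(cids)):
        for j in range(i + 1, len(cids)):
            worst = max(worst, chain_rmsd(s, cids[i], cids[j], atom_filter))
    return worst
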