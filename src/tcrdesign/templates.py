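"""Ideal residue geometry: internal-coordinate templates for side-chain building.

Side-chain atoms are rebuilt from internal coordinates (bond, angle, dihedral)
measured on the idealized residue models bundled with biotite (Chemical
Component Dictionary). Atoms whose torsion axis coincides with a canonical
chi bond are tagged with that chi index plus a fixed offset, so a side chain
can be re-posed at arbitrary chi angles; everything else (ring geometry,
branch openings) is rigid. Proline's ring carries no searchable chi and is
rebuilt as a rigid unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Canonical chi torsion quadruples.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# Polar hydrogens retained per residue (side chain; backbone amide H is
# placed separately because it needs the preceding residue).
POLAR_H: dict[str, tuple[str, ...]] = {
    "ARG": ("HE", "HH11", "HH12", "HH21", "HH22"),
    "ASN": ("HD21", "HD22"),
    "GLN": ("HE21", "HE22"),
    "HIS": ("HD1",),
    "LYS": ("HZ1", "HZ2", "HZ3"),
    "SER": ("HG",),
    "THR": ("HG1",),
    "TRP": ("HE1",),
    "TYR": ("HH",),
}

BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT", "H")


def nerf(d: np.ndarray, a: np.ndarray, p: np.ndarray,
         bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place an atom from three reference positions and internal coordinates.

    ``bond`` is the p-X distance (Angstrom); ``angle`` the a-p-X angle and
    ``dihedral`` the d-a-p-X torsion, both in degrees.
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(dihedral)
    bc = p - a
    bc /= np.linalg.norm(bc)
    n = np.cross(a - d, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return p + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v0 = np.asarray(p0) - np.asarray(p1)
    v1 = np.asarray(p2) - np.asarray(p1)
    c = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    parent: str
    angle_ref: str
    dihedral_ref: str
    bond: float
    angle: float
    dihedral: float          # fixed torsion, or offset added to chi
    chi_index: int | None    # 0-based; None = rigid


@dataclass(frozen=True)
class SidechainTemplate:
    aa: str
    atoms: tuple[TemplateAtom, ...]
    n_chi: int


@lru_cache(maxsize=None)
def sidechain_template(aa: str) -> SidechainTemplate:
    """Internal-coordinate template for one amino acid's side chain.

    Build order is a breadth-first tree rooted at CB; each atom's references
    are (parent, grandparent, great-grandparent), which for atoms directly
    bonded to a chi axis makes the stored torsion exactly chi + offset.
    """
    import biotite.structure.info as struc_info

    arr = struc_info.residue(aa)
    names = [str(n) for n in arr.atom_name]
    coord = {n: np.array(arr.coord[i], dtype=float) for i, n in enumerate(names)}
    elem = {n: str(arr.element[i]).capitalize() for i, n in enumerate(names)}
    adj: dict[str, set[str]] = {n: set() for n in names}
    for i, j, _ in arr.bonds.as_array():
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])

    keep_h = set(POLAR_H.get(aa, ()))
    keep = [n for n in names
            if n not in BACKBONE_NAMES
            and not n.startswith("HXT")
            and (not elem[n].startswith("H") or n in keep_h)]

    parent: dict[str, str] = {"CA": "N", "N": "C"}
    order: list[str] = []
    if "CB" in keep:
        parent["CB"] = "CA"
        order.append("CB")
        frontier = ["CB"]
        placed = {"N", "CA", "C", "CB"}
        while frontier:
            nxt = []
            for p in frontier:
                for child in sorted(adj[p]):
                    if child in placed or child not in keep:
                        continue
                    parent[child] = p
                    placed.add(child)
                    order.append(child)
                    nxt.append(child)
            frontier = nxt

    chis = CHI_ATOMS.get(aa, [])
    chi_by_axis = {(q[1], q[2]): (k, q[3]) for k, q in enumerate(chis)}

    atoms = []
    for name in order:
        p = parent[name]
        g = parent[p]
        d = parent[g]
        tor = dihedral_angle(coord[d], coord[g], coord[p], coord[name])
        chi_idx = None
        if (g, p) in chi_by_axis:
            chi_idx, chi_atom = chi_by_axis[(g, p)]
            tor = tor - dihedral_angle(coord[d], coord[g], coord[p], coord[chi_atom])
        atoms.append(TemplateAtom(
            name=name, element=elem[name], parent=p, angle_ref=g,
            dihedral_ref=d,
            bond=float(np.linalg.norm(coord[name] - coord[p])),
            angle=bond_angle(coord[g], coord[p], coord[name]),
            dihedral=tor, chi_index=chi_idx,
        ))
    return SidechainTemplate(aa=aa, atoms=tuple(atoms), n_chi=len(chis))


def build_sidechain(aa: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                    chis: tuple[float, ...] = ()) -> list[tuple[str, str, np.ndarray]]:
    """Return [(atom name, element, position)] for a side chain posed at ``chis``.

    Positions are derived from the residue's actual backbone N/CA/C frame.
    Missing chi values fall back to the template's own torsions (offset 0).
    """
    tpl = sidechain_template(aa)
    pos: dict[str, np.ndarray] = {"N": np.asarray(n, dtype=float),
                                  "CA": np.asarray(ca, dtype=float),
                                  "C": np.asarray(c, dtype=float)}
    out = []
    for atom in tpl.atoms:
        tor = atom.dihedral
        if atom.chi_index is not None:
            base = chis[atom.chi_index] if atom.chi_index < len(chis) else _template_chi(tpl, atom.chi_index)
            tor = base + atom.dihedral
        xyz = nerf(pos[atom.dihedral_ref], pos[atom.angle_ref], pos[atom.parent],
                   atom.bond, atom.angle, tor)
        pos[atom.name] = xyz
        out.append((atom.name, atom.element, xyz))
    return out


@lru_cache(maxsize=None)
def _template_chi(tpl: SidechainTemplate, k: int) -> float:
    import biotite.structure.info as struc_info
    arr = struc_info.residue(tpl.aa)
    coord = {n: np.array(arr.coord[i], dtype=float)
             for i, n in enumerate(arr.atom_name)}
    q = CHI_ATOMS[tpl.aa][k]
    return dihedral_angle(*(coord[x] for x in q))


def sidechain_heavy_names(aa: str) -> tuple[str, ...]:
    """Heavy side-chain atom names (CB and beyond) for an amino acid."""
    return tuple(a.name for a in sidechain_template(aa).atoms
                 if not a.element.startswith("H"))
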