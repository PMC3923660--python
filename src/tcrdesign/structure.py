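"""Molecular structure model for TCR-pMHC complexes.

Reads and writes PDB files (via gemmi), annotates chains with their role in
the complex (TCR alpha/beta, MHC heavy chain, beta-2-microglobulin, peptide),
attaches per-atom physical parameters (partial charge, Lennard-Jones radius
and well depth, implicit-solvation constants) from a united-atom style table
shipped with the package, and synthesizes small idealized two-chain
complexes for testing.

Only polar hydrogens are modeled; nonpolar hydrogens are implicit in the
heavy-atom parameters. Hydrogens are rebuilt with ideal geometry regardless
of whether the input file contained them.
"""

from __future__ import annotations

import copy as _copy
import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .templates import (
    AA1_TO_3,
    AA3,
    POLAR_H,
    build_sidechain,
    dihedral_angle,
    nerf,
    sidechain_heavy_names,
)

BACKBONE_HEAVY = ("N", "CA", "C", "O", "OXT")
WATER_NAMES = ("HOH", "WAT", "H2O", "DOD")


class Role(enum.Enum):
    TCR_ALPHA = "TCR_ALPHA"
    TCR_BETA = "TCR_BETA"
    MHC_HEAVY = "MHC_HEAVY"
    B2M = "B2M"
    PEPTIDE = "PEPTIDE"
    OTHER = "OTHER"


TCR_SIDE = frozenset({Role.TCR_ALPHA, Role.TCR_BETA})
PMHC_SIDE = frozenset({Role.MHC_HEAVY, Role.B2M, Role.PEPTIDE})


class StructureError(Exception):
    """Malformed or inconsistent structure input."""


class ParameterizationError(StructureError):
    """An atom has no entry in the parameter table."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    charge: float | None = None
    lj_radius: float | None = None
    lj_well_depth: float | None = None
    dg_free: float | None = None
    lam: float | None = None
    volume: float | None = None
    is_hydrogen: bool = False
    is_water: bool = False

    @property
    def parameterized(self) -> bool:
        return self.lj_radius is not None

    def copy(self) -> "Atom":
        a = _copy.copy(self)
        a.position = self.position.copy()
        return a


@dataclass
class Residue:
    chain_id: str
    seq: int
    aa: str                      # 3-letter code (or HOH for waters)
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.chain_id}{self.seq} has no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_heavy_atoms(self) -> list[Atom]:
        """Side chain = CB and beyond; glycine has none."""
        return [a for a in self.atoms
                if not a.is_hydrogen and a.name not in BACKBONE_HEAVY]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq, self.aa,
                       [a.copy() for a in self.atoms], self.icode)


class StructureModel:
    """Chains of residues with role labels plus a separate water collection."""

    def __init__(self, chains: dict[str, list[Residue]] | None = None,
                 roles: dict[str, Role] | None = None,
                 waters: list[Residue] | None = None):
        self.chains: dict[str, list[Residue]] = chains or {}
        self.roles: dict[str, Role] = roles or {}
        self.waters: list[Residue] = waters or []
        self.repacked: set[tuple[str, int, str]] = set()

    # -- traversal ---------------------------------------------------------
    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def find_residue(self, chain_id: str, seq: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.seq == seq and res.icode == icode:
                return res
        raise StructureError(f"no residue {chain_id}{seq}{icode}")

    def atoms(self, include_waters: bool = True):
        for res in self.residues():
            yield from ((res, a) for a in res.atoms)
        if include_waters:
            for res in self.waters:
                yield from ((res, a) for a in res.atoms)

    def side_residues(self, side: frozenset[Role]):
        for cid, chain in self.chains.items():
            if self.roles.get(cid) in side:
                yield from chain

    def n_atoms(self, include_waters: bool = True) -> int:
        return sum(1 for _ in self.atoms(include_waters))

    def copy(self) -> "StructureModel":
        m = StructureModel(
            {cid: [r.copy() for r in chain] for cid, chain in self.chains.items()},
            dict(self.roles),
            [r.copy() for r in self.waters],
        )
        m.repacked = set(self.repacked)
        return m

    # -- backbone dihedrals ------------------------------------------------
    def phi_psi(self, res: Residue) -> tuple[float | None, float | None]:
        """(phi, psi) in degrees; None at chain termini or chain breaks."""
        chain = self.chains[res.chain_id]
        i = chain.index(res)
        phi = psi = None
        if i > 0:
            prev = chain[i - 1]
            if prev.has_atom("C") and all(res.has_atom(n) for n in ("N", "CA", "C")):
                phi = dihedral_angle(prev.atom("C").position, res.atom("N").position,
                                     res.atom("CA").position, res.atom("C").position)
        if i < len(chain) - 1:
            nxt = chain[i + 1]
            if nxt.has_atom("N") and all(res.has_atom(n) for n in ("N", "CA", "C")):
                psi = dihedral_angle(res.atom("N").position, res.atom("CA").position,
                                     res.atom("C").position, nxt.atom("N").position)
        return phi, psi


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, keep_waters: bool = True) -> StructureModel:
    """Read a PDB file into a StructureModel.

    All ATOM records are retained; water HETATM records are retained iff
    ``keep_waters``. Alternate locations are resolved to the highest
    occupancy (ties broken by altloc letter order). Chain order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    gmodel = st[0]

    model = StructureModel()
    n_atoms = 0
    for gchain in gmodel:
        for gres in gchain:
            is_water = gres.name in WATER_NAMES
            if is_water and not keep_waters:
                continue
            res = Residue(chain_id=gchain.name, seq=gres.seqid.num,
                          aa=gres.name, icode=(gres.seqid.icode or "").strip())
            chosen: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = chosen.get(ga.name)
                if prev is None or (ga.occ, -ord(ga.altloc or "z")) > \
                        (prev.occ, -ord(prev.altloc or "z")):
                    chosen[ga.name] = ga
            for ga in gres:           # preserve file order of unique names
                if chosen.get(ga.name) is not ga:
                    continue
                elem = ga.element.name
                res.atoms.append(Atom(
                    name=ga.name, element=elem,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ, b_factor=ga.b_iso,
                    is_hydrogen=elem == "H", is_water=is_water,
                ))
                n_atoms += 1
            if is_water:
                model.waters.append(res)
            else:
                model.chains.setdefault(gchain.name, []).append(res)
    if n_atoms == 0:
        raise StructureError(f"{path}: no ATOM records")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (ATOM/HETATM/TER records)."""
    st = gemmi.Structure()
    st.name = "tcrdesign"
    gmodel = gemmi.Model("1")

    def _add(gchain: gemmi.Chain, res: Residue, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.aa
        gres.seqid = gemmi.SeqId(res.seq, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            gres.add_atom(ga)
        gchain.add_residue(gres)

    for cid, chain in model.chains.items():
        gchain = gemmi.Chain(cid)
        for res in chain:
            _add(gchain, res, het=False)
        gmodel.add_chain(gchain)
    if model.waters:
        gchain = gemmi.Chain("W" if "W" not in model.chains else "w")
        for res in model.waters:
            _add(gchain, res, het=True)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def assign_roles(model: StructureModel,
                 role_map: dict[str, Role | str] | None = None) -> StructureModel:
    """Label each chain with its role in the TCR-pMHC complex.

    With an explicit ``role_map`` the mapping is applied as given. Otherwise
    a length heuristic is used: the 8-13 residue chain is the peptide, a
    ~99-residue chain is beta-2-microglobulin, a longer (>=200) chain is the
    MHC heavy chain, and the remaining two chains are TCR alpha and beta in
    declared order.
    """
    if role_map is not None:
        for cid, role in role_map.items():
            if cid not in model.chains:
                raise StructureError(f"role map names unknown chain {cid}")
            model.roles[cid] = Role(role) if not isinstance(role, Role) else role
        for cid in model.chains:
            model.roles.setdefault(cid, Role.OTHER)
        return model

    lengths = {cid: len(chain) for cid, chain in model.chains.items()}

    def _pick(pred, label):
        cands = [cid for cid in lengths if pred(lengths[cid])]
        if len(cands) > 1:
            raise StructureError(
                f"ambiguous {label} assignment; candidates: {sorted(cands)}")
        return cands[0] if cands else None

    roles: dict[str, Role] = {}
    pep = _pick(lambda n: 8 <= n <= 13, "PEPTIDE")
    if pep:
        roles[pep] = Role.PEPTIDE
    b2m = _pick(lambda n: 80 <= n <= 119, "B2M")
    if b2m:
        roles[b2m] = Role.B2M
    mhc = _pick(lambda n: n >= 200, "MHC_HEAVY")
    if mhc:
        roles[mhc] = Role.MHC_HEAVY
    rest = [cid for cid in model.chains if cid not in roles]
    if len(rest) >= 2:
        roles[rest[0]] = Role.TCR_ALPHA
        roles[rest[1]] = Role.TCR_BETA
        for cid in rest[2:]:
            roles[cid] = Role.OTHER
    elif len(rest) == 1:
        roles[rest[0]] = Role.TCR_ALPHA
    model.roles = roles
    return model


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def load_parameter_table(path: str | Path | None = None) -> dict[tuple[str, str], dict]:
    """Load the per-atom parameter table (CSV shipped with the package).

    Keys are (residue name, atom name); the wildcard residue ``ANY`` matches
    any residue (used for terminal OXT).
    """
    if path is None:
        src = resources.files("tcrdesign.data").joinpath("atom_params.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[str, str], dict] = {}
    for row in csv.DictReader(text.splitlines()):
        res, atom = row["atom_type"].split(":")
        table[(res, atom)] = {
            "charge": float(row["charge"]),
            "lj_radius": float(row["lj_radius"]),
            "lj_well_depth": float(row["lj_well_depth"]),
            "dg_free": float(row["dg_free"]),
            "lam": float(row["lambda"]),
            "volume": float(row["volume"]),
        }
    return table


def _place_amide_h(prev: Residue, res: Residue) -> Atom | None:
    if res.aa == "PRO" or res.has_atom("H"):
        return None
    try:
        n = res.atom("N").position
        ca = res.atom("CA").position
        c_prev = prev.atom("C").position
    except StructureError:
        return None
    u = (n - ca) / np.linalg.norm(n - ca) + (n - c_prev) / np.linalg.norm(n - c_prev)
    u /= np.linalg.norm(u)
    return Atom(name="H", element="H", position=n + 1.00 * u, is_hydrogen=True)


def place_polar_hydrogens(model: StructureModel) -> StructureModel:
    """Add missing polar hydrogens (backbone amide, side-chain N/O donors).

    Positions come from ideal geometry: the amide H bisects the C(prev)-N-CA
    opening; side-chain hydrogens use the internal coordinates of the shipped
    residue templates evaluated on the actual heavy-atom positions. Rotatable
    hydroxyl hydrogens get the template torsion (no optimization).
    """
    from .templates import sidechain_template

    for chain in model.chains.values():
        for i, res in enumerate(chain):
            if res.aa not in AA3:
                continue
            if i > 0:
                h = _place_amide_h(chain[i - 1], res)
                if h is not None:
                    res.atoms.append(h)
            wanted = POLAR_H.get(res.aa, ())
            if not wanted:
                continue
            tpl = sidechain_template(res.aa)
            pos = {a.name: a.position for a in res.atoms}
            for ta in tpl.atoms:
                if ta.name not in wanted or ta.name in pos:
                    continue
                if not all(r in pos for r in
                           (ta.parent, ta.angle_ref, ta.dihedral_ref)):
                    continue
                tor = ta.dihedral
                if ta.chi_index is not None:
                    # measure the current chi from heavy atoms
                    q = None
                    from .templates import CHI_ATOMS
                    quad = CHI_ATOMS[res.aa][ta.chi_index]
                    if all(x in pos for x in quad):
                        q = dihedral_angle(*(pos[x] for x in quad))
                    tor = (q if q is not None else 0.0) + ta.dihedral
                xyz = nerf(pos[ta.dihedral_ref], pos[ta.angle_ref],
                           pos[ta.parent], ta.bond, ta.angle, tor)
                pos[ta.name] = xyz
                res.atoms.append(Atom(name=ta.name, element="H",
                                      position=xyz, is_hydrogen=True))
    return model


def assign_parameters(model: StructureModel,
                      parameter_table: dict | None = None) -> StructureModel:
    """Attach charges, LJ and solvation parameters to every atom.

    Missing polar hydrogens are placed first. Unknown atoms raise a
    ParameterizationError naming the residue and atom. Idempotent.
    """
    table = parameter_table if parameter_table is not None else load_parameter_table()
    place_polar_hydrogens(model)
    for res, atom in model.atoms(include_waters=True):
        key = (res.aa, atom.name)
        row = table.get(key) or table.get(("ANY", atom.name))
        if row is None and res.aa in WATER_NAMES:
            row = table.get(("HOH", atom.name))
        if row is None:
            if atom.is_water and atom.is_hydrogen:
                continue  # bare water hydrogens carry no parameters
            raise ParameterizationError(
                f"no parameters for atom {atom.name!r} in residue "
                f"{res.aa} {res.chain_id}{res.seq}")
        atom.charge = row["charge"]
        atom.lj_radius = row["lj_radius"]
        atom.lj_well_depth = row["lj_well_depth"]
        atom.dg_free = row["dg_free"]
        atom.lam = row["lam"]
        atom.volume = row["volume"]
    return model


# ---------------------------------------------------------------------------
# Synthetic complexes
# ---------------------------------------------------------------------------

_BB = {  # idealized backbone internal coordinates
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.229,
    "ang_n_ca_c": 111.0, "ang_ca_c_n": 116.6, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5,
}


def _build_chain(chain_id: str, sequence: str, start_seq: int = 1,
                 phi: float = -139.0, psi: float = 135.0) -> list[Residue]:
    """Extended-conformation chain with idealized backbone geometry."""
    residues = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(_BB["ang_n_ca_c"])
    c = ca + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i, aa1 in enumerate(sequence):
        aa = AA1_TO_3[aa1.upper()]
        res = Residue(chain_id=chain_id, seq=start_seq + i, aa=aa)
        res.atoms.append(Atom("N", "N", n.copy()))
        res.atoms.append(Atom("CA", "C", ca.copy()))
        res.atoms.append(Atom("C", "C", c.copy()))
        n_next = nerf(n, ca, c, _BB["c_n"], _BB["ang_ca_c_n"], psi)
        o = nerf(n, ca, c, _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
        res.atoms.append(Atom("O", "O", o))
        if aa != "GLY":
            for name, element, xyz in build_sidechain(aa, n, ca, c):
                res.atoms.append(Atom(name, element, xyz,
                                      is_hydrogen=element == "H"))
        residues.append(res)
        if i == len(sequence) - 1:
            break
        ca_next = nerf(ca, c, n_next, _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
        c_next = nerf(c, n_next, ca_next, _BB["ca_c"], _BB["ang_n_ca_c"], phi)
        n, ca, c = n_next, ca_next, c_next
    return residues


def _min_heavy_distance(res_a: list[Residue], res_b: list[Residue]) -> float:
    pa = np.array([a.position for r in res_a for a in r.heavy_atoms()])
    pb = np.array([a.position for r in res_b for a in r.heavy_atoms()])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def make_synthetic_complex(seed: int = 0, n_receptor: int = 5, n_ligand: int = 3,
                           gap: float = 5.0, receptor_seq: str | None = None,
                           ligand_seq: str | None = None,
                           parameterize: bool = True) -> StructureModel:
    """Deterministic two-chain poly-alanine complex for tests and fixtures.

    Two idealized extended chains (optionally with substitutions given as
    one-letter sequences) are separated so that the minimum inter-chain
    heavy-atom distance equals ``gap``. The receptor chain A is labeled
    TCR_ALPHA and the ligand chain B PEPTIDE.
    """
    if n_receptor < 1 or n_ligand < 1:
        raise ValueError("chain lengths must be >= 1")
    rec_seq = (receptor_seq or "A" * n_receptor).upper()
    lig_seq = (ligand_seq or "A" * n_ligand).upper()
    if len(rec_seq) != n_receptor or len(lig_seq) != n_ligand:
        raise ValueError("sequence length does not match residue count")

    rng = np.random.default_rng(seed)
    receptor = _build_chain("A", rec_seq)
    ligand = _build_chain("B", lig_seq)
    for res in (*receptor, *ligand):
        for a in res.atoms:
            a.position = a.position + rng.normal(0.0, 0.005, size=3)
    # ligand runs antiparallel above the receptor
    for res in ligand:
        for a in res.atoms:
            x, y, z = a.position
            a.position = np.array([-x, -y, z])
    # lift the ligand along +z until the closest heavy-atom pair sits at ``gap``
    pa = np.array([a.position for r in receptor for a in r.heavy_atoms()])
    pb = np.array([a.position for r in ligand for a in r.heavy_atoms()])
    dxy2 = ((pa[:, None, :2] - pb[None, :, :2]) ** 2).sum(-1)
    dz0 = pb[None, :, 2] - pa[:, None, 2]

    def _mindist(s: float) -> float:
        return float(np.sqrt(dxy2 + (dz0 + s) ** 2).min())

    from scipy.optimize import brentq
    lo, hi = 0.0, gap + 20.0
    if _mindist(lo) < gap:
        s = float(brentq(lambda s: _mindist(s) - gap, lo, hi, xtol=1e-10))
    else:
        s = 0.0 if _mindist(0.0) <= gap + 0.5 else \
            float(brentq(lambda s: _mindist(s) - gap, -5.0, hi, xtol=1e-10))
    for res in ligand:
        for a in res.atoms:
            a.position = a.position + np.array([0.0, 0.0, s])

    model = StructureModel(chains={"A": receptor, "B": ligand},
                           roles={"A": Role.TCR_ALPHA, "B": Role.PEPTIDE})
    if parameterize:
        assign_parameters(model)
    return model
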