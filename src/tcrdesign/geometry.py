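"""Interface geometry: contacts, buried surface, hydrogen bonds, RMSD,
and the TCR-pMHC crossing angle.

Distance criteria use heavy atoms only. "Side chain" means CB and beyond,
so glycine has no side-chain atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energy import _AtomGroup
from .structure import (
    PMHC_SIDE,
    TCR_SIDE,
    Atom,
    Residue,
    Role,
    StructureError,
    StructureModel,
)


@dataclass(frozen=True)
class InterfaceDefinition:
    """Distance and sampling criteria for interface analysis (Angstrom)."""
    cutoff_interface: float = 5.5    # TCR residue near pMHC
    cutoff_contact: float = 6.0      # peptide residue near a mutant side chain
    rmsd_zone: float = 10.0          # backbone-RMSD zone around the interface
    probe_radius: float = 1.4        # SASA probe
    hbond_ha_max: float = 2.7        # H...acceptor maximum
    hbond_da_max: float = 3.6        # donor...acceptor maximum
    sasa_points: int = 960           # sphere-sampling density per atom

    def __post_init__(self):
        for name in ("cutoff_interface", "cutoff_contact", "rmsd_zone",
                     "probe_radius", "hbond_ha_max", "hbond_da_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_DEFN = InterfaceDefinition()

# SASA atomic radii by element (Angstrom)
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _heavy(residues) -> list[tuple[Residue, Atom]]:
    return [(r, a) for r in residues for a in r.heavy_atoms()]


def interface_residues(model: StructureModel,
                       defn: InterfaceDefinition = DEFAULT_DEFN) -> list[Residue]:
    """TCR-side residues with any heavy atom within the interface cutoff of
    any pMHC-side heavy atom, sorted by chain then residue number."""
    if not model.roles:
        raise StructureError("assign chain roles before interface analysis")
    tcr = _heavy(model.side_residues(TCR_SIDE))
    pmhc = _heavy(model.side_residues(PMHC_SIDE))
    if not tcr or not pmhc:
        raise StructureError("need both TCR-side and pMHC-side chains")
    tree = cKDTree(np.array([a.position for _, a in pmhc]))
    hits: dict[tuple, Residue] = {}
    dists, _ = tree.query(np.array([a.position for _, a in tcr]),
                          distance_upper_bound=defn.cutoff_interface)
    for (res, _), d in zip(tcr, dists):
        if np.isfinite(d):
            hits.setdefault(res.key, res)
    order = {cid: i for i, cid in enumerate(model.chains)}
    return sorted(hits.values(),
                  key=lambda r: (order[r.chain_id], r.seq, r.icode))


def residue_contacts(model: StructureModel, residue: Residue,
                     defn: InterfaceDefinition = DEFAULT_DEFN) -> list[Residue]:
    """Peptide residues with any heavy atom within the contact cutoff of any
    side-chain heavy atom of the query residue."""
    if residue.key not in {r.key for r in model.residues()}:
        raise StructureError(f"residue {residue.key} not in model")
    side = residue.sidechain_heavy_atoms()
    if not side:
        return []
    pep = [(r, a) for cid, chain in model.chains.items()
           if model.roles.get(cid) is Role.PEPTIDE
           for r in chain for a in r.heavy_atoms()]
    if not pep:
        return []
    spos = np.array([a.position for a in side])
    out: dict[tuple, Residue] = {}
    for r, a in pep:
        if np.linalg.norm(spos - a.position, axis=1).min() <= defn.cutoff_contact:
            out.setdefault(r.key, r)
    return sorted(out.values(), key=lambda r: (r.chain_id, r.seq, r.icode))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley sphere sampling)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(atoms: list[Atom], defn: InterfaceDefinition = DEFAULT_DEFN) -> np.ndarray:
    """Per-atom solvent-accessible surface area of heavy atoms, A^2.

    Sphere sampling with >= 960 points per atom; element-typed radii plus
    the probe radius.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        return np.zeros(0)
    pos = np.array([a.position for a in heavy])
    rad = np.array([SASA_RADII.get(a.element, 1.7) + defn.probe_radius
                    for a in heavy])
    sphere = _fibonacci_sphere(defn.sasa_points)
    tree = cKDTree(pos)
    out = np.zeros(len(heavy))
    rmax = rad.max()
    for i in range(len(heavy)):
        pts = pos[i] + rad[i] * sphere
        nbrs = [j for j in tree.query_ball_point(pos[i], rad[i] + rmax)
                if j != i]
        if nbrs:
            d = np.linalg.norm(pts[:, None, :] - pos[nbrs][None, :, :], axis=-1)
            buried = (d < rad[nbrs][None, :]).any(axis=1)
        else:
            buried = np.zeros(len(pts), dtype=bool)
        out[i] = 4.0 * np.pi * rad[i] ** 2 * (1.0 - buried.mean())
    return out


def buried_sasa(model: StructureModel,
                defn: InterfaceDefinition = DEFAULT_DEFN) -> dict[str, float]:
    """Complex and free-chain SASA plus the pMHC surface buried on binding.

    pmhc_buried = (pMHC SASA computed alone) - (pMHC portion of the complex
    SASA). Waters are excluded from the surface calculation.
    """
    tcr_atoms = [a for r in model.side_residues(TCR_SIDE) for a in r.heavy_atoms()]
    pmhc_atoms = [a for r in model.side_residues(PMHC_SIDE) for a in r.heavy_atoms()]
    if not tcr_atoms or not pmhc_atoms:
        raise StructureError("need both interface sides for buried SASA")
    all_atoms = tcr_atoms + pmhc_atoms
    per_atom = sasa(all_atoms, defn)
    complex_sasa = float(per_atom.sum())
    pmhc_in_complex = float(per_atom[len(tcr_atoms):].sum())
    tcr_free = float(sasa(tcr_atoms, defn).sum())
    pmhc_free = float(sasa(pmhc_atoms, defn).sum())
    return {
        "complex_sasa": complex_sasa,
        "tcr_free_sasa": tcr_free,
        "pmhc_free_sasa": pmhc_free,
        "pmhc_buried": pmhc_free - pmhc_in_complex,
    }


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrogenBond:
    donor_res: tuple
    donor_atom: str
    acceptor_res: tuple
    acceptor_atom: str
    water_mediated: bool = False
    water_res: tuple | None = None


def hydrogen_bonds(model: StructureModel,
                   defn: InterfaceDefinition = DEFAULT_DEFN) -> list[HydrogenBond]:
    """Geometric hydrogen bonds: H...A <= 2.7 A and D...A <= 3.6 A.

    Polar hydrogens must be present (assign_parameters places them). A
    water-mediated bond is reported when one water bridges a donor and an
    acceptor: the solute-donor leg obeys both criteria toward the water
    oxygen; the water-to-acceptor leg uses the donor-acceptor distance
    criterion only (water hydrogens are not required).
    """
    pairs = [(r, a) for r in model.residues() for a in r.atoms]
    grp = _AtomGroup(pairs, require_params=False)
    bonds: list[HydrogenBond] = []
    hi = np.flatnonzero(grp.donor_h)
    ai = np.flatnonzero(grp.acceptor)
    if ai.size:
        apos = grp.pos[ai]
        for i in hi:
            dj = grp.donor_heavy_idx[i]
            dha = np.linalg.norm(apos - grp.pos[i], axis=1)
            daa = np.linalg.norm(apos - grp.pos[dj], axis=1)
            ok = (dha <= defn.hbond_ha_max) & (daa <= defn.hbond_da_max)
            for k in np.flatnonzero(ok):
                j = ai[k]
                if grp.res[j] is grp.res[i]:
                    continue
                bonds.append(HydrogenBond(
                    donor_res=grp.res[dj].key, donor_atom=grp.atoms[dj].name,
                    acceptor_res=grp.res[j].key, acceptor_atom=grp.atoms[j].name))
    # water bridges
    for wres in model.waters:
        try:
            ow = wres.atom("O")
        except StructureError:
            continue
        donors: list[int] = []
        for i in hi:
            dj = grp.donor_heavy_idx[i]
            if (np.linalg.norm(ow.position - grp.pos[i]) <= defn.hbond_ha_max and
                    np.linalg.norm(ow.position - grp.pos[dj]) <= defn.hbond_da_max):
                donors.append(dj)
        accs = [j for j in ai
                if np.linalg.norm(ow.position - grp.pos[j]) <= defn.hbond_da_max]
        for dj in donors:
            for j in accs:
                if grp.res[j] is grp.res[dj]:
                    continue
                bonds.append(HydrogenBond(
                    donor_res=grp.res[dj].key, donor_atom=grp.atoms[dj].name,
                    acceptor_res=grp.res[j].key, acceptor_atom=grp.atoms[j].name,
                    water_mediated=True, water_res=wres.key))
    return bonds


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping q onto p (least squares)."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = pc - r @ qc
    return r, t


def superpose_and_rmsd(model_a: StructureModel, model_b: StructureModel,
                       selection=None) -> dict:
    """Least-squares rigid superposition of model_b onto model_a.

    ``selection`` is a predicate (residue, atom) -> bool (default: all heavy
    atoms). Atoms are matched 1:1 by (chain, residue, insertion code, atom
    name); a mismatch raises an error naming the unmatched atoms. Returns
    {"rotation", "translation", "rmsd"}.
    """
    if selection is None:
        selection = lambda res, atom: not atom.is_hydrogen  # noqa: E731

    def _collect(m):
        return {(r.key, a.name): a.position
                for r, a in m.atoms(include_waters=False) if selection(r, a)}

    da = _collect(model_a)
    db = _collect(model_b)
    if set(da) != set(db):
        missing = sorted(set(da) ^ set(db))[:8]
        raise StructureError(f"selection mismatch between models: {missing}")
    keys = sorted(da)
    p = np.array([da[k] for k in keys])
    q = np.array([db[k] for k in keys])
    r, t = _kabsch(p, q)
    q2 = q @ r.T + t
    rmsd = float(np.sqrt(((p - q2) ** 2).sum(axis=1).mean()))
    return {"rotation": r, "translation": t, "rmsd": rmsd}


def backbone_interface_selection(model: StructureModel,
                                 defn: InterfaceDefinition = DEFAULT_DEFN):
    """Predicate selecting backbone atoms of residues within the RMSD zone of
    the binding interface (both sides)."""
    tcr = _heavy(model.side_residues(TCR_SIDE))
    pmhc = _heavy(model.side_residues(PMHC_SIDE))
    ttree = cKDTree(np.array([a.position for _, a in tcr]))
    ptree = cKDTree(np.array([a.position for _, a in pmhc]))
    zone: set[tuple] = set()
    for res, a in tcr:
        if ptree.query(a.position)[0] <= defn.rmsd_zone:
            zone.add(res.key)
    for res, a in pmhc:
        if ttree.query(a.position)[0] <= defn.rmsd_zone:
            zone.add(res.key)

    def pred(res, atom):
        return res.key in zone and atom.name in ("N", "CA", "C", "O")

    return pred


# ---------------------------------------------------------------------------
# Crossing angle
# ---------------------------------------------------------------------------

def crossing_angle(model: StructureModel, v_domain_length: int = 115,
                   signed: bool = False) -> float:
    """TCR-pMHC docking (crossing) angle in degrees.

    Definition used here: the angle between (i) the vector joining the mass
    centers of the V-alpha and V-beta domains (first ``v_domain_length``
    residues of each TCR chain) and (ii) the peptide-groove axis (principal
    line through the peptide CA atoms, oriented N- to C-terminus), both
    projected onto the MHC binding-platform plane (principal plane of the
    MHC alpha-1/alpha-2 CA atoms, residues 1-180; if no MHC chain is
    present, the principal plane of the peptide CAs and domain centers).
    Unsigned values lie in [0, 90]; with ``signed=True`` the sign is that of
    cross(TCR vector, peptide axis) . plane normal (right-handed, normal
    pointing from platform toward the TCR).
    """
    pep = [r for cid, chain in model.chains.items()
           if model.roles.get(cid) is Role.PEPTIDE for r in chain]
    if not pep:
        raise StructureError("no peptide chain; cannot compute crossing angle")
    pep_ca = np.array([r.atom("CA").position for r in pep if r.has_atom("CA")])
    if len(pep_ca) < 2:
        raise StructureError("peptide too short for an axis fit")
    pep_axis = _principal_axis(pep_ca)
    if pep_axis @ (pep_ca[-1] - pep_ca[0]) < 0:
        pep_axis = -pep_axis

    centers = []
    for role in (Role.TCR_ALPHA, Role.TCR_BETA):
        chains = [c for cid, c in model.chains.items()
                  if model.roles.get(cid) is role]
        if not chains:
            raise StructureError(f"missing {role.value} chain")
        res = chains[0][:v_domain_length]
        pos = np.array([a.position for r in res for a in r.heavy_atoms()])
        centers.append(pos.mean(axis=0))
    tcr_vec = centers[1] - centers[0]

    mhc = [r for cid, chain in model.chains.items()
           if model.roles.get(cid) is Role.MHC_HEAVY for r in chain[:180]]
    if mhc:
        plane_pts = np.array([r.atom("CA").position for r in mhc
                              if r.has_atom("CA")])
    else:
        plane_pts = np.vstack([pep_ca, centers])
    normal = _plane_normal(plane_pts)
    tcr_up = np.mean(centers, axis=0) - plane_pts.mean(axis=0)
    if normal @ tcr_up < 0:
        normal = -normal

    u1 = tcr_vec - (tcr_vec @ normal) * normal
    u2 = pep_axis - (pep_axis @ normal) * normal
    if np.linalg.norm(u1) < 1e-9 or np.linalg.norm(u2) < 1e-9:
        raise StructureError("degenerate projection; cannot define angle")
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    cosang = abs(float(u1 @ u2))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if signed:
        s = np.sign(float(np.cross(u1, u2) @ normal)) or 1.0
        return s * ang
    return ang


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    return vt[0]


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    return vt[-1]
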