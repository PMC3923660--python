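"""Point-mutant modeling: rotamer repacking of the mutated side chain with
optional torsion-space minimization of the interface.

Protocols mirror the four modeling modes used for TCR design work:

* NOMIN  - only the mutant side chain is repacked (exhaustive enumeration
  over the expanded rotamer set against a fixed environment); the backbone
  is untouched.
* MIN_SC - additionally minimizes interface side-chain chi angles.
* MIN_BB - additionally minimizes interface backbone phi/psi.
* MIN    - both.

The rotamer library is a compact backbone-independent set of chi-angle
means shipped as CSV, expanded with +/- one standard deviation sub-rotamers
on chi1-chi3. Packing is fully deterministic: ties in energy resolve to the
lowest library index.
"""

from __future__ import annotations

import csv
import enum
import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from .energy import (
    ZAFFI_1_1,
    ScoreWeights,
    _AtomGroup,
    _cross_terms,
    intra_residue_repulsion,
    score,
)
from .geometry import DEFAULT_DEFN, InterfaceDefinition, interface_residues
from .structure import (
    Atom,
    PMHC_SIDE,
    Residue,
    Role,
    StructureError,
    StructureModel,
    load_parameter_table,
)
from .templates import (
    AA1_TO_3,
    AA3_TO_1,
    CHI_ATOMS,
    build_sidechain,
    dihedral_angle,
    sidechain_template,
)

logger = logging.getLogger(__name__)

_GREEK = {"α": Role.TCR_ALPHA, "a": Role.TCR_ALPHA, "A": Role.TCR_ALPHA,
          "β": Role.TCR_BETA, "b": Role.TCR_BETA, "B": Role.TCR_BETA}
_ROLE_GREEK = {Role.TCR_ALPHA: "α", Role.TCR_BETA: "β"}


@dataclass(frozen=True)
class MutationSpec:
    """One point substitution on a TCR chain, e.g. alpha-D26Y."""
    chain_role: Role
    position: int
    wt_aa: str      # one-letter
    mut_aa: str     # one-letter

    def __post_init__(self):
        if self.chain_role not in (Role.TCR_ALPHA, Role.TCR_BETA):
            raise ValueError("mutations are specified on TCR chains")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA1_TO_3:
                raise ValueError(f"unknown amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant amino acids are identical")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse compact notation like 'αD26Y', 'aD26Y' or 'bL98W'."""
        text = text.strip()
        if len(text) < 4 or text[0] not in _GREEK:
            raise ValueError(f"cannot parse mutation {text!r}")
        role = _GREEK[text[0]]
        wt = text[1].upper()
        mut = text[-1].upper()
        pos = int(text[2:-1])
        return cls(chain_role=role, position=pos, wt_aa=wt, mut_aa=mut)

    def __str__(self) -> str:
        return f"{_ROLE_GREEK[self.chain_role]}{self.wt_aa}{self.position}{self.mut_aa}"


class PackingMode(enum.Enum):
    NOMIN = "nomin"
    MIN_SC = "minsc"
    MIN_BB = "minbb"
    MIN = "min"


@dataclass(frozen=True)
class PackingProtocol:
    mode: PackingMode = PackingMode.NOMIN
    include_waters: bool = False


class RotamerLibrary:
    """Backbone-independent chi-angle rotamer library with sub-rotamer
    expansion (+/- sigma on chi1-chi3)."""

    def __init__(self, rotamers: dict[str, list[tuple[float, ...]]],
                 sigma: float = 9.0):
        self._rot = rotamers
        self.sigma = sigma

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RotamerLibrary":
        if path is None:
            text = resources.files("tcrdesign.data").joinpath(
                "rotamers.csv").read_text()
        else:
            text = Path(path).read_text()
        rot: dict[str, list[tuple[float, ...]]] = {}
        sigma = 9.0
        for row in csv.DictReader(text.splitlines()):
            chis = tuple(float(row[f"chi{k}"]) for k in range(1, 5)
                         if row[f"chi{k}"] != "")
            rot.setdefault(row["aa"], []).append(chis)
            sigma = float(row["sigma"])
        return cls(rot, sigma=sigma)

    def base_rotamers(self, aa3: str) -> list[tuple[float, ...]]:
        return list(self._rot.get(aa3, [()]))  # GLY/ALA/PRO: one bare entry

    def expanded_rotamers(self, aa3: str) -> list[tuple[float, ...]]:
        """Base rotamers plus +/- sigma sub-rotamers on chi1-chi3."""
        out = []
        for chis in self.base_rotamers(aa3):
            nexp = min(len(chis), 3)
            offset_sets = [(-self.sigma, 0.0, self.sigma)] * nexp + \
                          [(0.0,)] * (len(chis) - nexp)
            for offs in itertools.product(*offset_sets):
                out.append(tuple(c + o for c, o in zip(chis, offs)))
        return out


_DEFAULT_LIB: RotamerLibrary | None = None


def default_rotamer_library() -> RotamerLibrary:
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        _DEFAULT_LIB = RotamerLibrary.load()
    return _DEFAULT_LIB


def chain_of_role(model: StructureModel, role: Role) -> str:
    for cid, r in model.roles.items():
        if r is role:
            return cid
    raise StructureError(f"model has no chain with role {role.value}")


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------

def _strip_sidechain(res: Residue) -> None:
    keep = ("N", "CA", "C", "O", "OXT", "H")
    res.atoms = [a for a in res.atoms if a.name in keep]


def _parameterize_atoms(res: Residue, table: dict) -> None:
    for a in res.atoms:
        if a.parameterized:
            continue
        row = table.get((res.aa, a.name)) or table.get(("ANY", a.name))
        if row is None:
            raise StructureError(
                f"no parameters for {a.name} in {res.aa} {res.chain_id}{res.seq}")
        a.charge = row["charge"]
        a.lj_radius = row["lj_radius"]
        a.lj_well_depth = row["lj_well_depth"]
        a.dg_free = row["dg_free"]
        a.lam = row["lam"]
        a.volume = row["volume"]


def _build_rotamer(res: Residue, aa3: str, chis: tuple[float, ...],
                   table: dict) -> None:
    """Replace the residue's side chain with ``aa3`` posed at ``chis``."""
    _strip_sidechain(res)
    res.aa = aa3
    if aa3 != "GLY":
        n = res.atom("N").position
        ca = res.atom("CA").position
        c = res.atom("C").position
        for name, element, xyz in build_sidechain(aa3, n, ca, c, chis):
            res.atoms.append(Atom(name, element, xyz,
                                  is_hydrogen=element == "H"))
    _parameterize_atoms(res, table)


def packing_energy(model: StructureModel, res: Residue,
                   weights: ScoreWeights = ZAFFI_1_1,
                   include_waters: bool = False,
                   _env_group: _AtomGroup | None = None) -> float:
    """Weighted interaction energy of one residue's side chain with its fixed
    environment, plus the residue's intra-residue repulsion."""
    side = [(res, a) for a in res.atoms if a.name not in
            ("N", "CA", "C", "O", "OXT", "H")]
    env = _env_group if _env_group is not None else \
        environment_group(model, res, include_waters)
    w = weights
    if side:
        terms = _cross_terms(_AtomGroup(side), env)
        e = (w.w_vdw_attr * terms["vdw_attr"] + w.w_vdw_rep * terms["vdw_rep"]
             + w.w_solvation * terms["solvation"] + w.w_hbond * terms["hbond"]
             + w.w_elec * terms["electrostatics"])
    else:
        e = 0.0
    return e + w.w_intra_rep * intra_residue_repulsion(res)


def environment_group(model: StructureModel, res: Residue,
                      include_waters: bool) -> _AtomGroup:
    pairs = [(r, a) for r in model.residues() if r.key != res.key
             for a in r.atoms]
    if include_waters:
        pairs += [(r, a) for r in model.waters for a in r.atoms]
    return _AtomGroup(pairs)


def mutate_and_pack(model: StructureModel, spec: MutationSpec,
                    lib: RotamerLibrary | None = None,
                    mode: PackingProtocol | PackingMode = PackingMode.NOMIN,
                    weights: ScoreWeights = ZAFFI_1_1,
                    parameter_table: dict | None = None,
                    defn: InterfaceDefinition = DEFAULT_DEFN) -> StructureModel:
    """Build a point-mutant structure by exhaustive rotamer enumeration.

    The mutated side chain is rebuilt at every (expanded) rotamer and scored
    against the fixed environment; the lowest-energy conformation is kept
    (ties resolve to the lowest library index). In NOMIN mode the backbone
    and all other side chains are untouched; MIN modes follow packing with
    torsion-space minimization of the interface.
    """
    protocol = (mode if isinstance(mode, PackingProtocol)
                else PackingProtocol(mode=mode))
    lib = lib or default_rotamer_library()
    table = parameter_table or load_parameter_table()

    cid = chain_of_role(model, spec.chain_role)
    mutant = model.copy()
    try:
        res = mutant.find_residue(cid, spec.position)
    except StructureError:
        raise StructureError(
            f"no residue {spec.position} on chain {cid} "
            f"({spec.chain_role.value})") from None
    observed = AA3_TO_1.get(res.aa, "?")
    if observed != spec.wt_aa:
        raise StructureError(
            f"wild-type mismatch at {cid}{spec.position}: spec says "
            f"{spec.wt_aa}, structure has {observed} ({res.aa})")

    aa3 = AA1_TO_3[spec.mut_aa]
    env = environment_group(mutant, res, protocol.include_waters)
    best = None
    for idx, chis in enumerate(lib.expanded_rotamers(aa3)):
        _build_rotamer(res, aa3, chis, table)
        e = packing_energy(mutant, res, weights,
                           protocol.include_waters, _env_group=env)
        if best is None or e < best[0] - 1e-12:
            best = (e, idx, chis)
    _build_rotamer(res, aa3, best[2], table)
    mutant.repacked.add(res.key)

    if protocol.mode is not PackingMode.NOMIN:
        mutant = minimize_interface(mutant, defn, protocol, weights)
    return mutant


# ---------------------------------------------------------------------------
# Torsion-space minimization
# ---------------------------------------------------------------------------

def minimize_torsions(x0: np.ndarray, energy_fn, tol: float = 1e-4,
                      max_iter: int = 500) -> tuple[np.ndarray, float, bool]:
    """Quasi-Newton minimization of an energy over torsion angles (degrees).

    Returns (x, energy, converged). Falls back to the best iterate if the
    optimizer does not converge.
    """
    res = _sp_minimize(energy_fn, np.asarray(x0, dtype=float),
                       method="L-BFGS-B",
                       options={"ftol": tol * 1e-3, "gtol": 1e-8,
                                "maxiter": max_iter})
    if not res.success:
        logger.warning("torsion minimization did not converge: %s", res.message)
    return res.x, float(res.fun), bool(res.success)


def _sidechain_chis(res: Residue) -> list[float]:
    quads = CHI_ATOMS.get(res.aa, [])
    pos = {a.name: a.position for a in res.atoms}
    out = []
    for q in quads:
        if all(x in pos for x in q):
            out.append(dihedral_angle(*(pos[x] for x in q)))
        else:
            return []
    return out


def _rotate_downstream(chain: list[Residue], i: int, axis_a: np.ndarray,
                       axis_b: np.ndarray, delta_deg: float,
                       include_self_from: str) -> None:
    """Rotate atoms downstream of a backbone torsion axis by delta degrees."""
    from scipy.spatial.transform import Rotation
    ax = axis_b - axis_a
    ax /= np.linalg.norm(ax)
    rot = Rotation.from_rotvec(np.deg2rad(delta_deg) * ax)

    def _apply(atom):
        atom.position = rot.apply(atom.position - axis_a) + axis_a

    res = chain[i]
    started = False
    for a in res.atoms:
        if a.name == include_self_from:
            started = True
        if started and a.name in ("C", "O", "OXT"):
            _apply(a)
    if include_self_from == "N":   # phi moves the side chain too
        for a in res.atoms:
            if a.name not in ("N", "CA", "H"):
                _apply(a)
    for r in chain[i + 1:]:
        for a in r.atoms:
            _apply(a)


def minimize_interface(model: StructureModel,
                       defn: InterfaceDefinition = DEFAULT_DEFN,
                       mode: PackingProtocol | PackingMode = PackingMode.MIN,
                       weights: ScoreWeights = ZAFFI_1_1,
                       tol: float = 1e-4, max_iter: int = 500) -> StructureModel:
    """Local torsion-space minimization restricted to interface residues.

    MIN_SC moves side-chain chi angles, MIN_BB backbone phi/psi, MIN both.
    The final structure never scores worse than the input (the input is
    returned if the optimizer fails to improve it).
    """
    protocol = (mode if isinstance(mode, PackingProtocol)
                else PackingProtocol(mode=mode))
    if protocol.mode is PackingMode.NOMIN:
        return model
    do_sc = protocol.mode in (PackingMode.MIN_SC, PackingMode.MIN)
    do_bb = protocol.mode in (PackingMode.MIN_BB, PackingMode.MIN)

    iface = interface_residues(model, defn)
    pmhc_near = [r for r in model.side_residues(PMHC_SIDE)
                 if any(np.linalg.norm(a.position - b.position) <= defn.cutoff_interface
                        for rr in iface for b in rr.heavy_atoms()
                        for a in r.heavy_atoms())]
    moving = list(iface) + pmhc_near
    keys = {r.key for r in moving} | set(model.repacked)

    # degrees of freedom
    dofs: list[tuple] = []
    x0: list[float] = []
    for r in moving:
        if do_sc and CHI_ATOMS.get(r.aa):
            chis = _sidechain_chis(r)
            if chis:
                dofs.append(("sc", r.key))
                x0.extend(chis)
        if do_bb:
            phi, psi = model.phi_psi(r)
            if phi is not None:
                dofs.append(("phi", r.key))
                x0.append(phi)
            if psi is not None:
                dofs.append(("psi", r.key))
                x0.append(psi)
    if not x0:
        return model

    table = load_parameter_table()
    base = model.copy()

    def _apply(x: np.ndarray) -> StructureModel:
        m = base.copy()
        k = 0
        for kind, key in dofs:
            r = m.find_residue(*key)
            if kind == "sc":
                nchi = len(CHI_ATOMS[r.aa])
                chis = tuple(x[k:k + nchi])
                k += nchi
                _build_rotamer(r, r.aa, chis, table)
            else:
                chain = m.chains[r.chain_id]
                i = chain.index(r)
                phi, psi = m.phi_psi(r)
                if kind == "phi":
                    delta = x[k] - phi
                    _rotate_downstream(chain, i, r.atom("N").position,
                                       r.atom("CA").position, delta, "C")
                else:
                    delta = x[k] - psi
                    _rotate_downstream(chain, i, r.atom("CA").position,
                                       r.atom("C").position, delta, "ZZZ")
                k += 1
        return m

    def _energy(x: np.ndarray) -> float:
        m = _apply(x)
        return score(m, weights, defn, intra_residues=keys,
                     include_waters=protocol.include_waters)

    e0 = _energy(np.array(x0))
    x, e, _ = minimize_torsions(np.array(x0), _energy, tol=tol,
                                max_iter=max_iter)
    if e > e0:
        return model
    out = _apply(x)
    out.repacked = set(model.repacked)
    return out


# ---------------------------------------------------------------------------
# Side-chain RMSD against a reference structure
# ---------------------------------------------------------------------------

#: Chemically equivalent atom-name swaps for symmetric side chains.
SYMMETRY_SWAPS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "ARG": [("NH1", "NH2")],
}


def sidechain_rmsd(model_pred: StructureModel, model_xtal: StructureModel,
                   spec: MutationSpec,
                   defn: InterfaceDefinition = DEFAULT_DEFN) -> float:
    """RMSD of the mutated residue's side-chain heavy atoms after fitting the
    interface backbone of the prediction onto the reference structure.

    Symmetry-equivalent naming (e.g. aromatic ring flips) is resolved by
    taking the lower-RMSD assignment.
    """
    from .geometry import backbone_interface_selection, superpose_and_rmsd

    sel = backbone_interface_selection(model_xtal, defn)
    fit = superpose_and_rmsd(model_xtal, model_pred, selection=sel)
    rot, trans = fit["rotation"], fit["translation"]

    cid_p = chain_of_role(model_pred, spec.chain_role)
    cid_x = chain_of_role(model_xtal, spec.chain_role)
    res_p = model_pred.find_residue(cid_p, spec.position)
    res_x = model_xtal.find_residue(cid_x, spec.position)
    names = [a.name for a in res_x.sidechain_heavy_atoms()]
    if sorted(names) != sorted(a.name for a in res_p.sidechain_heavy_atoms()):
        raise StructureError(
            f"side-chain atom mismatch at {spec}: "
            f"{sorted(names)} vs "
            f"{sorted(a.name for a in res_p.sidechain_heavy_atoms())}")

    xpos = {a.name: a.position for a in res_x.sidechain_heavy_atoms()}
    ppos = {a.name: rot @ a.position + trans
            for a in res_p.sidechain_heavy_atoms()}

    swaps = SYMMETRY_SWAPS.get(res_x.aa, [])
    best = None
    for flip in ([False, True] if swaps else [False]):
        mapping = {n: n for n in names}
        if flip:
            for a, b in swaps:
                mapping[a], mapping[b] = b, a
        sq = [np.sum((xpos[n] - ppos[mapping[n]]) ** 2) for n in names]
        rmsd = float(np.sqrt(np.mean(sq)))
        best = rmsd if best is None else min(best, rmsd)
    return best
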