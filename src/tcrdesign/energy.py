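"""Six-term interface energy function and weighted linear binding score.

The score is a dot product of six physically motivated interface terms with
a weight vector; the shipped default weights are the retrained ZAFFI 1.1
values. Predicted binding ddG of a mutant is score(mutant) - score(wild
type); negative means predicted improved binding.

Functional forms (reference; version 1 of this term set)
--------------------------------------------------------
* Lennard-Jones 6-12 on cross-interface atom pairs, rmin_ij = r_i + r_j,
  eps_ij = sqrt(eps_i eps_j), split into an attractive part (clamped at
  -eps inside rmin) and a repulsive part (E + eps inside rmin, continued
  linearly below 0.6 rmin to avoid the singularity).
* Gaussian-exclusion implicit solvation (Lazaridis-Karplus form): each heavy
  atom j excludes solvent from atom i with a Gaussian of correlation length
  lambda_i; desolvating polar atoms is penalized, burying hydrophobic atoms
  rewarded.
* Hydrogen bonding: donor-H ... acceptor pairs, Gaussian in the H...A
  distance (optimum 1.9 A, width 0.3 A) times the squared D-H...A
  collinearity; always <= 0.
* Long-range Coulomb electrostatics with distance-dependent dielectric
  eps(r) = 4r, evaluated only for charged-atom pairs at r >= 5.0 A.
* Intra-residue repulsion: the LJ repulsive part summed over within-residue
  atom pairs three or more bonds apart, for repacked residues only.
* All pairwise sums are truncated at 8.0 A with a smoothstep switching
  function over 7.0-8.0 A.

Score units are arbitrary; only the calibrated mapping to kcal/mol (via
regression, or the -0.6 score <-> -0.25 kcal/mol anchor) carries
thermodynamic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    PMHC_SIDE,
    TCR_SIDE,
    Residue,
    StructureModel,
    StructureError,
)

CUTOFF = 8.0
SWITCH_START = 7.0
ELEC_MIN_DIST = 5.0
DIELECTRIC_SLOPE = 4.0          # eps(r) = 4 r
COULOMB_CONST = 332.0637        # kcal mol^-1 A e^-2
REP_LINEAR_FRACTION = 0.6       # linear continuation below 0.6 rmin
HBOND_STRENGTH = 2.0            # kcal/mol at ideal geometry
HBOND_R0 = 1.9
HBOND_SIGMA = 0.3
HBOND_MAX_DIST = 3.5
IMPROVEMENT_CUTOFF = -0.6       # score units; ~ -0.25 kcal/mol


@dataclass(frozen=True)
class EnergyBreakdown:
    """The six per-interface energy terms consumed by the weighted score."""
    vdw_attr: float
    vdw_rep: float
    solvation: float
    hbond: float
    intra_rep: float
    electrostatics: float

    def as_array(self) -> np.ndarray:
        return np.array([self.vdw_attr, self.vdw_rep, self.solvation,
                         self.hbond, self.intra_rep, self.electrostatics])

    TERM_NAMES = ("vdw_attr", "vdw_rep", "solvation", "hbond",
                  "intra_rep", "electrostatics")


@dataclass(frozen=True)
class ScoreWeights:
    """Linear weights applied to an EnergyBreakdown (dimensionless)."""
    w_vdw_attr: float
    w_vdw_rep: float
    w_solvation: float
    w_hbond: float
    w_intra_rep: float
    w_elec: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w_vdw_attr, self.w_vdw_rep, self.w_solvation,
                         self.w_hbond, self.w_intra_rep, self.w_elec])

    @classmethod
    def from_array(cls, w) -> "ScoreWeights":
        return cls(*(float(x) for x in np.asarray(w)))


#: Retrained six-term weight vector (van der Waals attractive, repulsive,
#: solvation, hydrogen bonding, intra-residue repulsion, electrostatics).
ZAFFI_1_1 = ScoreWeights(0.57, 0.0045, 0.58, 1.2, 0.026, 0.03)


def switch(r: np.ndarray) -> np.ndarray:
    """Smoothstep truncation factor: 1 below 7 A, 0 above 8 A."""
    r = np.asarray(r, dtype=float)
    t = np.clip((CUTOFF - r) / (CUTOFF - SWITCH_START), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def lj_split(r, rmin, eps):
    """(attractive, repulsive) parts of the 6-12 potential, before switching."""
    r = np.asarray(r, dtype=float)
    rmin = np.asarray(rmin, dtype=float)
    eps = np.asarray(eps, dtype=float)
    r0 = REP_LINEAR_FRACTION * rmin
    rs = np.maximum(r, r0)
    x = rmin / rs
    e = eps * (x ** 12 - 2.0 * x ** 6)
    attr = np.where(r >= rmin, e, -eps)
    rep = np.where(r >= rmin, 0.0, e + eps)
    # linear continuation below 0.6 rmin with the slope at 0.6 rmin
    slope = eps * 12.0 * (x ** 12 - x ** 6) / rs      # -dE/dr at rs
    rep = rep + np.where(r < r0, slope * (r0 - r), 0.0)
    return attr, rep


class _AtomGroup:
    """Flat arrays over a set of atoms for vectorized pair sums."""

    def __init__(self, pairs: list[tuple[Residue, "object"]],
                 require_params: bool = True):
        self.res = [r for r, _ in pairs]
        self.atoms = [a for _, a in pairs]
        n = len(self.atoms)
        self.pos = np.array([a.position for a in self.atoms]).reshape(n, 3)
        self.rmin = np.array([a.lj_radius or 0.0 for a in self.atoms])
        self.eps = np.array([a.lj_well_depth or 0.0 for a in self.atoms])
        self.q = np.array([a.charge or 0.0 for a in self.atoms])
        self.dg = np.array([a.dg_free or 0.0 for a in self.atoms])
        self.lam = np.array([a.lam or 3.5 for a in self.atoms])
        self.vol = np.array([a.volume or 0.0 for a in self.atoms])
        self.heavy = np.array([not a.is_hydrogen for a in self.atoms])
        if require_params and n and \
                any(not a.parameterized for a in self.atoms if not a.is_hydrogen):
            bad = next(a for a in self.atoms
                       if not a.is_hydrogen and not a.parameterized)
            raise StructureError(f"unparameterized atom {bad.name}")
        # hydrogen-bond roles
        self.donor_h = np.zeros(n, dtype=bool)
        self.donor_heavy_idx = np.full(n, -1, dtype=int)
        self.acceptor = np.zeros(n, dtype=bool)
        self._annotate_hbond_roles()

    def _annotate_hbond_roles(self) -> None:
        n = len(self.atoms)
        if n == 0:
            return
        tree = cKDTree(self.pos)
        neighbor_lists = tree.query_ball_tree(tree, 1.85)
        for i, a in enumerate(self.atoms):
            nbrs = [j for j in neighbor_lists[i] if j != i]
            if a.is_hydrogen:
                cands = [j for j in nbrs
                         if self.atoms[j].element in ("N", "O", "S")
                         and np.linalg.norm(self.pos[j] - self.pos[i]) < 1.3]
                if cands:
                    j = min(cands, key=lambda j: float(
                        np.linalg.norm(self.pos[j] - self.pos[i])))
                    self.donor_h[i] = True
                    self.donor_heavy_idx[i] = j
            elif a.element == "O":
                self.acceptor[i] = True
            elif a.element == "N":
                has_h = any(self.atoms[j].is_hydrogen and np.linalg.norm(
                    self.pos[j] - self.pos[i]) < 1.15 for j in nbrs)
                heavy_deg = sum(1 for j in nbrs if not self.atoms[j].is_hydrogen)
                if not has_h and heavy_deg <= 2:
                    self.acceptor[i] = True


def _interface_groups(model: StructureModel,
                      include_waters: bool = True) -> tuple[_AtomGroup, _AtomGroup]:
    tcr = [(r, a) for r in model.side_residues(TCR_SIDE) for a in r.atoms]
    pmhc = [(r, a) for r in model.side_residues(PMHC_SIDE) for a in r.atoms]
    if include_waters:
        pmhc += [(r, a) for r in model.waters for a in r.atoms]
    if not tcr or not pmhc:
        raise StructureError("interface scoring needs a TCR side and a pMHC side")
    return _AtomGroup(tcr), _AtomGroup(pmhc)


def _cross_terms(ga: _AtomGroup, gb: _AtomGroup) -> dict[str, float]:
    d = np.linalg.norm(ga.pos[:, None, :] - gb.pos[None, :, :], axis=-1)
    sw = switch(d)
    within = d < CUTOFF

    rmin = ga.rmin[:, None] + gb.rmin[None, :]
    eps = np.sqrt(ga.eps[:, None] * gb.eps[None, :])
    attr, rep = lj_split(d, rmin, eps)
    attr = float(np.sum(attr * sw, where=within))
    rep = float(np.sum(rep * sw, where=within))

    # solvation: heavy-heavy only
    hh = ga.heavy[:, None] & gb.heavy[None, :] & within
    with np.errstate(divide="ignore", invalid="ignore"):
        da = (d - ga.rmin[:, None]) / ga.lam[:, None]
        db = (d - gb.rmin[None, :]) / gb.lam[None, :]
        pref = 1.0 / (2.0 * np.pi ** 1.5 * np.maximum(d, 1e-6) ** 2)
        fa = ga.dg[:, None] / ga.lam[:, None] * np.exp(-da ** 2) * pref
        fb = gb.dg[None, :] / gb.lam[None, :] * np.exp(-db ** 2) * pref
        solv = -np.sum((fa * gb.vol[None, :] + fb * ga.vol[:, None]) * sw,
                       where=hh)
    solv = float(solv)

    hb = _hbond_energy(ga, gb, d) + _hbond_energy(gb, ga, d.T)

    qq = ga.q[:, None] * gb.q[None, :]
    emask = within & (d >= ELEC_MIN_DIST) & (np.abs(qq) > 1e-12)
    with np.errstate(divide="ignore"):
        elec = np.where(emask,
                        COULOMB_CONST * qq /
                        (DIELECTRIC_SLOPE * np.maximum(d, 1e-6) ** 2) * sw,
                        0.0)
    elec = float(elec.sum())
    return {"vdw_attr": attr, "vdw_rep": rep, "solvation": solv,
            "hbond": hb, "electrostatics": elec}


def _hbond_energy(gdon: _AtomGroup, gacc: _AtomGroup, d: np.ndarray) -> float:
    """Donor hydrogens in gdon paired with acceptors in gacc."""
    hi = np.flatnonzero(gdon.donor_h)
    ai = np.flatnonzero(gacc.acceptor)
    if hi.size == 0 or ai.size == 0:
        return 0.0
    total = 0.0
    for i in hi:
        dv = gdon.pos[gdon.donor_heavy_idx[i]]
        hv = gdon.pos[i]
        u1 = hv - dv
        u1 /= np.linalg.norm(u1)
        dha = d[i, ai]
        ok = dha <= HBOND_MAX_DIST
        if not ok.any():
            continue
        av = gacc.pos[ai[ok]]
        u2 = av - hv
        u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
        cosang = u2 @ u1
        f_ang = np.where(cosang > 0.0, cosang ** 2, 0.0)
        f_dist = np.exp(-((dha[ok] - HBOND_R0) ** 2) / (2.0 * HBOND_SIGMA ** 2))
        total += float(np.sum(-HBOND_STRENGTH * f_dist * f_ang))
    return total


def _residue_bond_graph(res: Residue) -> dict[int, set[int]]:
    pos = np.array([a.position for a in res.atoms])
    n = len(res.atoms)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    if n < 2:
        return adj
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            lim = 1.85 if not (res.atoms[i].is_hydrogen or
                               res.atoms[j].is_hydrogen) else 1.25
            if d[i, j] < lim:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def intra_residue_repulsion(res: Residue) -> float:
    """LJ repulsion over within-residue pairs >= 3 bonds apart."""
    adj = _residue_bond_graph(res)
    n = len(res.atoms)
    total = 0.0
    for i in range(n):
        # BFS graph distances from i
        dist = {i: 0}
        frontier = [i]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for j in range(i + 1, n):
            if dist.get(j, 99) < 3:
                continue
            ai, aj = res.atoms[i], res.atoms[j]
            if not (ai.parameterized and aj.parameterized):
                continue
            r = float(np.linalg.norm(ai.position - aj.position))
            if r >= CUTOFF:
                continue
            _, rep = lj_split(r, ai.lj_radius + aj.lj_radius,
                              np.sqrt(ai.lj_well_depth * aj.lj_well_depth))
            total += float(rep) * float(switch(r))
    return total


def energy_terms(model: StructureModel, defn=None,
                 intra_residues: set[tuple[str, int, str]] | None = None,
                 include_waters: bool = True) -> EnergyBreakdown:
    """Compute the six interface energy terms for a parameterized model.

    Cross-interface terms sum over TCR-side vs pMHC-side atom pairs (waters
    count as fixed environment on the pMHC side). The intra-residue
    repulsion sums over the residues in ``intra_residues`` (defaults to the
    model's repacked set).
    """
    ga, gb = _interface_groups(model, include_waters=include_waters)
    terms = _cross_terms(ga, gb)
    keys = intra_residues if intra_residues is not None else model.repacked
    intra = 0.0
    for key in sorted(keys):
        res = model.find_residue(*key)
        intra += intra_residue_repulsion(res)
    return EnergyBreakdown(vdw_attr=terms["vdw_attr"], vdw_rep=terms["vdw_rep"],
                           solvation=terms["solvation"], hbond=terms["hbond"],
                           intra_rep=intra,
                           electrostatics=terms["electrostatics"])


def score(model: StructureModel, weights: ScoreWeights = ZAFFI_1_1,
          defn=None, **kwargs) -> float:
    """Weighted linear score: dot(weights, energy terms)."""
    bd = energy_terms(model, defn, **kwargs)
    return float(weights.as_array() @ bd.as_array())


def score_breakdown(bd: EnergyBreakdown,
                    weights: ScoreWeights = ZAFFI_1_1) -> float:
    return float(weights.as_array() @ bd.as_array())


def predict_ddg(wt: StructureModel, mutant: StructureModel,
                weights: ScoreWeights = ZAFFI_1_1, defn=None,
                include_waters: bool = True) -> float:
    """Predicted binding ddG = score(mutant) - score(wild type).

    Intra-residue repulsion is evaluated over the union of the two models'
    repacked residues in both structures, so the difference is well defined.
    """
    for m in (wt, mutant):
        if sorted(wt.chains) != sorted(mutant.chains):
            raise StructureError("models have different chain topology")
    for cid in wt.chains:
        if len(wt.chains[cid]) != len(mutant.chains[cid]):
            raise StructureError(f"chain {cid} lengths differ")
    keys = wt.repacked | mutant.repacked
    s_wt = score(wt, weights, defn, intra_residues=keys,
                 include_waters=include_waters)
    s_mut = score(mutant, weights, defn, intra_residues=keys,
                  include_waters=include_waters)
    return s_mut - s_wt


def classify_improvement(score_ddg: float,
                         cutoff: float = IMPROVEMENT_CUTOFF) -> bool:
    """True iff the predicted score meets the improvement cutoff (<= -0.6)."""
    if not np.isfinite(score_ddg):
        raise ValueError("score must be finite")
    return bool(score_ddg <= cutoff)
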