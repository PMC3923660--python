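"""Design pipelines: saturation mutagenesis over the interface, differential
(specificity) scans between two peptide ligands, Ramachandran-based proline
candidate selection, and the high-clash filter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .energy import ZAFFI_1_1, EnergyBreakdown, ScoreWeights, energy_terms, \
    intra_residue_repulsion
from .geometry import InterfaceDefinition, interface_residues, residue_contacts
from .packing import (
    MutationSpec,
    PackingMode,
    PackingProtocol,
    RotamerLibrary,
    chain_of_role,
    default_rotamer_library,
    mutate_and_pack,
)
from .structure import Role, StructureError, StructureModel, TCR_SIDE
from .templates import AA1_TO_3, AA3_TO_1

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: High-clash threshold on the van der Waals repulsive term (score units).
CLASH_THRESHOLD = 580.0


@dataclass(frozen=True)
class ScanConfig:
    interface_cutoff: float = 5.5
    modes: tuple[PackingMode, ...] = (PackingMode.NOMIN,)
    weights: ScoreWeights = ZAFFI_1_1
    rep_clash_threshold: float = CLASH_THRESHOLD
    improvement_cutoff: float = -0.6
    include_waters: bool = False
    library: RotamerLibrary | None = None

    def defn(self) -> InterfaceDefinition:
        return InterfaceDefinition(cutoff_interface=self.interface_cutoff)


@dataclass(frozen=True)
class ScanRecord:
    mutation: MutationSpec
    ligand: str
    mode: PackingMode
    score: float                    # predicted ddG, score units
    breakdown: EnergyBreakdown      # per-term mutant-minus-wild-type deltas
    contacts: tuple[str, ...]       # peptide residues near the mutant side chain
    categories: tuple[str, ...] = ()


@dataclass
class ScanResult:
    records: list[ScanRecord] = field(default_factory=list)

    def ranked(self) -> list[ScanRecord]:
        return sorted(self.records, key=lambda r: (r.score, str(r.mutation)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ranked():
            row = {
                "mutation": str(r.mutation), "ligand": r.ligand,
                "mode": r.mode.value, "score": r.score,
                "contacts": ";".join(r.contacts),
                "categories": ";".join(r.categories),
            }
            row.update(zip(EnergyBreakdown.TERM_NAMES, r.breakdown.as_array()))
            rows.append(row)
        return pd.DataFrame(rows)


def _wt_reference(model: StructureModel, defn, include_waters: bool):
    """Interface terms of the wild type without any intra contribution."""
    return energy_terms(model, defn, intra_residues=set(),
                        include_waters=include_waters)


def _record_for(model, wt_terms, spec: MutationSpec, mode: PackingMode,
                config: ScanConfig, ligand: str,
                categories: tuple[str, ...] = ()) -> ScanRecord:
    defn = config.defn()
    mutant = mutate_and_pack(
        model, spec, lib=config.library or default_rotamer_library(),
        mode=PackingProtocol(mode=mode, include_waters=config.include_waters),
        weights=config.weights, defn=defn)
    cid = chain_of_role(model, spec.chain_role)
    wt_res = model.find_residue(cid, spec.position)
    wt_intra = intra_residue_repulsion(wt_res)
    mut_terms = energy_terms(mutant, defn, intra_residues=mutant.repacked,
                             include_waters=config.include_waters)
    delta = mut_terms.as_array() - wt_terms.as_array()
    delta[4] -= wt_intra            # intra term relative to the wt residue
    bd = EnergyBreakdown(*delta)
    ddg = float(config.weights.as_array() @ delta)
    mut_res = mutant.find_residue(cid, spec.position)
    contacts = tuple(f"{AA3_TO_1.get(r.aa, 'X')}{r.seq}"
                     for r in residue_contacts(mutant, mut_res, defn))
    return ScanRecord(mutation=spec, ligand=ligand, mode=mode, score=ddg,
                      breakdown=bd, contacts=contacts, categories=categories)


def saturation_scan(model: StructureModel, config: ScanConfig = ScanConfig(),
                    ligand: str = "LIG",
                    extra_mutations: list[MutationSpec] | None = None) -> ScanResult:
    """All 19 non-identity substitutions at every TCR interface residue.

    Records are ranked by predicted score (ascending = best first). Manually
    chosen mutations can be appended via ``extra_mutations`` (tagged TEST).
    """
    defn = config.defn()
    iface = [r for r in interface_residues(model, defn)
             if model.roles.get(r.chain_id) in TCR_SIDE and r.aa in AA3_TO_1]
    wt_terms = _wt_reference(model, defn, config.include_waters)
    result = ScanResult()
    for res in iface:
        wt1 = AA3_TO_1[res.aa]
        role = model.roles[res.chain_id]
        for aa in AA_ALPHABET:
            if aa == wt1:
                continue
            spec = MutationSpec(role, res.seq, wt1, aa)
            for mode in config.modes:
                cats = ("PROLINE",) if aa == "P" else ("AFFINITY",)
                result.records.append(_record_for(
                    model, wt_terms, spec, mode, config, ligand, cats))
    for spec in extra_mutations or []:
        for mode in config.modes:
            result.records.append(_record_for(
                model, wt_terms, spec, mode, config, ligand, ("TEST",)))
    return result


def _tcr_sequence(model: StructureModel) -> dict[Role, tuple]:
    out = {}
    for role in (Role.TCR_ALPHA, Role.TCR_BETA):
        try:
            cid = chain_of_role(model, role)
        except StructureError:
            continue
        out[role] = tuple((r.seq, r.aa) for r in model.chains[cid])
    return out


def specificity_scan(model_lig_a: StructureModel, model_lig_b: StructureModel,
                     config: ScanConfig = ScanConfig(),
                     ligand_a: str = "A", ligand_b: str = "B") -> pd.DataFrame:
    """Differential scan between two ligand complexes sharing one TCR.

    For every substitution at the union of the two interfaces the predicted
    ddG toward each ligand is computed; differential = ddG(A) - ddG(B), so
    negative favors ligand A. Mutations predicted to clash (repulsive delta
    above the threshold) in exactly one complex are flagged.
    """
    if _tcr_sequence(model_lig_a) != _tcr_sequence(model_lig_b):
        raise StructureError("the two complexes have different TCR sequences")
    defn = config.defn()
    keys = set()
    for m in (model_lig_a, model_lig_b):
        for r in interface_residues(m, defn):
            if m.roles.get(r.chain_id) in TCR_SIDE and r.aa in AA3_TO_1:
                keys.add((m.roles[r.chain_id], r.seq, AA3_TO_1[r.aa]))
    wt_a = _wt_reference(model_lig_a, defn, config.include_waters)
    wt_b = _wt_reference(model_lig_b, defn, config.include_waters)
    rows = []
    for role, seq, wt1 in sorted(keys, key=lambda k: (k[0].value, k[1])):
        for aa in AA_ALPHABET:
            if aa == wt1:
                continue
            spec = MutationSpec(role, seq, wt1, aa)
            for mode in config.modes:
                ra = _record_for(model_lig_a, wt_a, spec, mode, config, ligand_a)
                rb = _record_for(model_lig_b, wt_b, spec, mode, config, ligand_b)
                clash_a = ra.breakdown.vdw_rep > config.rep_clash_threshold
                clash_b = rb.breakdown.vdw_rep > config.rep_clash_threshold
                rows.append({
                    "mutation": str(spec), "mode": mode.value,
                    f"ddg_{ligand_a}": ra.score, f"ddg_{ligand_b}": rb.score,
                    "differential": ra.score - rb.score,
                    "clash_one_sided": clash_a != clash_b,
                })
    return pd.DataFrame(rows).sort_values(
        "differential", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Proline candidates
# ---------------------------------------------------------------------------

def load_rama_regions(path: str | Path | None = None) -> dict[str, list[Polygon]]:
    """Favorable (phi, psi) regions for proline and pre-proline positions,
    shipped as editable polygon boundaries."""
    if path is None:
        text = resources.files("tcrdesign.data").joinpath(
            "rama_regions.csv").read_text()
    else:
        text = Path(path).read_text()
    verts: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in csv.DictReader(text.splitlines()):
        verts.setdefault((row["region"], row["polygon"]), []).append(
            (float(row["phi"]), float(row["psi"])))
    out: dict[str, list[Polygon]] = {}
    for (region, _), pts in verts.items():
        out.setdefault(region, []).append(Polygon(pts))
    return out


def in_region(regions: dict[str, list[Polygon]], region: str,
              phi: float, psi: float) -> bool:
    p = Point(phi, psi)
    return any(prep(poly).intersects(p) for poly in regions[region])


def proline_candidates(bound: StructureModel, scan: ScanResult,
                       regions: dict[str, list[Polygon]] | None = None
                       ) -> list[tuple[str, int]]:
    """Positions suitable for proline substitution.

    A position qualifies when its backbone (phi, psi) falls in the
    proline-favorable region, the preceding residue falls in the
    pre-proline-favorable region, and the scanned proline mutant has
    predicted ddG <= 0 in at least one packing mode. Chain termini with
    undefined dihedrals are skipped.
    """
    regions = regions or load_rama_regions()
    pro_ok: dict[tuple[str, int], bool] = {}
    for rec in scan.records:
        if rec.mutation.mut_aa != "P":
            continue
        cid = chain_of_role(bound, rec.mutation.chain_role)
        key = (cid, rec.mutation.position)
        pro_ok[key] = pro_ok.get(key, False) or rec.score <= 0.0

    out = []
    for (cid, seq), favorable in sorted(pro_ok.items()):
        if not favorable:
            continue
        chain = bound.chains[cid]
        res = bound.find_residue(cid, seq)
        i = chain.index(res)
        phi, psi = bound.phi_psi(res)
        if phi is None or psi is None or i == 0:
            logger.info("skipping terminus %s%s for proline selection", cid, seq)
            continue
        prev = chain[i - 1]
        pphi, ppsi = bound.phi_psi(prev)
        if pphi is None or ppsi is None:
            logger.info("skipping %s%s: preceding residue at terminus", cid, seq)
            continue
        if in_region(regions, "proline_favorable", phi, psi) and \
                in_region(regions, "preproline_favorable", pphi, ppsi):
            out.append((cid, seq))
    return out


# ---------------------------------------------------------------------------
# Clash filter
# ---------------------------------------------------------------------------

def clash_filter(results: ScanResult, config: ScanConfig = ScanConfig()
                 ) -> tuple[ScanResult, ScanResult]:
    """Partition scan records into (kept, removed) by the high-clash rule:
    removed iff the van der Waals repulsive term exceeds the threshold
    (strictly)."""
    kept, removed = [], []
    for r in results.records:
        (removed if r.breakdown.vdw_rep > config.rep_clash_threshold
         else kept).append(r)
    return ScanResult(kept), ScanResult(removed)
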