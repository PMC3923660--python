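"""Thermodynamic arithmetic linking measured dissociation constants to
binding free-energy changes, fold improvements, specificity shifts, and
double-mutant coupling energies.

ddG = RT ln(KD_mut / KD_wt); negative means improved binding. Fold change
is the improvement in the association constant, KD_wt / KD_mut. Displayed
values round to two significant figures to match conventional reporting;
raw values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

GAS_CONSTANT = 1.9872e-3       # kcal / (mol K)
STANDARD_TEMPERATURE = 298.15  # K (25 C)

NO_BINDING = "NB"


@dataclass(frozen=True)
class AffinityRecord:
    mutant: str
    ligand: str
    kd_um: float | None            # None = no detectable binding
    kd_error_um: float | None = None
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self):
        if self.kd_um is not None and self.kd_um <= 0:
            raise ValueError("KD must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def rt(temperature: float = STANDARD_TEMPERATURE) -> float:
    """RT in kcal/mol (0.5925 at 298.15 K)."""
    return GAS_CONSTANT * temperature


def ddg_from_kd(kd_wt: float, kd_mut: float,
                temperature: float = STANDARD_TEMPERATURE) -> float:
    """Binding free-energy change RT ln(KD_mut/KD_wt), kcal/mol."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    return rt(temperature) * math.log(kd_mut / kd_wt)


def fold_change(kd_wt: float, kd_mut: float) -> float:
    """Improvement in association constant relative to wild type:
    KD_wt / KD_mut (> 1 means tighter binding)."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_wt / kd_mut


def spec_change(kd_wt_a: float, kd_mut_a: float,
                kd_wt_b: float, kd_mut_b: float) -> float:
    """Specificity shift toward ligand B relative to ligand A:
    fold_change(B) / fold_change(A); > 1 means a shift toward B."""
    return fold_change(kd_wt_b, kd_mut_b) / fold_change(kd_wt_a, kd_mut_a)


def coupling_energy(ddg_double: float, ddg_single1: float,
                    ddg_single2: float) -> float:
    """Double-mutant coupling: ddG(double) - [ddG(1) + ddG(2)], kcal/mol.
    Negative = cooperative (more favorable than additive)."""
    return ddg_double - (ddg_single1 + ddg_single2)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_sig(x: float, sig: int = 2) -> str:
    """Two-significant-figure display string (e.g. 395.8 -> '400')."""
    r = round_sig(x, sig)
    if r == int(r) and abs(r) >= 1:
        return str(int(r))
    return f"{r:g}"


def derive_affinity_table(df: pd.DataFrame, wt_id: str = "wild-type",
                          ligand_ref: str | None = None,
                          temperature: float = STANDARD_TEMPERATURE
                          ) -> pd.DataFrame:
    """Add ddG / fold-change / specificity-change columns to a long-format
    affinity table with columns (mutant, ligand, kd_um; 'NB' allowed).

    ``ligand_ref`` names the reference ligand for the specificity change
    (defaults to the first ligand in the table); the specificity change of a
    mutant is fold_change(other ligand) / fold_change(reference).
    """
    df = df.copy()
    df["kd_um"] = df["kd_um"].apply(
        lambda v: None if (isinstance(v, str) and v.strip().upper() == NO_BINDING)
        else float(v))
    ligands = list(dict.fromkeys(df["ligand"]))
    ligand_ref = ligand_ref or ligands[0]
    wt_kd = {row["ligand"]: row["kd_um"]
             for _, row in df[df["mutant"] == wt_id].iterrows()}
    ddgs, folds = [], []
    for _, row in df.iterrows():
        kd = row["kd_um"]
        if kd is None or row["mutant"] == wt_id:
            ddgs.append(None)
            folds.append(None)
        else:
            ddgs.append(ddg_from_kd(wt_kd[row["ligand"]], kd, temperature))
            folds.append(fold_change(wt_kd[row["ligand"]], kd))
    df["ddg_kcal"] = ddgs
    df["fold_change"] = folds

    spec = {}
    for mut in df["mutant"].unique():
        if mut == wt_id:
            continue
        sub = df[df["mutant"] == mut].set_index("ligand")["fold_change"]
        others = [l for l in ligands if l != ligand_ref and l in sub.index]
        if ligand_ref in sub.index and others and \
                sub[ligand_ref] is not None and sub[others[0]] is not None:
            spec[mut] = sub[others[0]] / sub[ligand_ref]
    df["spec_change"] = df["mutant"].map(spec)
    df.loc[df["ligand"] != ligand_ref, "spec_change"] = None
    return df
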