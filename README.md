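# tcrdesign

Structure-based affinity and specificity design for T cell receptor (TCR)
interfaces with peptide–MHC (pMHC) ligands.

TCRs bind their pMHC targets weakly (KD typically 1–300 µM), and engineering
higher-affinity variants for immunotherapy risks losing peptide specificity:
a substitution that grips the MHC platform harder binds *every* peptide
presented on that MHC. This package implements a conservative, structure-based
route around that problem: score every point mutation of the TCR residues
that actually touch the ligand, prefer mutations predicted to contact the
peptide itself, and verify candidates against measured binding data. It is
aimed at computational structural biologists working on TCR (or general
protein–protein interface) engineering.

## What it computes

**Mutant modeling.** Given a TCR–pMHC complex (PDB format), a point mutant is
built by exhaustively enumerating side-chain rotamers for the substituted
residue against a fixed environment (the `NoMin` protocol; `MinSC`, `MinBB`
and `Min` variants additionally relax interface side-chain χ and/or backbone
φ/ψ torsions). The rotamer library ships with the package and is expanded
with ±1σ sub-rotamers on χ1–χ3.

**Binding score.** A mutant's predicted binding change is a weighted sum of
six interface energy terms,

```
ΔΔG_pred = w · [E_vdw_attr, E_vdw_rep, E_solv, E_hbond, E_intra_rep, E_elec](mut)
         − w · [ ... ](wt)
```

with default weights **w = (0.57, 0.0045, 0.58, 1.2, 0.026, 0.03)** — the
retrained six-term "ZAFFI 1.1" vector. Scores are in arbitrary units; a
score ≤ −0.6 (≈ −0.25 kcal/mol) flags a predicted binding improvement, and
mutants with van der Waals repulsion > 580 are treated as clashes. The
weights can be refit to any measured dataset by no-intercept least squares
(`fit_weights`), and any score set can be evaluated with Pearson r,
Kendall τ-b and ROC AUC (`evaluate_functions`).

**Design scans.** `saturation_scan` enumerates all 19 substitutions at every
TCR residue within 5.5 Å of the pMHC; `specificity_scan` ranks mutations by
differential ΔΔG between two ligand complexes; `proline_candidates` selects
positions whose backbone (φ, ψ) lies in proline-favorable territory (with a
pre-proline-favorable preceding residue).

**Thermodynamics and SPR.** `ddg_from_kd` (RT·ln KD_mut/KD_wt), fold changes,
specificity changes and double-mutant coupling energies connect measured
dissociation constants to the design predictions. The `spr` module fits
steady-state 1:1 Langmuir equilibria and single-cycle kinetic titrations
(1:1 association model with baseline drift, piecewise-analytic integration)
and simulates sensorgrams for parameter-recovery testing.

**Interface geometry.** Contact enumeration, buried solvent-accessible
surface area (Shrake–Rupley sphere sampling, 1.4 Å probe), geometric
hydrogen bonds (H···A ≤ 2.7 Å and D···A ≤ 3.6 Å, including water-mediated
bridges), Kabsch superposition/RMSD, and the TCR–pMHC crossing angle.

## Worked example

```python
from tcrdesign import *

# Thermodynamics of the high-affinity double mutant (KDs in uM)
ddg_from_kd(9.5, 0.024)          # -> -3.54  kcal/mol
format_sig(fold_change(9.5, 0.024))   # -> '400'

# Evaluate scoring functions on the packaged measured dataset
ds = packaged_dmf5_dataset()
rep = evaluate_functions(ds, ["ZF", "Ros"])
for row in rep.rows:
    print(f"{row.function}: r={row.pearson_r:.2f} (p={row.p_value:.1e}), "
          f"AUC={row.auc:.2f}, n={row.n_correlation}/{row.n_auc}")

# SPR kinetic-titration round trip at 1 RU noise
sched = InjectionSchedule.titration([10e-9 * 2**i for i in range(5)])
gram = simulate_sensorgram(KineticParams(kon=1.7e6, koff=0.05, rmax=100.0),
                           sched, noise_sd=1.0, seed=11)
fit = kinetic_titration_fit(gram)
print(f"kon={fit['params'].kon:.2e} 1/(M s), koff={fit['params'].koff:.3f} 1/s, "
      f"KD={fit['kd']*1e9:.1f} nM")

# Score a point mutation on a synthetic two-chain complex
m = make_synthetic_complex(seed=1, n_receptor=4, n_ligand=3, gap=4.5)
mut = mutate_and_pack(m, MutationSpec.parse("aA3W"))
print(f"predicted ddG(alphaA3W) = {predict_ddg(m, mut):+.3f} score units")
```

Output:

```
ZF: r=0.59 (p=2.3e-03), AUC=0.85, n=24/32
Ros: r=0.72 (p=7.1e-05), AUC=0.95, n=24/32
kon=1.70e+06 1/(M s), koff=0.050 1/s, KD=29.3 nM
predicted ddG(alphaA3W) = +1.369 score units
```

The evaluation lines read: over the 24 mutants with measured ΔΔG (after
excluding four true-negative outliers), the fixed-backbone scores correlate
at r = 0.59 (ZAFFI) and 0.72 (Rosetta transcription), and over all 32
mutants the latter discriminates >3-fold binding improvements with
AUC = 0.95. The SPR fit recovers the generating rate constants from a noisy
five-injection single-cycle titration.

## Data files

`src/tcrdesign/data/` ships the united-atom parameter table
(`atom_params.csv`), the rotamer library (`rotamers.csv`), the
proline/pre-proline Ramachandran polygons (`rama_regions.csv`), and CSV
transcriptions of the published DMF5 measured-affinity and score tables
(`table1.csv`, `table2.csv`) used by the calibration and evaluation
fixtures.
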