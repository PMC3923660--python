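# Methods

This note documents the models, parameters and numerical choices behind
`tcrdesign`, and what the test suite does and does not demonstrate.

## Structure model and parameterization

Structures are read and written in PDB format via gemmi. Alternate
locations resolve to the highest-occupancy conformer (ties broken by altloc
letter). Chain roles (TCR α/β, MHC heavy chain, β2-microglobulin, peptide)
are assigned either explicitly or by a length heuristic (peptide 8–13
residues, β2m ≈ 99, MHC heavy ≥ 200, remaining two chains = TCR α then β in
declared order); ambiguity is an error rather than a guess.

Only polar hydrogens are modeled. The backbone amide H bisects the
C(prev)–N–CA opening at 1.00 Å; side-chain polar hydrogens are rebuilt from
ideal internal coordinates regardless of whether the input file carried
hydrogens, so results do not depend on upstream protonation conventions.
Rotatable hydroxyl hydrogens take the template torsion — their orientation
is not optimized, a known approximation that mainly affects Ser/Thr/Tyr
hydrogen-bond geometry.

Per-atom parameters (partial charge, Lennard-Jones rmin/2 and well depth,
implicit-solvation ΔG_free, correlation length λ, volume) come from a
self-contained united-atom table (`data/atom_params.csv`), with
CHARMM19/EEF1-flavoured values: aliphatic carbons are united CH_n atoms,
charge groups sum to the residue's formal charge (±1e-6 e), ionic atom
types get λ = 6 Å, all others 3.5 Å. Water oxygens carry sterics and
hydrogen-bond capability but zero charge and zero ΔG_free (environment
only). Users can supply their own table; unknown atoms raise an error
naming the residue and atom.

Ideal side-chain geometry (bond lengths, angles, ring torsions) is derived
at import time from the idealized residue models bundled with biotite
(Chemical Component Dictionary), converted to an internal-coordinate tree
rooted at CB. Atoms whose torsion axis is a canonical χ bond are tagged
with the χ index plus a fixed offset, so side chains can be re-posed at
arbitrary χ. Rings close exactly because the tree's internal coordinates
are mutually consistent; the ideal aromatic rings are very slightly
asymmetric (ring-flip residual ≈ 0.004 Å), which is why the symmetry tests
use a 0.01 Å tolerance.

## Energy function

Six terms are summed over cross-interface atom pairs (TCR side vs pMHC
side, waters counting as fixed pMHC-side environment), truncated at 8 Å
with a smoothstep switch over 7–8 Å:

- **LJ 6–12**, rmin_ij = r_i + r_j, ε_ij = √(ε_i ε_j), split into an
  attractive branch (clamped at −ε inside rmin) and a repulsive branch
  (E + ε inside rmin, continued linearly below 0.6·rmin with the slope at
  0.6·rmin). The repulsive branch is therefore finite, non-negative and
  monotone in distance.
- **Gaussian-exclusion implicit solvation** (Lazaridis–Karplus form),
  heavy atoms only: −[f_i(r)V_j + f_j(r)V_i], with
  f_i = ΔG_free,i/(2π^{3/2} λ_i r²)·exp(−((r−R_i)/λ_i)²).
- **Hydrogen bonding**: donor-H/acceptor pairs, −2.0 kcal/mol ×
  exp(−(d_HA−1.9)²/(2·0.3²)) × cos²θ(D–H···A) for θ < 90°, cut at 3.5 Å;
  always ≤ 0. Donors and acceptors are detected geometrically (H within
  1.3 Å of N/O/S; acceptors are all O plus N with no bound H and heavy
  degree ≤ 2), which avoids bookkeeping connectivity through the model.
- **Long-range Coulomb electrostatics** with distance-dependent dielectric
  ε(r) = 4r, evaluated only for charged pairs at r ≥ 5.0 Å. The short-range
  regime is deliberately excluded; short-range polar interactions are the
  hydrogen-bond term's job.
- **Intra-residue repulsion**: the LJ repulsive branch over within-residue
  pairs ≥ 3 bonds apart (bonds inferred from distance), computed for
  repacked residues only — for a point-mutant ΔΔG this means the mutated
  position in both wild type and mutant, so the difference is well defined.

The weighted score is `w · terms`; the shipped default is the retrained
six-term vector (0.57, 0.0045, 0.58, 1.2, 0.026, 0.03). Scores are in
arbitrary units. The published absolute score columns of the external
engines these terms emulate are *not* reproduced numerically — the term
sources are named in the literature but their internal parameters are not
printed — so the toolkit treats the score scale as calibratable: the
−0.6 ↔ −0.25 kcal/mol anchor classifies improvements, the >580 repulsion
threshold flags clashes, and `fit_weights` absorbs scale differences when
measured data are available. All functional forms above are fixed in
`energy.py` (term-set version 1).

## Packing and minimization

`NoMin` packing replaces the mutated side chain, enumerates the expanded
rotamer set exhaustively, scores each conformation against the fixed
environment (cross terms plus the residue's intra repulsion) and keeps the
argmin; ties resolve to the lowest library index, so packing is fully
deterministic and the backbone is untouched by construction. The library
(`data/rotamers.csv`) is a compact backbone-independent set of χ means
(192 entries) with ±1σ (σ = 9°) sub-rotamers on χ1–χ3 emulating extra-χ
sampling; χ4 is not expanded. Proline is built as a rigid ring (no χ
search); its backbone N carries no amide H and the ring CD balances the
charge group.

Minimization (`MinSC`/`MinBB`/`Min`) runs after packing: L-BFGS-B in
torsion space over the interface residues' χ and/or φ/ψ (tolerance 1e-4,
max 500 iterations), with backbone rotations propagating downstream along
the chain. If the optimizer fails to lower the energy the input structure
is returned, so minimized energy never exceeds the starting energy. The
order (pack, then minimize) and the convergence thresholds are this
package's choices; they are deliberately conservative because relaxation
that is too aggressive produces false-positive predictions.

## Interface geometry

Distance criteria use heavy atoms only; "side chain" means CB and beyond
(glycine has none). Defaults: interface membership 5.5 Å, peptide contact
6.0 Å, RMSD zone 10 Å, SASA probe 1.4 Å, hydrogen bonds H···A ≤ 2.7 Å and
D···A ≤ 3.6 Å. For two-ligand scans the interface is the union of the
per-complex interface sets, keeping the scan comparable across ligands;
per-complex lists are available by calling `interface_residues` on each
complex.

SASA is Shrake–Rupley sphere sampling with 960 Fibonacci points per atom
and element radii (C 1.70, N 1.55, O 1.52, S 1.80 Å), which puts the
single-sphere closed form within 1%. Buried pMHC surface is free-state
SASA minus the pMHC portion of the complex SASA.

The crossing angle is defined here as the angle between the Vα→Vβ
mass-center vector (first 115 residues of each TCR chain) and the peptide
axis (principal line through peptide Cα, oriented N→C), both projected
onto the MHC platform plane (principal plane of MHC residues 1–180 Cα).
The sign convention (optional) is the sign of cross(TCR vector, peptide
axis)·normal with the normal pointing from platform toward the TCR. No
community-standard formula exists for this angle, so values should be
compared across structures computed with the same definition; a few
degrees of disagreement with other conventions is expected.

Water-mediated hydrogen bonds are reported when one water bridges a donor
and an acceptor; the solute-donor leg obeys both geometric criteria toward
the water oxygen, while the water-to-acceptor leg uses the donor–acceptor
distance criterion only, because water hydrogens are typically absent from
crystal structures and are not rebuilt.

## Design scans

Saturation scans enumerate all 19 non-identity substitutions at each TCR
interface residue (19k records for k residues, by construction). Records
carry per-term mutant-minus-wild-type deltas; the clash filter removes
records with repulsion delta strictly above 580. Proline candidates
require (φ, ψ) inside the shipped proline-favorable region *and* the
preceding residue inside the pre-proline-favorable region *and* predicted
proline ΔΔG ≤ 0 in at least one packing mode. The Ramachandran regions are
explicit polygons in `data/rama_regions.csv` (proline: φ ∈ [−110, −40]
with ψ ∈ [−75, 10] or [100, 180]; pre-proline: broad β plus a small α
patch) — editable, since published favorable-region contours vary by
source.

## Calibration and evaluation

Weight fitting is ordinary least squares of measured ΔΔG on the six term
columns with **no intercept** (a null mutation must predict zero) after
removing clash rows; rank-deficient designs raise an error naming the
collinear terms. Evaluation reports Pearson r with its two-sided t-test
p-value, Kendall τ-b, and ROC AUC where lower score ranks as more positive
(Mann–Whitney tie handling). Correlations are computed over the measured
rows minus an explicit, overridable outlier list; the default excludes the
four ELA-complex true negatives at position αG28 (I/L/N/Y) — mutants
correctly predicted not to bind whose extreme scores would otherwise
dominate r. This specific set is an inference (the published account
names "four αG28 outliers" without enumerating them); with it, the
packaged score table reproduces the published correlations to two
decimals, and the list is a parameter precisely because it is inferred.
AUC positives default to measured fold improvement > 3; ΔΔG < −0.25
kcal/mol is selectable. Non-binding mutants enter the AUC as negatives and
are excluded from correlations.

## SPR fitting

The 1:1 interaction model dR/dt = kon·C(t)·(Rmax − R) − koff·R is linear
within each constant-concentration segment, so simulation uses the exact
piecewise-exponential solution — there is no integrator error to tune.
The observed response adds a baseline r0 and a single linear drift slope
over the whole cycle (slope-per-segment is out of scope). The kinetic fit
optimizes (log kon, log koff, log Rmax, drift, r0) by Levenberg–Marquardt
over the full trace; initial estimates are deterministic (koff from the
terminal dissociation log-slope, kon from the first-injection initial
slope). Near-singular Jacobians raise a non-identifiability error rather
than returning garbage. Steady-state data fit R(C) = Rmax·C/(KD + C) by
`curve_fit` with asymptotic standard errors. Mass-transport limitation is
not modeled. Note koff/kon for the published rate pair is 29.4 nM; the fit
reports this ratio, and any discrepancy with a separately printed KD is a
property of the source data, not reconciled here.

## Synthetic data

`make_synthetic_complex` builds two idealized chains (default poly-alanine,
arbitrary sequences allowed) with ideal backbone geometry (N–CA 1.458,
CA–C 1.525, C–N 1.329 Å; extended φ = −139°, ψ = 135°, ω = 180°), adds
0.005 Å Gaussian coordinate jitter (seeded, bitwise reproducible), and
separates the chains so the minimum inter-chain heavy-atom distance equals
the requested gap exactly (solved by bisection). The SPR simulator's
default study condition is the published experiment's layout: five 2-fold
titrations from 10 nM, 120 s contacts, 600 s dissociation, rates
kon = 1.7×10⁶ M⁻¹s⁻¹ and koff = 0.05 s⁻¹, and 1 RU Gaussian noise for the
noisy condition. Synthetic calibration datasets draw standard-normal term
matrices (repulsion and intra columns folded positive) at n = 200 with
σ = 0.1 kcal/mol noise for the noisy condition.

What synthetic fixtures do not emulate: real side-chain packing density,
correlated experimental noise, mass transport in SPR, and the size and
chemistry of a genuine TCR–pMHC interface. Passing tests therefore
demonstrate algorithmic correctness (oracle equivalence, parameter
recovery, invariances) and faithful arithmetic on the published tables —
not predictive accuracy on new interfaces, which is what the evaluation
module is for when measured data exist.

## Problem sizes and scope

The test suite and the acceptance script run on small synthetic complexes
(≤ 8 residues), the packaged 32-row measured dataset, and 1201-point
sensorgrams; these sizes were chosen as the smallest that exercise every
code path and keep the full suite fast on one CPU. Crystal-structure-scale
analyses (interface enumeration over a full TCR–pMHC complex, crossing
angles and buried surface of deposited entries) use exactly the same
functions and accept any PDB input, but deposited structures are not
bundled and no test depends on downloading them. The published absolute
score columns, the RMSDs of externally built mutant models, and
correlations on external mutant panels are out of scope: they depend on a
third-party engine's internals, and this package's calibration route is
validated by parameter recovery on synthetic term matrices instead.
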