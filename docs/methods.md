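# Methods

This note documents the models implemented in pepforge, the choices made
where the underlying methods are underdetermined, and what the synthetic
test data can and cannot show.

## Structure model and templates

Structures are heavy-atom only. Peptides are built in internal
coordinates (NeRF chaining) with fixed bond lengths and angles;
backbone geometry uses Engh–Huber-like constants (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, N–CA–C 111.2°, …) and side chains come from
z-matrix templates derived automatically from the ideal coordinates of
the chemical component dictionary shipped with biotite. Rotatable
side-chain torsions (χ angles) are detected as acyclic single bonds;
branch atoms ride on the first-placed sibling at a fixed offset.
D-amino acids use the mirrored L template (all torsions negated), which
is the exact mirror image under fixed bond geometry. Non-natural
residues are hand-built: cyclobutylalanine (`CBA`) uses a planar-square
ring approximation; the two hydrocarbon-staple residues (`S5A`, `R8A`)
are α-methyl residues with saturated 5- and 8-carbon chains whose tips
are joined by an explicit inter-residue bond — no attempt is made to
model the olefin geometry of the metathesized bridge. Proline's ring is
kept rigid at template geometry; its φ is not mechanically coupled to
the ring, so φ restriction arises only energetically.

Hydrogens are never stored. Hydrogen-bond donors are inferred from
heavy-atom connectivity, with ideal H positions generated on demand
(amide H on the C′–N–CA bisector; sp2 NH₂ in-plane; ammonium NH₃
tetrahedral with a fixed phase). Hydroxyl and thiol donors are treated
as freely rotatable: the H is placed on its tetrahedral cone at the
azimuth most favorable to the candidate acceptor. Protonation follows
standard states at pH 7.4 with neutral His (ND1 acceptor, NE2 donor).

## Interface descriptors

SASA uses deterministic sphere sampling (Shrake–Rupley style) with a
Fibonacci-spiral point set, 960 points/atom by default, probe 1.4 Å,
radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 Å. Agreement with a
dense brute-force oracle is within 1% on random clusters (tested). The
point set is orientation-fixed, so SASA-derived quantities are rotation
invariant only to discretization accuracy (≈1% — relevant to the
`solvated` binding flavor).

Burial is ΔSASA(atom) = SASA(isolated component) − SASA(complex),
clamped at zero; `buried_SA` sums both sides of the interface.
Hydrogen bonds use conventional geometric criteria (donor–acceptor
≤ 3.5 Å, D–H···A ≥ 120°, best-distance matching with one acceptor per
donor-H); salt bridges count charged-group *pairs* within 4.0 Å, and the
"net" count is favorable minus like-charge pairs — the source material
does not define "net", and this reading is flagged to users. The
hydrophobic/charged burial descriptors are converted to kcal/mol with a
configurable 0.025 kcal/(mol·Å²) scale; whether the original descriptors
were areas, counts or calibrated energies is not recoverable from the
published description, and only the unit-independent intercept of the
scoring equation is treated as exact. Free ionized termini count as
charged groups only for uncapped chains.

The packing-normality metrics (dihedral, 1D, 3D) are *surrogates* with
the same interface as an external knowledge-based provider: a smooth
bimodal Ramachandran frequency model for dihedral normality and
interface contact-count/anisotropy Z-scores against fixed reference
constants. Only the weighted combiner (0.145/0.390/0.465) is specified
exactly; the surrogate Z-scores are not calibrated against any PDB-wide
reference and should not be compared across packages.

## Force field and binding flavors

Nonbonded energy is 12-6 Lennard-Jones plus screened Coulomb with the
distance-dependent dielectric ε(d) = 4d (pair energy k·qᵢqⱼ/(4d²),
k = 332.0636 kcal·Å/mol·e²). Parameters ship as versioned CSVs: a
compact atom-type set (aliphatic/aromatic/carbonyl C, amide/guanidinium/
ammonium N, carbonyl/hydroxyl/carboxylate O, S) with Amber-like LJ wells
and heavy-atom-lumped partial charges that reproduce formal charges per
residue. This static table stands in for per-residue quantum-derived
(RESP) charges, which are data, not code, from this package's
perspective. Exclusions: 1-2/1-3 removed, 1-4 scaled by 0.5. No cutoffs
(systems are small).

Solvation is a Gaussian-exclusion continuum term: a fully exposed atom
contributes its reference free energy ΔG_ref; each neighbor j subtracts
(ΔG_ref,i / (2√π λᵢ r²)) · exp(−((r−Rᵢ)/λᵢ)²) · Vⱼ. Charged types use
λ = 6 Å, others 3.5 Å. The `solvated` binding flavor combines this term
with a 0.65 kcal/(mol·Å²) buried-surface nonpolar term; it deliberately
replaces a Poisson–Boltzmann treatment, which is out of scope, while
keeping the polar + nonpolar intent and the published 0.65 scale.

Because sampling is torsional, minimization in Cartesian space maintains
covalent geometry by harmonic restraints on bonded (1-2, k = 300) and
geminal (1-3, k = 80 kcal/mol/Å²) distances, with restraint targets
taken from ideal template geometry (torsion-independent). Torsional
force-field terms are omitted; steric and electrostatic terms shape the
backbone distributions instead (see the Ramachandran discussion below).
The minimizer is L-BFGS restricted to movable atoms, restarted across
premature line-search terminations, converged at max |∇| < 0.05
kcal/mol/Å; a result is accepted only if it lowers the energy, making
each round exactly non-increasing. The two-round protocol (round 1:
backbones fixed, peptide side chains plus receptor side chains within
4 Å of the peptide free; round 2: receptor fixed, peptide free) is
alternating minimization — iterating it converges, but a single pass on
a contacting complex need not reach a joint stationary point.

The `neutralized` flavor discharges charged side chains *and* free
termini (the published description leaves termini unstated; both is the
default here). The `strain` flavor minimizes the extracted free peptide
with a function-evaluation budget; its non-negativity (strain ≥ simple)
is exact, but its value is reproducible under rigid motion only to the
optimizer's path tolerance (≈0.05 kcal/mol in tests).

## MCSAM sampling

Conformations live in torsion space (φ/ψ per residue plus χ angles;
ω fixed trans). Each run initializes a stack of 100 random minimized
conformations, grows it to at most 200, and performs Monte-Carlo-with-
minimization steps: with probability 0.8 a residue's (φ, ψ) pair is
drawn jointly from its Ramachandran bias map, otherwise a single torsion
receives a Gaussian perturbation (σ = 30°); the proposal is minimized
(bounded L-BFGS in torsion space) and accepted by Metropolis on
minimized energies along a geometric 1000 K → 300 K ladder. Stack
maintenance (the published rules defer to an external reference):
insert if below capacity or better than the worst member; a candidate
within the diversity radius (0.5 Å backbone+Cβ RMSD) of an existing
member replaces it only when lower in energy. Macrocycle closure bonds
(staple, head-to-tail) are maintained by a harmonic restraint since
torsion-space building cannot close rings exactly.

Ramachandran bias maps are computed per position from the flanking
tripeptide on a 10° grid, Boltzmann-weighted at T_bias = 600 K (chosen
to populate minor basins). Flanking residues sit at (180°, 180°), which
is its own mirror image, so achiral maps are exactly point-symmetric and
the map of a D residue is exactly the point reflection of the fully
mirrored tripeptide's map. Missing neighbors at chain termini default
to alanine of the central residue's chirality.

Ensembles are merged across runs, filtered at 15 kcal/mol above the
minimum, and clustered by a leader algorithm in energy order at 1.0 Å
backbone+Cβ RMSD; "top-k clusters" are ranked by representative energy
(cluster-size ranking is a plausible alternative the source leaves
open). Desk-scale defaults are 20 runs × 500 steps; the `paper` profile
preserves 500 × 10,000.

Because the model is heavy-atom with no torsional potentials, the
sampled backbone distributions are broader than hydrogen-resolved force
fields give: at desk scale a tetra-alanine reference run places ≈ 92% of
low-energy interior (φ, ψ) in sterically allowed regions (φ < 0 or the
left-handed island) rather than ≳ 95%; the regression test pins 85% at a
fixed seed to leave stochastic margin below the attained value.

## Boltzmann-weighted affinity

The peptide is sampled in torsions plus six rigid-body coordinates
around its bound pose; the protein is rigid (optional receptor
side-chain flexibility is off by default, matching the stated runs).
Non-terminal backbone heavy atoms (one residue excluded at each end —
configurable to two) are tied to the reference backbone by a flat-bottom
well: no penalty within 1.0 Å, harmonic beyond with k = 10 kcal/mol/Å²
(the force constant is unstated in the source; the default is exposed).
Each run contributes its minimum-total-energy pose; weights are
exp(−E_total/kT) at 300 K (also unstated; only the T → 0 and T → ∞
limits are relied on) and the score is the weighted mean of the
protein–peptide interaction energy. Interaction energy excludes all
intra-peptide terms, so no strain estimate enters the score. Mutated
side chains are placed from the ideal template rotamer on the retained
backbone and relaxed by the sampling itself.

## SAR statistics

ΔΔG = RT·ln(Kd/Kd_ref). The bundled prospective-scan table is
transcribed as printed and guarded by a checksum test. Its MDMX ΔΔG
column is consistent with RT = 0.593 kcal/mol (298 K), while its MDM2
column is reproducible only with an effective RT ≈ 0.815 kcal/mol; both
constants are exposed (`RT_298`, `TABLE4_MDM2_EFFECTIVE_RT`) and the
discrepancy is reported, not corrected. Correlations are computed over
mutant rows only (the wild type has no calculated ΔΔG entries); a flag
can include it at (0, 0). Because Pearson r is affine invariant, the r²
values are insensitive to the RT chosen and to ΔΔG-vs-pKd axis choices.
Inactive peptides receive a floor *binding-energy* value of
−2.0 kcal/mol — the source wording conflates Kd with an energy; the
energy reading is implemented. In the sampling benchmark table, the
printed per-entry best-RMSD-in-top-100 column averages 1.93 Å while the
printed summary row says 2.16 Å; the fixture keeps the printed cells and
`table2_stats` reports the recomputed mean.

## Anisotropy models

The 1:1 direct model uses the exact quadratic bound fraction; the
competitive model uses the exact cubic closed form (d, e, f, θ as
conventionally defined — the printed rendition of the equation contains
typographical corruption, and the brute-force two-species equilibrium
solver in the tests is the arbiter of correctness). The trigonometric
root suffers catastrophic cancellation when one equilibrium constant
dominates, so the free-protein root is polished by safeguarded
Newton/bisection on [0, P_total] in extended precision; agreement with
the equilibrium solvers is at machine precision over 10⁴ random
parameter draws. Fitting is least squares with per-point replicate
weighting when replicates ≥ 2, log-parameterized Kd, delta-method
standard errors. Control criteria from the assay design are enforced:
P_t > L_st is warned on violation, and a fitted titration whose observed
final baseline falls below the free-peptide anisotropy (beyond
max(0.005, 3 SEM of the tail)) is flagged as indicating an unintended
competitor–tracer interaction. The simulator emulates the published
design (250 nM protein, 50 nM labeled peptide, serial competitor
dilutions, Gaussian noise, triplicate).

## What the synthetic data does and does not show

Toy complexes realize each requested interaction at an isolated site, so
descriptor counts are exact by construction; they validate the counting
and scoring logic, not the empirical weights' transferability to real
interfaces. The sampling and affinity tests run at desk scale on small
peptides; they verify determinism, bounds, limits and rigged-potential
recovery, not the reproduction of crystallographic bound conformations,
which requires the published sampling sizes and experimental structures.
The benchmark statistics are recomputed from printed per-entry values,
not regenerated by sampling. Titration simulations share the model used
in fitting, so recovery tests establish estimator correctness and
precision at the stated noise, not robustness to instrument artifacts.

## Known limitations

Heavy-atom energetics (no explicit hydrogens, no torsional terms), a
representative rather than complete parameter set, surrogate packing
metrics, restraint-based covalent geometry during Cartesian
minimization, approximate ring geometry for cyclobutylalanine and
proline, no crystal-symmetry/mmCIF handling, and no absolute-Kd
prediction from energies (affinity scores are relative).
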