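# Methods

`metabolon` implements the computational core of a study of transient
enzyme assemblies ("metabolons") in the *E. coli* 1-carbon metabolism
pathway: permutation statistics over a split-YFP protein–protein
interaction (PPI) fluorescence matrix, an interface-overlap statistic over
protein surfaces, degenerate-codon library arithmetic, and a
patchy-particle Langevin reaction–diffusion simulator that converts the
measured PPI network into metabolic-flux predictions.  This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic-data tests do and do not establish.

## 1. The fluorescence matrix and its permutation statistics

A bimolecular fluorescence complementation screen measures every protein
pair in two fusion orientations.  The working symmetric matrix takes the
per-pair maximum mean fluorescence intensity (MFI) over orientations whose
wells analyzed at least 10,000 cells (`min_cells`, configurable); a pair
with no retained orientation is missing.  MFI classes use half-open
intervals [750, 900) weak, [900, 1100) moderate, [1100, ∞) strong — the
source convention leaves exact boundary values unassigned, so the
half-open choice guarantees that classification partitions [0, ∞).

The cluster statistic is the median (mean available) of the MFI values of
a named pair set.  The null resamples, `n_perm` = 10,000 times, an equal
number of **distinct, non-missing, off-diagonal, unordered** pairs
uniformly from the matrix; pairs are drawn without replacement within a
draw and independently across draws.  Diagonal (homo-oligomer) entries are
excluded from the pool by default because the tested clusters are
heterodimeric; this is configurable.  The one-sided empirical p value is

    p = (#(S_null ≥ S_obs) + 1) / (N + 1),

bounded in [1/(N+1), 1]; ties count against the alternative and no mid-p
correction is applied.  The same machinery drives (i) conditional
cross-matrix tests — select pairs by a rule on one matrix (e.g. TM score
> 0.5), evaluate the statistic and null on the other, null pool always the
whole matrix; (ii) per-protein interaction-propensity tests (pair set =
the protein's non-missing row); and (iii) comparisons by the unpaired
Welch *t* test (via `scipy.stats.ttest_ind(equal_var=False)`).

Prediction concordance scores agreement between simulation-predicted
binders (binding free energy ΔG ≤ −3 kcal/mol, an input table) and the
fluorescence call (MFI > 670): the reported fraction is the share of
predicted binders with MFI above threshold, and the permutation null
relabels binder status uniformly over the evaluated pairs holding the
number of binders fixed, which preserves both margins.  ΔG values are
inputs; no free-energy computation happens here.

## 2. Interface overlap (mean inter-surface contacts)

For a protein with n ≥ 2 per-partner interaction surfaces S_i (residue
sets with Cα coordinates), overlap is scored by

    MISC = Σ_{i<j} C(S_i, S_j) / (n(n−1)/2),
    C(S_i, S_j) = #{(s,p) : |r_s − r_p| ≤ 7 Å} / (m_i m_j),

a normalized Cα–Cα contact count in [0, 1]; shared residues contribute at
distance 0.  The null draws sets of `n_R` = 50 random surfaces (the
source alternates between 50 and 100; 50 is the default, both exposed in
configuration), each defined as the exposed residues (relative solvent
accessibility > 0.25) within a probe radius of a uniformly chosen exposed
seed residue.  The probe radius defaults to the mean radius of gyration of
the observed surfaces so random surfaces match the observed size scale.
With 10,000 such sets the Z score is

    Z = (MISC_obs − mean(MISC_rand)) / (σ/√n_sets),

and p is the standard-normal upper tail of Z (with n_sets = 10,000 a
t reference is indistinguishable; the normal is used for determinacy).

**A calibration caveat is intrinsic to this Z**: dividing by σ/√n_sets
treats a single observed MISC as if it were a mean over n_sets null sets,
so under the null |Z| is of order √n_sets, not 1 — the test is extremely
anticonservative as a frequentist p value and should be read as a
standardized effect size.  `OverlapResult` therefore also carries
`p_empirical`, the empirical upper-tail probability of the observed MISC
within the null sample, which is uniform under the null (verified by the
calibration tests) and is the right quantity for null-calibrated
decisions.  Degenerate nulls (σ = 0, e.g. every exposed residue within one
contact shell) are flagged and fall back to the empirical bound.

Because a random surface is fully determined by its seed residue, the
implementation precomputes all candidate surfaces and their pairwise C
values once; the 10,000 random sets then reduce to index lookups.  This is
algebraically identical to drawing surfaces one at a time (unit-tested
against the naive loop).

Interface extraction from a two-chain structure takes, for each chain, the
residues with any partner-chain Cα within a cutoff that defaults to the
same 7 Å as the contact function (the inter-chain cutoff is not pinned by
the source; configurable).  Residue-frequency maps report, per residue,
the fraction of a protein's surfaces containing it.

## 3. Degenerate-codon arithmetic

An IUPAC triplet is expanded to concrete codons and translated with the
standard genetic code.  VDS = [ACG][AGT][GC] gives 18 codons encoding 13
amino acids with no stops; across the 85 library positions that is 1530
codon variants and an 1105-member amino-acid library.  VDS omits F/W/Y,
proline and cysteine, so screened fluorescence changes cannot be blamed on
truncation or gross destabilization.

## 4. The patchy-particle reaction–diffusion model

Each of 10 enzyme types is a rigid sphere (diameter 20 Å) with two
antipodal patches (diameter 8 Å): a PPI patch whose identity is the enzyme
type and an active-site patch whose identity is the substrate state it
converts.  Ligands are 8 Å spheres carrying a state S_0…S_9 or the
absorbing product P; enzyme k catalyzes S_k → S_{k+1} with per-timestep
probability p_react.  Catalytic efficiencies are sampled as
log10(k_cat/K_M) ~ Normal(5, 1) and normalized by the diffusion limit
1e8 M⁻¹s⁻¹.

Nonspecific interactions (core–core, core–ligand, non-cognate
patch–ligand, ligand–ligand) are Lennard-Jones with ε = 0.8 kT, σ the sum
of radii, cutoff 2.5σ, truncated and shifted.  Specific binding is a Morse
well: PPI patch–patch with α = 2.2 Å⁻¹, r₀ = 17.056 Å, cutoff 20 Å, depth
from the fluorescence matrix through a stepwise K_D map (MFI > 1000 →
10 µM; 800–1000 → 200 µM; 650–800 → 500 µM; below 650 → 100 mM) and
D_e = |ln(K_D / 1 M)| kT (the well-depth magnitude; the attractive sign
lives in the Morse form itself); cognate active-site–ligand binding with
α = 1 Å⁻¹, r₀ = 12.7 Å, capture 2.5 Å, D_e = 5 kT.  Morse potentials are
also shifted to zero at their cutoffs — a constant that leaves forces and
all observables unchanged while keeping total energy continuous.

**Valence.**  The active site is strictly single-valent: explicit
bookkeeping lets one ligand occupy one site (capture and release at
r₀ + 2.5 Å).  For PPI patches, the stated "attraction range 2.8 Å" is read
as the Morse truncation range (17.056 + 2.8 ≈ the 20 Å cutoff): the Morse
acts pairwise between all patch pairs within the cutoff, and valence is
limited geometrically — the steep inner wall repels patches below ~16 Å
and core excluded volume caps the coordination.  A strict mechanical
one-partner-per-patch rule was tried first and caps every cluster at a
dimer, which cannot reproduce the observed large multimeric clusters; the
geometric reading does (typical patch valence 2–4 in equilibrated
clusters, reported by the `ppi_valence` diagnostic).

**Dynamics.**  The Langevin equation m r̈ = F_c − γv + F_r uses the Stokes
drag γ = 6πηa (translation) and 8πηa³ (rotation) with
fluctuation–dissipation-consistent noise; the source's printed damping
expression kT/(6πηa) is dimensionally a diffusion coefficient and enters
as D = kT/γ.  Translation integrates with BAOAB (exactly velocity Verlet
when the thermostat is off); rotation propagates each rigid frame with the
scalar moment of inertia (2/5)ma² via Rodrigues updates.  Internal units:
Å, fs, kT(300 K); masses default to 18 kDa (enzyme; inertial relaxation
m/γ ≈ 1.6 ps, i.e. effectively overdamped at the 30 fs step) and 300 Da
(ligand).  An overdamped Brownian integrator (r += D F Δt/kT + √(2DΔt) ξ,
with the same bond and reaction bookkeeping, drift clamped at 2 Å/step as
a numerical guard against initial overlaps) is the faster desk-scale
default; its whole substep loop runs in one compiled kernel.

Verified physics: thermostat-off total-energy drift < 0.1% over 10⁴ steps
at 30 fs; translational kinetic energy 3/2 kT per particle within 5% under
the thermostat; ensemble MSD of free particles = 6Dt within 10% with
D = kT/6πηa; bit-identical trajectories for identical seeds.

**Cluster analytics.**  Two enzymes are connected when their PPI patches
are within the 20 Å Morse cutoff; clusters are connected components
(union-find, cross-checked against networkx).  Summaries carry cumulative
per-reaction counts over time, pooled cluster-size histograms, mean
per-type-pair contact matrices, and mean cluster composition.  Flux ratios
divide PPI-on by PPI-off reaction counts per step (∞ flagged on zero
denominators); the smoothed variant (count+1)/(count+1) aggregates across
replicas.

### Desk-scale study conditions

The published runs (300 copies/type at 50 µM per type, η = 1e-3 Pa·s,
5 × 10 µs ≈ 3 × 10⁸ steps) are cluster-scale.  The desk-scale flux
experiment uses 3 copies/type at the same 50 µM per-type concentration
(box ≈ 464 Å), 3 ligands per enzyme, 6 × 10⁵ Brownian steps of 15 fs at
η = 1e-4 Pa·s, the first 10% confined to a 50 Å nucleation sphere, and
reaction probabilities uniformly rescaled ×50 (reported in run
parameters; on/off flux *ratios* are invariant to the common factor).
Three constraints fix these numbers, each of which broke a naive scaling
during development:

1. *Well resolution*: the PPI Morse well is 1/α ≈ 0.45 Å wide; per-step
   Brownian noise must stay below ~0.1 Å per axis or bonds dissolve and
   clusters evaporate.  This caps how far viscosity can be lowered at a
   given timestep; 15 fs at η = 1e-4 restores resolution while keeping
   diffusion 10× the aqueous rate.
2. *Control dispersal*: the monomeric control starts from the same
   nucleation blob and must evaporate well within the run (~2 × 10⁵
   steps), otherwise both arms behave as dense blobs and no contrast can
   exist.
3. *Bulk starvation*: per-type enzyme spacing in the bulk (~300 Å at
   50 µM with 3 copies) must make sequential intermediate hand-off
   diffusion-starved outside clusters within the run length.

Under these conditions the PPI-on arm assembles percolated clusters of
15–22 of the 30 enzymes, completes full 10-step cascades, and shows
late-step flux ratios of ~2–6× while early steps stay near 1 — the
qualitative signature of channeling (late-over-early ordering).  The
asserted endpoint pools reaction counts over the five paired replicas
before forming ratios, mirroring how the published per-step ratios
aggregate the independent trajectories; single desk-scale replicas carry
count noise of the same order as the effect.  The published
several-orders-of-magnitude gains require the cluster-scale runs and are
not reproduced at desk scale.

## 5. Synthetic data

Generators emulate every input shape: a 35-protein two-orientation MFI
table with one planted 5-protein cluster, homo-oligomer diagonal signal,
per-well orientation attenuation ~ U(0.5, 1), and missing wells via
low-cell-count dropout; a paired TM-score-like matrix whose planted
subgroup receives U(0.5, 0.9) similarities with a controllable coupling;
virtual-Cα chains (3.8 Å bonds; compact biased self-avoiding walk or ideal
helix) with planted surfaces of controlled mutual overlap and RSA assigned
so ≥ 40% of residues are exposed; and two-chain dimers with an exact
minimal inter-chain gap (bisected x-shift).  Background N(600, 60) and
cluster N(1150, 80) MFI distributions are not published values; they
reproduce the qualitative regime (a weak majority below 750, classifiable
planted clusters) and are fully exposed in the generator spec.  All
generators are seed-deterministic.

What passing tests show: the statistics recover planted structure at the
stated error rates and calibrate uniformly on structureless data.  What
they do not show: robustness to real-data pathologies — expression-level
confounds in fluorescence, fusion-orientation biases beyond a scalar
attenuation, RSA estimation error, or model error in predicted dimer
interfaces.

## 6. Degenerate inputs, tie-breaks, tolerances

Empirical p values use the +1 ceiling/floor convention throughout.  Welch
on two zero-variance equal-mean samples returns p = 1.  Greedy bond
capture resolves ties by distance then index (stable sort), making runs
bit-deterministic.  Matrix TSV round-trips are value-exact (`%.17g` out,
round-trip parsing in).  The purine-cluster membership ambiguity in the
source (one listing repeats a protein; the pair count implies one excluded
pair) does not affect this package: cluster membership is always an
explicit input.

## 7. Known limitations

- The overlap Z is anticonservative by construction (see §2); use
  `p_empirical` for calibrated decisions.
- The simulator's desk scale demonstrates directional channeling, not the
  published effect sizes; stoichiometry and contact-map outputs at desk
  scale are noisy below ~5 replicas.
- Hydrodynamic interactions, explicit substrate channeling conduits, and
  atomistic detail are out of scope by design.
- Cognate binding applies no attraction before capture, so on-rates are
  diffusion-limited encounters with the 15.2 Å capture sphere rather than
  funneled approaches.
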