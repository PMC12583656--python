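# metabolon

Statistics and coarse-grained simulation for transient enzyme-pathway
interaction networks.

Sequential enzymes of a metabolic pathway often associate into loose,
short-lived assemblies ("metabolons") held together by weak
protein–protein interactions (PPI).  Quantifying those interactions and
their functional consequences raises three computational problems that
this package solves for the *E. coli* 1-carbon metabolism system and any
dataset with the same shape:

1. **PPI-matrix statistics.**  A split-YFP (BiFC) screen yields a
   two-orientation fluorescence table over all protein pairs.  The package
   symmetrizes it (per-pair maximum over orientations, low-cell wells
   discarded), classifies interaction strength, and tests named pathway
   clusters with a non-parametric permutation null: the cluster median MFI
   against medians of equally sized random pair sets,
   p = (#(S_null ≥ S_obs)+1)/(N+1) at N = 10,000.  Conditional
   cross-matrix tests (e.g. pairs with TM score > 0.5 evaluated on the
   fluorescence matrix), per-protein propensity tests, Welch comparisons,
   strong-interaction graphs, and concordance scoring of simulation-
   predicted binders (ΔG ≤ −3 kcal/mol vs MFI > 670) complete the suite.
2. **Interface overlap.**  Whether a protein re-uses one "dedicated"
   surface across partners is scored by the mean inter-surface contact
   statistic MISC = Σ_{i<j} C(S_i,S_j)/(n(n−1)/2), with C a normalized
   7 Å Cα–Cα contact count, against a null of random exposed-residue
   surfaces of matched size (RSA > 0.25, probe radius = mean radius of
   gyration of the observed surfaces), summarized as a Z score.  Interface
   extraction from two-chain structures, residue-frequency maps, and
   VDS-codon saturation-library arithmetic support the same workflow.
3. **Reaction–diffusion simulation.**  A patchy-particle Langevin /
   Brownian simulator represents each of ten enzyme types as a rigid
   20 Å sphere with a PPI patch (Morse well, depth from the fluorescence
   matrix via a stepwise MFI → K_D map and D_e = |ln K_D| kT) and an
   active-site patch (5 kT cognate well) that converts diffusing ligands
   along the cascade S_0 → … → S_9 → P.  Paired runs with PPI energetics
   on vs off measure how enzyme clustering changes per-step metabolic
   flux.

See `docs/methods.md` for the models, parameters, and numerical choices.

## Worked example

Generate a synthetic 35-protein screen with a planted 5-protein cluster,
build the symmetric matrix, and test the cluster:

```python
from metabolon.matrix import symmetrize
from metabolon.permutation import PermutationSpec, cluster_permutation_test
from metabolon.synth import default_cluster_spec, synth_mfi

spec = default_cluster_spec(seed=11)
matrix = symmetrize(synth_mfi(spec), min_cells=spec.min_cells)
cluster = list(spec.clusters[0])
pairs = [(a, b) for i, a in enumerate(cluster) for b in cluster[i + 1:]
         if not matrix.is_missing(a, b)]
res = cluster_permutation_test(matrix, pairs,
                               PermutationSpec(n_perm=10_000, seed=1))
print(f"median MFI {res.s_obs:.0f} over {len(pairs)} pairs, p = {res.p:.4g}")
```

prints

```
median MFI 1142 over 10 pairs, p = 9.999e-05
```

— the planted cluster's median fluorescence (1142, "strong" class) is
never reached by any of the 10,000 random pair sets, so the empirical
p value sits at its floor 1/10001 ≈ 1e-4.

The same analyses are packaged as numbered drivers:

```bash
python analysis/01_simulate_screen.py        # synthetic screen -> results/
python analysis/02_cluster_statistics.py     # permutation statistics
python analysis/03_interface_overlap.py      # MISC / Z on planted surfaces
python analysis/04_codon_library.py          # VDS library arithmetic
python analysis/05_flux_simulation.py        # paired PPI-on/off flux runs
```

`analysis/05_flux_simulation.py` (five paired replicas, ten to fifteen
minutes; `--replicas 2` for a quick look) ends with:

```
pooled smoothed flux ratios: [0.95 0.97 0.96 1.03 1.09 1.25 1.62 2.1  1.71 1.2 ]
geometric mean, first three steps: 0.96; last three steps: 1.63
```

— early pathway steps are unchanged or slightly slowed by clustering,
while late steps gain several-fold: the signature of substrate channeling
through enzyme clusters.

A `metabolon` command-line interface wraps the same functions
(`metabolon ppi cluster-test`, `metabolon overlap run`,
`metabolon codon expand VDS --positions 85`, `metabolon sim run`,
`metabolon pipeline cluster_analysis`, …); every stochastic command takes
`--seed`.

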