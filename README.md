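# pstfst

Population-genetic and quantitative-trait differentiation analysis for
fragmented plant populations scored with **dominant markers** (ISSR/AFLP
presence–absence profiles) and measured for **field phenotypes**.

Conservation studies of rare, fragmented species often have exactly two
kinds of data: multilocus 0/1 band profiles from a fingerprinting assay,
and morphological traits measured in the wild. `pstfst` turns those into
the standard differentiation workup:

- per-population diversity (%P, Nei's gene diversity H and its unbiased
  variant, private bands) and the gene-diversity partition
  (H_T, H_S, G_ST) with the island-model gene-flow estimate Nm;
- **F_ST** from dominant band data under Hardy–Weinberg equilibrium and a
  non-uniform (Beta) distribution of allele frequencies, with a
  locus-bootstrap CI and a permutation test;
- hierarchical **AMOVA** (regions / populations / individuals) with
  Φ-statistics and permutation p-values;
- Nei–Li (1 − Dice) distances between individual profiles;
- **P_ST**, the phenotypic surrogate of Q_ST,
  `P_ST = cσ²_B / (cσ²_B + 2h²σ²_W)`, pairwise and overall, with a 95%
  interval, the c/h² sensitivity curve and critical ratio r*, and the
  P_ST-vs-F_ST comparison that separates drift, directional selection and
  stabilising (convergent) selection;
- Mantel permutation tests, Holm multiple-testing correction, and the
  Evanno ΔK statistic for choosing the number of genetic clusters from
  external clustering log-likelihoods;
- a **synthetic-data generator** (Beta F-model markers + random-effects
  traits) with known ground truth, so the whole pipeline is testable
  end-to-end without any field data.

The comparison at the core: F_ST measures neutral divergence, P_ST
measures phenotypic divergence. `P_ST ≈ F_ST` is compatible with drift,
`P_ST > F_ST` indicates directional selection, and `P_ST < F_ST` —
phenotypes more similar than neutral divergence predicts — indicates
stabilising selection, i.e. no local adaptation in the measured traits.
Because c and h² are unknowable in the field, the comparison is swept over
the ratio `r = c/h² ∈ (0, 1]` starting from the null `c = h²`.

## Worked example

```python
from pstfst import (SimulationConfig, simulate_dataset, fst_wright,
                    pairwise_pst, pst_fst_comparison)

cfg = SimulationConfig(seed=42)   # 10 pops, 151 individuals, 171 loci, F = 0.365
ds = simulate_dataset(cfg)

fst = fst_wright(ds.markers, n_boot=1000, n_perm=1000, seed=42)
print(f"F_ST = {fst.fst_overall:.3f} "
      f"(95% CI {fst.ci95[0]:.3f}-{fst.ci95[1]:.3f}, p = {fst.perm_p:.4f})")

pst = pairwise_pst(ds.traits, n_boot=2000, seed=43)
print(f"P_ST(total) = {pst.overall:.3f} "
      f"(95% CI {pst.ci95[0]:.3f}-{pst.ci95[1]:.3f})")

comp = pst_fst_comparison(pst.pair_average.condensed(),
                          fst.fst_pairwise.condensed())
print(f"ANOVA: F(1,{comp.df[1]}) = {comp.F:.2f}, p = {comp.p:.2e} "
      f"-> {comp.classification}")
```

prints

```
F_ST = 0.385 (95% CI 0.358-0.410, p = 0.0010)
P_ST(total) = 0.200 (95% CI 0.167-0.315)
ANOVA: F(1,88) = 435.80, p = 7.61e-36 -> stabilising
```

The simulated neutral differentiation (generating F = 0.365) is recovered
by the marker estimator; the traits were generated with
σ²_B = 0.41, σ²_W = 1, i.e. an expected P_ST of 0.17, so phenotypic
divergence sits far below neutral divergence and the 45-pair comparison
classifies the regime as stabilising selection — the signature of
phenotypic similarity maintained across genetically isolated populations.

## Command line

Every stage is also a subcommand over the same library:

```bash
pstfst simulate --seed 1 --outdir demo            # synthetic dataset + truth sidecar
pstfst diversity demo/markers.tsv                 # %P, H, UH, private bands
pstfst fst demo/markers.tsv --seed 1              # F_ST, CI, permutation p
pstfst amova demo/markers.tsv --seed 1            # variance components, Phi_ST
pstfst pst demo/traits.tsv --seed 1               # pairwise/overall P_ST
pstfst mantel fst_pairwise.phy demo/geo_distance.phy
pstfst run-all run.yaml                           # full report bundle from YAML
```

Input formats are plain delimited text (rows = individuals; first columns
id, population, optional region) and Phylip-style square matrices; every
result table is TSV with a provenance header, and `run-all` writes a JSON
manifest (version, seed, every statistical flag) from which the whole
bundle can be reproduced.

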