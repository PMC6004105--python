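# Methods

`pstfst` implements the statistical core of a population-differentiation
study on dominant fingerprinting markers (ISSR/AFLP-style presence/absence
profiles) and field-measured quantitative traits: per-population
diversity, Wright-style F_ST, hierarchical AMOVA, the phenotypic
differentiation index P_ST with its c/h² sensitivity analysis, and the
permutation utilities (Mantel tests, Holm correction, Evanno ΔK) that
surround such an analysis. This note records the models, the estimators,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Dominant markers and allele frequencies

A dominant marker is scored only as band present (1) or absent (0); the
band-absent phenotype is the recessive homozygote, so under Hardy–Weinberg
equilibrium the observed band-absence frequency is `x = q²` for
null-allele frequency `q`. Three per-cell estimators of `q` are provided:

- `sqrt` — `q̂ = √(m/n)` for `m` absences among `n` individuals;
- `lynch_milligan` — the Taylor bias correction
  `q̂ = √x̄ · (1 − Var(x̄)/(8x̄²))⁻¹` with `Var(x̄) = x̄(1−x̄)/n`. Because the
  correction diverges as `x̄ → 0`, cells with fewer than 3 band-absent
  individuals fall back to the square-root path and are flagged
  (`pruned`);
- `bayes_nonuniform` — an empirical-Bayes posterior mean. A Beta(a, b)
  prior on `x` is fitted across loci by method of moments
  (`fit_beta_prior`; parameters clipped to ≥ 0.01, and a zero-variance
  input raises with instructions to fall back to the uniform prior);
  the posterior after `m` absences in `n` individuals is
  Beta(a+m, b+n−m) and `q̂ = E[√x] = B(a+m+½, b+n−m)/B(a+m, b+n−m)`,
  evaluated through log-Beta functions for numerical stability.

Diversity summaries use these frequencies: percent polymorphic loci (a
locus counts as polymorphic in a population when its presence frequency is
strictly between 0 and 1; the 95%/99% conventions are available through
`polymorphism_criterion`), Nei gene diversity `H = mean over loci of
2p̂q̂`, its unbiased variant `UH = H·2n/(2n−1)` applied per locus with the
locus-specific non-missing `n`, and private bands (loci present in exactly
one population). The gene-diversity partition reports `H_T`, `H_S`,
`G_ST = (H_T − H_S)/H_T` aggregated as a ratio of locus sums (Nei's
convention; stable when per-locus `H_T` is small) and the island-model
gene-flow estimate `Nm = ½(1 − G_ST)/G_ST`, undefined at `G_ST = 0`.

## F_ST: the Beta F-model moment estimator

The default `fst_wright` method (`beta_fmodel`) treats the population
frequencies at each locus as draws from a Beta distribution around an
ancestral frequency `q₀`:

    q_i ~ Beta(q₀(1−F)/F, (1−q₀)(1−F)/F),

whose among-population variance is exactly `F·q₀(1−q₀)` — the F-model, in
which the dispersion parameter *is* F_ST. This is the same "non-uniform
distribution of allele frequencies under Hardy–Weinberg equilibrium"
assumption that Bayesian dominant-marker F_ST methods make; here it is
fitted by method of moments on the scale the data actually live on, the
band-absence frequency `x = q²`:

1. per locus, the mean `A = mean_i(x̂_i)` and the noise-corrected
   among-population variance `V̂ = s²(x̂) − mean_i[x̂(1−x̂)/(n_i−1)]` are
   computed (both moments of `x` are unbiasedly estimable from binomial
   counts, which moments of `q` itself are not);
2. given F, the locus's ancestral frequency solves
   `E[q²] = (νq₀² + q₀)/(ν+1) = A` in closed form (`ν = (1−F)/F`), and the
   model's among-population variance of `x` follows from the Beta rising
   factorials, `Var(x) = E[q⁴] − E[q²]²`;
3. F is the root of `Σ_l VarModel(A_l, F) = Σ_l V̂_l`, found by bisection
   (the left side is increasing in F); the sum over loci plays the role of
   the ratio-of-locus-sums aggregation of classical G_ST;
4. because `VarModel` is concave in `A`, evaluating it at the noisy
   plug-in `Â` would bias the fitted F upward; a second-order Taylor
   correction `−½·Var(Â)·∂²VarModel/∂A²` (finite differences,
   `Var(Â) = s²(x̂)/k`) removes this.

Why not the textbook partition `(H_T − H_S)/H_T` of per-population `q̂`
estimates? The square-root transform is not linear: its mean function
`E[q̂ | q]` has regions of slope > 1, so the among-population variance of
`q̂` exceeds the variance of `q` even after subtracting any sampling
variance — an irreducible bias of order +0.03 to +0.06 at the default
study scale (10 populations × 15 individuals), which we verified by exact
binomial enumeration. The moment fit on the `x` scale avoids the
transform entirely; its measured recovery error over seeded F-model
replicates at the study scale is below 0.002 across F ∈ [0.05, 0.6]. The
partition estimators remain available (`method="sqrt"`,
`"lynch_milligan"`, `"bayes_nonuniform"`) for comparability with legacy
software, with the caveat above.

Pairwise F_ST applies the same fit to each population pair. Negative raw
partition estimates are truncated to 0 for reporting with the raw value
retained. The 95% CI is a percentile bootstrap over loci (default 1000
replicates, refitting F per replicate); the p-value permutes individuals
among populations (default 10 000) with `p = (#{F* ≥ F̂} + 1)/(n_perm+1)`.
One integer seed drives both streams through independent spawned
generators.

## AMOVA

For 0/1 profiles the squared Euclidean distance is the mismatch count;
missing cells are handled by rescaling the mismatch count over mutually
scored loci by `n_loci/n_shared` (an explicit, testable rule). Sums of
squares follow the standard distance form
(`SS_total = Σ_{i<j} d²_ij / N`, within-stratum sums analogous per group),
and variance components come from the expected-mean-square equations with
the unequal-sample-size coefficients (`n₀` one-level; `n₁, n₂, n₃`
two-level). The tests cross-check both against an independent oracle that
derives the EMS coefficients numerically from trace identities
`E[x'Ax] = tr(A·Cov)` and solves the linear system with `numpy`.

Φ_ST, Φ_SC and Φ_RT are ratios of the raw (untruncated) components;
components are truncated to zero only for the reported percentages, with
raw values retained. Permutation schemes follow the hierarchy: individuals
among populations (Φ_ST), individuals among populations within regions
(Φ_SC), whole populations among regions (Φ_RT); default `n_perm = 999`. A
two-level design with a single region collapses exactly to the one-level
analysis. All-identical profiles yield zero components and an undefined
(NaN) Φ, flagged rather than raised.

## P_ST

For a trait with between-population variance component σ²_B and
within-population component σ²_W,

    P_ST = c·σ²_B / (c·σ²_B + 2·h²·σ²_W),

with heritability h² and the fraction c of between-population variance
that is additive-genetic; only `r = c/h²` enters, and the headline value
uses the null assumption `c = h²` (r = 1). Components come from one-way
random-effects ANOVA: `σ̂²_W = MS_W`,
`σ̂²_B = max(0, (MS_B − MS_W)/n₀)` with
`n₀ = (N − Σn_i²/N)/(k−1)`; groups with fewer than two non-missing values
are dropped per trait (pairwise, not globally), so sparsely measured
populations still contribute where they can.

Two summaries are computed and deliberately kept distinct:

- **Pairwise P_ST** per trait and population pair (components from the two
  populations only), the per-pair trait average, and their mean. These 45
  pair-level values are what enters the pairwise P_ST-vs-F_ST one-way
  ANOVA (two groups of 45, df = 1 and 88) and the Mantel tests. But as an
  estimator of the generating differentiation the mean over pairs is
  inconsistent: each pair's MS_B has a single degree of freedom, and the
  mean of the concave P_ST transform of χ²₁-distributed components
  converges to a value well below the true P_ST (≈ 0.24 when the truth is
  1/3 in our generator's regime).
- **Overall P_ST** therefore uses the all-population components per trait,
  averaged over traits. Its 95% interval comes from the exact F-pivot of
  the one-way ANOVA: per trait, confidence-distribution draws of the
  variance ratio `λ = F_obs/F*` with `F* ~ F(k−1, N−k)` are mapped through
  `ρ = (λ−1)/n₀` (truncated at 0) and the P_ST formula, then averaged
  across traits and summarised by percentiles. This interval is exact for
  a single trait and, unlike a bootstrap over individuals, carries the
  between-population sampling of the population effects — the dominant
  source of uncertainty with ten populations. In calibration runs
  (100 seeded replicates, 10 populations × 50 individuals, σ²_B = σ²_W = 1)
  it covered the generating value 96 times, against 2/100 for an
  individuals-within-populations bootstrap.

The sensitivity analysis sweeps `r` over (0, 1] (default grid 0.01–1.00 in
steps of 0.01): `P_ST(r) = rσ²_B/(rσ²_B + 2σ²_W)` is non-decreasing in r,
and the critical ratio solving `P_ST(r*) = F` against the lower 95% bound
F of F_ST is `r* = 2σ²_W·F/((1−F)σ²_B)`, reported as absent when it
exceeds 1 or σ²_B = 0. The pipeline's overall curve applies the formula to
the per-trait all-population components and averages traits; its r* is the
smallest grid ratio at which the curve exceeds the F_ST lower bound.
Classification of the pairwise comparison follows the standard reading:
significantly lower P_ST → stabilising (convergent) selection,
significantly higher → directional selection, otherwise drift
(α = 0.05).

Count traits are used untransformed by default (`log1p` is a caller-side
choice); P_ST is scale-invariant per trait, so units do not matter.

## Resampling utilities

**Mantel.** `r_M` is the Pearson correlation of the upper-triangle entries
after aligning the second matrix by labels; the null permutes its rows and
columns simultaneously. The default tail is two-sided (`|r| ≥ |r_obs|`)
since the direction is rarely prespecified; one-sided `greater` is
available. For n ≤ 7 (or whenever `n! ≤ n_perm`) the full permutation set
is enumerated and the exact proportion reported; otherwise
`p = (count + 1)/(n_perm + 1)` over sampled permutations (default 9 999),
with ties handled by a 1e-12 slack so exact duplicates count. Constant
matrices are rejected.

**Holm.** Step-down family-wise adjustment, delegated to
`statsmodels.stats.multitest.multipletests(method="holm")`; families are
user-supplied groupings, never inferred.

**Evanno ΔK.** Consumes an external table of clustering log-likelihoods
(K, replicate, lnP); the admixture inference itself is out of scope. For
interior K, `ΔK = mean over replicates |L(K−1) − 2L(K) + L(K+1)| / sd[L(K)]`,
with replicates aligned by the `replicate` column (or input order) when
counts are equal, and second differences of the K-means otherwise. Zero
replicate standard deviation flags ΔK undefined at that K.

## Synthetic data

`simulate_markers` draws, per locus, an ancestral null-allele frequency
`q₀ ~ Beta(q̄θ, (1−q̄)θ)` and per-population frequencies from the F-model
above, then Bernoulli band-absence with probability `q_i²`. The generator
therefore pins the exact F the marker estimators should recover, which is
all they can see — no coalescent history, migration, linkage or selection
is modelled. `simulate_traits` draws population effects
`~ Normal(0, σ²_B)` and individual deviations `~ Normal(0, σ²_W)` per
trait, so the generating overall P_ST at c = h² = 1 is
`σ²_B/(σ²_B + 2σ²_W)`; phenotypes are not decomposed into additive and
environmental parts because P_ST estimation never observes h².
`simulate_dataset` adds population coordinates and an environmental
distance matrix whose coupling to the realised genetic divergence is set
by `env_corr` (0 = independent, 1 = an exact monotone function; geography
uses a classical-MDS embedding blended with random positions).

Defaults mirror a ten-population field study: sample sizes
(18, 8, 10, 15, 14, 13, 20, 13, 20, 20) (151 individuals), 171 loci,
F = 0.365, 7 traits on heterogeneous plant-like scales, σ²_B = 0.41,
σ²_W = 1 (expected P_ST ≈ 0.17), q̄ = 0.75 and θ = 2 — chosen so the
simulated diversity tables (≈ 40% polymorphic loci, H ≈ 0.11–0.15, a few
private bands per population) look like real ISSR data on a rare herb —
and `env_corr = 0`. Passing tests on these data demonstrate estimator
correctness under the stated models; they cannot certify behaviour under
features the generator omits (scoring error, linked loci, non-Gaussian
traits, genotype-environment correlation).

All generators and resampling streams are driven by
`numpy.random.default_rng` from a single seed (sub-streams spawned
deterministically), so every table is bit-reproducible.

## Problem sizes used in the self-checks

The test suite and the acceptance script size their simulations to the
defaults above: F_ST recovery uses 50 replicates of 10 × 15 × 171 at
F ∈ {0.1, 0.365} (tolerance 0.02 on the mean), P_ST coverage uses 100
replicates of 10 × 50 with 1000 confidence draws (≥ 90/100 required),
type-I-error calibration uses 500 null replicates with 199 permutations
each (acceptance band 0.03–0.07 at α = 0.05), and all brute-force oracle
comparisons are exact to 1e-9 on small instances.

## Known limitations

- The F-model moment estimator assumes Beta-distributed population
  frequencies; under strong non-Beta structure (e.g. recent admixture) it
  still returns the best-matching dispersion, which may differ from
  heterozygosity-based definitions of F_ST.
- The `bayes_nonuniform` per-cell estimator fits one prior across all
  population × locus cells; with few loci the method-of-moments fit is
  rough, and the code falls back to the uniform prior when the fit fails.
- AMOVA supports at most two hierarchy levels, matching the
  regions/populations/individuals design.
- Overall P_ST inference assumes the one-way random-effects model per
  trait (Gaussian population effects); h² and c are always user inputs,
  never estimated.
- The Mantel test treats distances as exchangeable under the null;
  spatially autocorrelated non-independence is not modelled.
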