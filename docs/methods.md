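# Methods

## The analysis model

The package targets unreplicated multi-environment trials of multiparent
doubled-haploid (DH) populations: every line is observed once per
treatment and year. All phenotype modelling starts from the mixed model

    y_ijk = μ + L_i + T_j + Y_k + (LT)_ij + ε_ijk,

with line, year and line×treatment random and treatment fixed. Three
consequences of the unreplicated design shape the implementation:

* **Variance components per treatment.** Within one treatment the data form
  a line × year table with one observation per cell, so the line×year
  interaction and the residual cannot be separated. `fit_variance_components`
  reports their sum as V_E with V_GY = 0 and a `confounded` flag. The
  heritability denominator V_G + V_GY/y + V_E/y is unaffected — only the
  split between its last two terms is. With replicated cells all three
  components are estimated. Balanced layouts use the closed-form ANOVA
  (expected-mean-squares) estimators, which coincide with REML whenever the
  solution is interior; negative solutions are truncated at zero.
  Unbalanced layouts use an EM-REML iteration on the mixed-model equations
  (tolerance 1e-6 relative to the phenotypic variance, max 2000 iterations,
  boundary components pinned at zero; convergence state is returned).

* **BLUPs per treatment-year.** The random-intercept model y = μ + L + ε is
  degenerate when every line has a single record: only σ²_g + σ²_e is
  identified and the likelihood is flat along the split. The fitter adopts
  the boundary convention σ²_e = 0, so BLUPs equal raw deviations from the
  stratum mean (`identified=False` marks this). With replication the usual
  shrinkage σ²_g/(σ²_g + σ²_e/n) applies. Scan responses are the
  per-treatment-year BLUPs averaged over years.

* **LSmeans** reduce to per-line marginal means over years (the design has
  no further covariates in scope); correlations are pairwise-complete
  Pearson with per-pair n reported.

The stress tolerance index STI = y_p·y_s/ȳ_p² is computed per line and
year with a year-specific control mean ȳ_p; a pooled-mean variant would
only rescale years jointly and is intentionally not the default.

## The multilocus scan

Each marker is tested by a sequential (Type-I) F-test: cofactors first,
the candidate marker last, on mean-imputed genotype columns. Forward
selection admits, per iteration, the smallest-P marker that passes three
gates simultaneously — nominal P ≤ α (default 0.001), Benjamini–Hochberg
adjusted P ≤ 0.05 across the markers tested in that iteration, and the
genome-wide permutation threshold. The conjunction is the conservative
reading of a protocol that names all three criteria in one breath; any
single gate can be disabled by setting its level to 1.

The permutation threshold is the empirical α-quantile of the genome-wide
minimum P over `n_perm` response permutations (default 1000). By default it
is computed once at the first iteration, with no cofactors, and reused in
later iterations; recomputing per iteration (`perm_each_iteration`) is
supported but roughly multiplies scan cost by the number of iterations
while changing results only marginally, since later-iteration nulls are
slightly less extreme. Permutations shuffle the response across lines, not
residuals.

Ties in the selection (equal P) break by larger F, then lower map position
(chromosome block order, then cM), then marker id; with continuous
responses ties are essentially impossible, but the rule makes runs
reproducible byte for byte.

The marker×treatment scan stacks the two treatments' responses with a
treatment indicator and tests M×T entered after M in
y = μ + M + T + M×T + ε. Selected markers contribute both their main and
interaction columns as cofactors. Its permutation null permutes line
labels, keeping each line's WW/TD pair together, which preserves the
treatment main effect while destroying any marker association.

Cross-validation refits the selected model on random 80% subsets
(20 rounds) and reports each marker's mean sequential P in selection
order; the retention rule mean-P ≤ α is configurable. The cofactor set is
fixed from the full-data scan (only coefficients are refit), the cheaper
and more stable of the two possible conventions.

Explained variance follows sequential sums of squares in selection order:
R²_M = SQ_M/SQ_g with SQ_g the total (line) sum of squares of the
response; the total is the sum over selected markers. For the interaction
scan the numerator is the interaction term's sequential SS over the
stacked-response total SS.

Degrees of freedom are those of the ordinary least-squares fit; no attempt
is made to replicate any particular mixed-procedure denominator-df
approximation.

## Post-processing

Significant first-iteration markers are clustered per chromosome with
single linkage at the 7 cM comparison window; each cluster's peak (lowest
P) defines a QTL with confidence interval peak ± 3.5 cM clipped to the
chromosome's mapped extent. The 3.5 cM half-width and 7 cM window reflect
the linkage-disequilibrium scale of dense MAGIC maps. Colocalization of
QTL across traits and contexts uses the same single-linkage rule; chains
(0–6–12 cM merging into one cluster) are a documented consequence of
pairwise position comparison, verified against a transitive-closure oracle.

Founder allelic effects are group-mean deviations: mean response of a
founder class's carriers minus the overall mean, with group sizes and SEs;
the carrier-weighted effects sum to zero identically. Classes with fewer
than three carriers are flagged low-confidence. Founders with identical
allele vectors (e.g. a deliberately cloned founder pair) are merged into
one class because no marker can distinguish them. A joint-regression
estimator is provided as an option; at a single locus with no covariates
it coincides with the group means.

## The simulator

The generator emulates the study population: 534 DH lines from a balanced
eight-way funnel (four two-way crosses, two four-way, one eight-way; the
same funnel order for all lines, fresh gametes per line at each
generation), seven chromosomes totalling 1000 cM with one marker per
0.191 cM (~5200 SNPs), founder-level minor-allele frequencies drawn in
[0.125, 0.5], 2% random missingness followed by the MAF ≥ 1% / <10%
missing filter, and seven traits × two treatments × two years whose means,
dispersions and heritabilities echo the published descriptive table.
Variance components were derived once from (SD, H²) per trait with year
and line×treatment terms each at 5% of the phenotypic variance and
V_E = 2·V_G·(1−H²)/H² for two unreplicated years. Planted QTL sit at loci
reported for this population (e.g. a +6.23 g TKW effect of the Ragusa
haplotype on 2H near 19.9 cM, with smaller effects and
treatment interactions elsewhere).

Meiosis follows the Haldane (no-interference) map function: adjacent
markers d cM apart recombine with probability (1 − e^(−2d/100))/2, and
each chromosome starts from a uniformly chosen strand. The map function is
isolated in one helper so Kosambi could be added. DH lines double a single
gamete of the eight-way F1, skipping selfing-generation bookkeeping — a
stated simplification adequate for mosaic structure, not an inference
about the real population's pedigree. Genotypes are coded 0/2
(minor/major homozygote); heterozygotes cannot occur.

What the generator does **not** emulate: row/column field trends and
augmented-design check structure, genotyping error, epistasis, selection
during DH production, and population structure (the funnel yields balanced
founder proportions by construction). Passing tests therefore demonstrate
correctness of the estimators and the scan's operating characteristics
under the stated generative model, not robustness to those real-data
complications.

A consequence worth knowing: biallelic SNPs tag an eight-founder haplotype
imperfectly (several founders usually share the minor allele), so planted
founder-specific effects of moderate size — especially
treatment-interaction effects — may not clear the conservative triple
gate at study scale. The default simulation consequently yields few or no
M×T calls even though interactions are planted; the M×T machinery's power
is demonstrated separately in the test suite with marker-aligned effects.

## Numerical choices

* Column-mean imputation of missing genotypes before testing.
* Rank-revealing QR bases for cofactor projection; markers numerically
  constant or collinear after projection are skipped with a reason, never
  silently tested.
* All scan randomness flows from one seeded generator per run
  (`numpy.random.SeedSequence`); the pipeline derives one sub-seed per
  (context, trait) so stages are individually reproducible and
  re-running a run configuration is byte-identical.
* Empirical quantiles via `numpy.quantile` (linear interpolation); with
  1000 permutations at α = 0.001 the threshold sits at the extreme order
  statistic, which is exactly as stringent as the protocol demands.

## Problem sizes in the tests

Unit tests run on small maps (tens to hundreds of markers) where oracles
are exact. The statistical suites use: heritability recovery at 534 lines
× 2 years × 50 replicates; type-I error on 100 null replicates of 500
lines × 500 markers with 200 permutations; power on 100 replicates at 534
lines with a 10%-variance QTL; greedy-oracle equivalence on 200 instances
of ≤10 markers; BH and colocalization oracles on 1000 and 500 random
inputs. The acceptance script runs the full pipeline at study scale
(534 × ~5200, 1000 permutations) plus the two calibration experiments.

## Known limitations

* No kinship or population-structure correction (the motivating population
  shows none; other populations may need it).
* The EM-REML fallback is robust but slow on large unbalanced layouts;
  balanced data never touch it.
* Founder effects are marginal group means, not joint multi-locus
  estimates; closely linked QTL can leak into each other's founder tables.
* The interval rule (contiguous significant markers, single linkage at
  7 cM) is one defensible reading of "clustering by first-iteration
  significance"; the gap criterion is a package choice and configurable.
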