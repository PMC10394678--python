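# magicscan

QTL mapping for multiparent (MAGIC) doubled-haploid populations evaluated
under contrasting treatments — for plant geneticists and breeders who need a
transparent, reproducible reimplementation of the classic multilocus
forward-selection genome scan, together with the phenotype statistics that
feed it and a funnel-cross simulator that provides ground-truth data for
validation.

The motivating design is a spring barley MAGIC population: 534 DH lines
from an eight-way funnel cross of seven German landraces and the cultivar
Barke, genotyped at ~5200 SNPs (one per 0.191 cM) and phenotyped for seven
yield-related traits under well-watered (WW) and late-terminal drought (TD)
treatment in two years.

## What it computes

**Phenotype statistics.** For each trait and treatment: descriptive
statistics (mean, min, max, SE, SD, CV = 100·SD/mean), REML/ANOVA variance
components for

    y_ijk = μ + L_i + Y_k + (LY)_ik + ε_ijk     (line, year random)

and broad-sense heritability

    H² = V_G / (V_G + V_GY / y + V_E / y),

per-treatment-year line BLUPs from the random-intercept model
y = μ + L + ε, trait LSmeans and Pearson correlations, and the stress
tolerance index STI = (y_p · y_s) / ȳ_p², where y_p and y_s are a line's
values under control and stress and ȳ_p is the control mean.

**Multilocus genome scan.** Single-marker F-tests in the fixed model
y = μ + M (+ T + M×T for the interaction scan), embedded in a forward
selection: at each iteration every unselected marker is tested with the
current selection as cofactors (sequential/Type-I order), and the most
informative marker is admitted only if it passes all of

* nominal P ≤ 0.001,
* Benjamini–Hochberg FDR-adjusted P ≤ 0.05,
* the genome-wide permutation threshold (α-quantile of the min-P null
  distribution over 1000 response permutations).

Selected QTL are validated by 20 rounds of leave-20%-out cross-validation
(mean refit P), and their explained variance reported as
R²_M = SQ_M / SQ_g (sequential sums of squares over the total line sum of
squares).

**Post-processing.** QTL intervals of ±3.5 cM around each peak,
colocalization of peaks across traits/treatments by single linkage within a
7 cM window, and founder allelic effects at each peak (mean response of the
lines carrying a founder's haplotype, as a deviation from the population
mean; founders sharing a haplotype are merged).

**Simulator.** Founder alleles → funnel meiosis under the Haldane map
function r = (1 − e^(−2d/100))/2 → DH derivation by doubling one gamete of
the eight-way F1 → genotype degradation (missingness, MAF ≥ 1% filter) →
phenotypes from a mixed model with planted QTL, treatment, year,
line×treatment and residual terms. Every downstream stage is tested against
this known ground truth.

## Worked example

```python
import magicscan as ms
from magicscan.phenostats import blup_matrix
from magicscan.postprocess import founder_allelic_effects

ds = ms.simulate_dataset(seed=1)                      # 534 lines, ~5200 SNPs
y = blup_matrix(ds.phenotypes, "TKW", "WW")           # scan response
res = ms.forward_multilocus_scan(y, ds.genotypes, ms.ScanConfig(seed=1), ds.gmap)
print(res.selected[["marker_id", "chromosome", "position_cM", "F", "P", "R2M"]]
      .to_string(index=False))
print(f"permutation threshold: {res.perm_threshold:.3e}; total R2: {res.total_r2:.3f}")
eff = founder_allelic_effects(ds.mosaic, y, res.selected["marker_id"].iloc[0],
                              ds.founder_alleles)
print(eff.to_string(index=False))
```

Output:

```
marker_id chromosome  position_cM         F            P      R2M
2H_m00120         2H    22.911695 84.878045 7.311432e-19 0.137593
permutation threshold: 9.766e-08; total R2: 0.138

  founder_class    effect  n_carriers       se  low_confidence
   Ack. Bavaria -1.371985          72 0.624346           False
   Ack. Danubia  0.577093          62 0.718522           False
      Criewener -2.198603          72 0.651815           False
  Heils Franken -0.693216          75 0.640322           False
   Heines Hanna -0.023862          60 0.823275           False
Pflugs Intensiv -2.142430          72 0.691559           False
         Ragusa  5.511659          78 0.632532           False
          Barke -0.021603          43 0.756162           False
```

The default simulation plants a thousand-kernel-weight QTL on chromosome 2H
near 19.9 cM whose Ragusa allele raises TKW by +6.23 g. The scan localizes
it 3 cM away (well inside the ±3.5 cM confidence interval), it explains
13.8% of the BLUP variance, and the founder-effect table recovers the
Ragusa haplotype at +5.51 g versus the population mean — close to the
planted deviation 6.23 × 7/8 ≈ 5.45 g, since carriers are ~1/8 of lines.

The same analyses are available from the shell:

```sh
magicscan simulate --seed 1 --out data/
magicscan scan --genotypes data/genotypes.tsv --map data/map.tsv \
    --phenotypes data/phenotypes.tsv --trait TKW --treatment WW --out results/
magicscan pipeline --config run.yaml     # every stage, ten result TSVs
```

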