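# Methods

This note documents the models and procedures `alumet` implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions at the edges. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

Input is a processed gene-level intensity matrix (genes × samples) with
explicit missing values and a case/control label per sample — the form
in which public microarray series are deposited. Normalization, batch
correction and probe-level preprocessing are out of scope; the model
assumes the deposited matrix is already comparable across samples.

**Presence filter.** A gene is retained when its intensity is observed
in at least a `cutoff` fraction of *all* samples (default 0.70, i.e. the
filter removes genes missing in strictly more than 30% of samples; the
70%-present boundary is inclusive). The fraction is computed jointly
over both groups, not per group. Filtering happens before testing and
never changes the p-value of a retained gene, because missing entries
are omitted pairwise rather than imputed.

**Test.** Per gene, a two-tailed two-sample *t*-test on the non-missing
values. The default is Student's pooled-variance statistic — the
historical default of the microarray tools this stage mirrors — with
Welch available via `equal_var=False`. Degenerate genes follow fixed
conventions: both groups constant and equal → p = 1; constant but
different → p = 0; fewer than two observations in either group → the
gene is excluded from testing, flagged, and does not count toward the
multiplicity burden. Bonferroni adjustment uses m = number of genes
actually tested; a gene is a DEG when the adjusted p falls below `alpha`
(default 0.05). Direction is the sign of mean(case) − mean(control).

Inputs are assumed gene-level. Where probe-level tables exist,
`collapse_probes` keeps each gene's smallest-raw-p probe; it is off the
default path because probe handling is platform-specific.

## Alu-insertion enrichment

The annotation maps uppercased gene symbols to insertion types
(exonic, exonized, intronic, promoter); a gene may carry several types,
so the distinct-gene count under "all" is below the per-type sum. Gene
identity is the uppercased symbol with no alias resolution — symbol
matching across array annotations and the insertion lists is assumed.
Genes absent from the annotation count as "without Alu": membership is
positive evidence only.

For each stratum (5 insertion types × 3 directions = 15 by default) the
2×2 table is a = |DEG ∩ Alu|, b = |DEG \ Alu|, c = |Alu \ DEG|,
d = remainder, over the **universe of tested genes of that study** —
enrichment must condition on testability, so the background is the
post-filter tested set, not the whole annotation. Significance uses the
two-sided Fisher exact test with BH adjustment across the 15 strata of
one study (mirroring per-study correction). A stratum with no DEGs is
reported with p = 1 and an `empty` flag rather than dropped.

**Reproducible gene set.** The default reproducibility analysis
intersects, across studies, the downregulated DEG lists restricted to
Alu-inserted genes, including a study only when its down × all-insertion
stratum is significant, and keeps genes supported by at least
`min_support = 2` studies. All three choices (direction, insertion type,
support threshold) are exposed.

## Exact statistics

The inferential core is implemented in-package (`alumet.stats`) so it
can be audited and enumerated against oracles; scipy/statsmodels
equivalents serve only as independent cross-checks in the tests.

- **Fisher two-sided p**: the minimum-likelihood rule — sum of
  hypergeometric probabilities of all same-margin tables whose point
  probability is ≤ the observed one, with a 1e−7 relative tolerance so
  float round-off cannot split exact ties; log-gamma factorials keep
  totals of 1e5+ stable. Any zero margin returns p = 1 (no association
  testable). Mid-p and doubling conventions exist in the literature;
  the minimum-likelihood rule is the convention of the mainstream
  implementations this pipeline is meant to reproduce.
- **Benjamini–Hochberg**: step-up q_(i) = min_{j≥i} min(1, p_(j)·m/j)
  with stable tie-breaking, returned in input order. Bonferroni
  dominates BH entrywise (a tested invariant).
- **Pearson r**: the product-moment coefficient; a constant vector
  raises `ZeroVarianceError` rather than returning a number.

## COBRA quantification

The assay interrogates two CpG loci in the AluS internal promoter.
After bisulfite conversion and PCR, TaqI (TCGA) cuts only sites whose
CpG was methylated, so the four joint states map to fragments:
uCuC → 133; mCuC → 90 + 43; uCmC → 75 + 58; mCmC → 43 + 32 + 58 (bp).

Band-intensity shares (percent of lane) are divided by fragment length —
intensity is mass-proportional for intercalating stains, so the quotient
is a relative molar quantity — giving A..F, and the printed estimator is
evaluated verbatim (see README for the five formulas). Two properties
motivate implementing it exactly as printed:

- The pattern denominator A + C + D + F counts every molecule exactly
  once (133 for uu, 75 for um, 90 for mu, 32 for mm), so the four
  pattern percentages are a closed composition summing to 100 and equal
  the state fractions exactly on noise-free forward-simulated lanes.
- The %mC numerator (E + B) excludes the 32-bp band even though mCmC
  molecules also produce it; under the forward model
  %mC = 100·((p_mu + p_um)/2 + p_mm), exactly the fraction of
  methylated CpG loci (two per molecule). The printed formula is
  therefore followed rather than "corrected".

The identity %mC = (%mCuC + %uCmC)/2 + %mCmC holds on every noise-free
forward profile and is asserted in the tests. The forward simulator is
the estimator's oracle: 1000 random mixtures round-trip to < 1e−9.

Numerical conventions: lanes are validated non-negative and normalized
to shares summing to 100 (tolerance 1e−6); a lane with a vanishing
denominator (blank lane, or signal only in bands outside the
denominator) raises `BlankLaneError` instead of returning numbers. A
`stain='molar'` mode exists for count-proportional chemistries, and the
simulator-only `digestion_efficiency < 1` models incomplete TaqI
digestion to probe estimator bias (it biases %mC downward); the
estimator itself assumes complete digestion. Position-resolved Alu
methylation is out of scope — the assay averages over genomic copies.

## qPCR fold change

ΔCt = mean replicate Ct(AluS) − mean replicate Ct(GAPDH) per sample;
ΔΔCt subtracts the control-group mean ΔCt; relative expression is
2^−ΔΔCt. The group fold change is FC = 2^(−mean case ΔΔCt) — the
geometric mean of per-sample relative expression — because the published
FC/log2 pairs this stage reproduces (1.75/0.81 and 3.68/1.88) are
internally consistent with that definition; an arithmetic-mean-of-FC
alternative sits behind `aggregate='arithmetic'`. Group tests are
two-tailed *t*-tests on ΔCt (approximately normal), never on
exponentiated fold changes, with BH across the comparisons fitted
together. Amplification-efficiency correction and absolute
quantification are out of scope. Two algebraic invariants are tested:
a constant Ct shift applied to one assay across all samples leaves the
fold change unchanged, and swapping case/control labels maps FC to 1/FC.

## Integration

Group comparisons of the five methylation metrics use the same t-test
kernel, with the BH family being the five metrics of one comparison
(matching the per-comparison row structure of the motivating cohort
tables), not all comparisons pooled. Unpaired tests are used: the
cohorts are sex/age-matched at the group level and only group summaries
are modelled. Samples with an undefined metric are dropped for that
metric with a warning. Correlation with relative expression is Pearson
(the quantity reported in the field), with Spearman as an option since
gel-derived percentages may be non-normal; strata (e.g. one phenotypic
subgroup plus its matched controls) are explicit sample-id lists, and
n < 3 after filtering is an error.

## Synthetic-data generators

Defaults are the study conditions the pipeline targets; every generator
is a pure function of (parameters, seed) and returns its planted truth.

- **Annotation**: independent per-type membership with frequencies
  0.95/0.12/0.06/0.04 (intronic/exonic/exonized/promoter) among
  Alu-insertable genes — the proportions of the public insertion-type
  lists. Expression universes mark 60% of genes Alu-inserted (≈13.5k of
  ~22k protein-coding genes).
- **Expression**: i.i.d. normal baseline (no gene–gene correlation —
  the t-test's implicit assumption; a planted-correlation stress mode
  was considered out of scope), 5% planted DEGs shifted by 3 pooled-SD
  units, 70% of them downregulated (downregulation dominates in the
  motivating data), with the downregulated set drawn with odds
  multiplier `alu_down_enrichment` for Alu genes (1 = enrichment null;
  3 = the planted-association condition). Missingness is completely at
  random (no mechanism is specified for the real data). Multi-study
  bundles share one annotation and force a common Alu-inserted
  downregulated core (default 50 genes) into every study.
- **COBRA cohorts**: group mixtures default to the published LCL group
  means renormalized to sum to one (control ≈ 33.8/21.8/18.7/25.7% for
  uu/mu/um/mm; subgroups M, L, S analogous). Per-sample mixtures are
  Dirichlet perturbations with concentration 2500 plus lognormal gel
  noise of CV 0.02, chosen so per-sample pattern SDs are ≈0.7–1.0
  percentage points — the spread the published n = 10 subgroup tables
  report. Cohort sizes default to 20 controls and 36 cases split
  10/6/20 into subgroups M/L/S.
- **Ct cohorts**: reference Ct ~ N(18, 0.3); true per-sample
  ΔCt = 5.0 − log2FC(group) + N(0, 0.25) biological noise; triplicates
  add N(0, 0.15) technical noise. The replicate SD is a typical qPCR
  technical spread; the biological SD of 0.25 cycles is a realistic
  between-sample spread chosen a priori (no published value exists for
  it). True subgroup log2FCs default to 0.06 (M), −1.77 (L), 1.88 (S).
- **Coupled cohort**: expression is an affine function of standardized
  %uCmC plus independent noise, so the population Pearson correlation
  equals the requested ρ (default 0.5149).

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: gene–gene correlation and batch
structure in expression matrices, platform-specific probe effects,
informative missingness, gel saturation/background subtraction
artifacts, bisulfite conversion failure, and qPCR efficiency drift.
Recovery and power results are statements about the estimators under
the stated noise model, not about any particular cohort.

## Problem sizes in the checks

The simulation-based checks use 100–200 replicates per operating
characteristic, 2000-gene universes for null calibration and 5000-gene
universes (20 vs 20 samples) for power, n = 10 vs 10 for the subgroup
power analyses and n = 20 for correlation sampling — sizes chosen to
keep Monte-Carlo error well below the asserted margins while the whole
suite stays fast. `scripts/acceptance.py` additionally enumerates all
2×2 tables with N ≤ 30 against a hypergeometric oracle (the test suite
goes to N ≤ 40).

## Known limitations

- Symbol-based gene matching will mis-join aliased symbols across
  annotation generations.
- Bonferroni over tested genes is conservative under correlated
  expression; the FWER simulation covers the independent case only.
- The COBRA estimator assumes complete digestion and mass-proportional
  staining; deviations bias %mC (the simulator can quantify this, the
  estimator does not correct it).
- The reproducibility step counts list membership; it does not pool
  effect sizes across studies.
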