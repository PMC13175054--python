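# Methods

## Scope and data model

The package analyses diploid microsatellite genotypes on a fixed autosomal
panel. A `GenotypeTable` stores, per animal: a barcode, a birth year, a
registered sex, a pair of sex-determination marker calls, and one ordered
pair of integer allele sizes (base pairs) per locus. Genotypes are
unordered; pairs are kept sorted ascending with the missing sentinel
first, so equality of the two values is the only heterozygosity test the
code ever performs. Sex markers are metadata: they drive one QC stage and
never enter any statistic, because the panel statistics are defined over
the autosomal loci only.

## QC cascade

Five stages run in a fixed canonical order: missing-call removal →
allele-range removal → sex-marker screening → duplicate-barcode
resolution → minimum-cohort filtering. The order matters (permuting
stages changes the counts, e.g. a record with both a missing call and a
sex anomaly is counted once, under the earlier stage) and is therefore
frozen; the report records every stage count and checks the exact
identity `final = raw − ii − iii − iv − dup_dropped + recovered − vi` on
every run. Design choices:

* **Sex rule** — females X/X, males X/Y (amelogenin-style reading);
  configurable because laboratories differ. Removal reasons are disjoint
  with priority OTHER value > missing value > registered-sex mismatch.
  `sex_rule: null` disables the stage (needed for Genepop input, which
  carries no sex).
* **Duplicates** — a multi-record barcode group merges to one record only
  if all members agree at every non-missing call and share birth year and
  registered sex; missing calls are filled from any member that has the
  call. Agreement is exact: no mismatch tolerance, because a genotyping
  tolerance would need an error model the pipeline does not assume. Two
  half-missing genotypes that could only be reconciled by guessing are
  treated as discordant. Discordant groups are dropped entirely.
* **Allele ranges** — inclusive bounds per locus, supplied as
  configuration (instrument calling windows are lab-specific, not
  constants).
* **Minimum cohort** — default 100 heads per birth year; yearly
  statistics on smaller cohorts are too noisy to plot on the same axes.

QC is idempotent: a second pass removes nothing.

## Diversity statistics

Frequencies use fully typed individuals only (after QC that is every
individual). `H_exp` defaults to the exact gene diversity `1 − Σp²`; the
`2N/(2N−1)` unbiased variant is available but changes nothing before the
fifth decimal at N in the hundreds of thousands. PIC uses the Botstein
form. Two F_IS estimators are reported side by side:

* the ratio form `(H_exp − H_obs)/H_exp`, and
* the Weir–Cockerham within-population `f = 1 − c/(b+c)`.

They disagree in the third decimal at realistic sample sizes (the WC form
weights loci and samples differently), which is visible when
reconstructing published mean rows; neither is forced to match the other.
The summary's mean row is the unweighted mean over loci, which is how
panel tables in this field print it.

## F-statistics

The normative between-cohort estimator is Weir & Cockerham (1984) θ from
per-allele variance components with the `n̄`/`n_c` sample-size weights, so
unequal cohorts need no subsampling. Multilocus and multi-allele
combination is always a ratio of sums, never a mean of ratios. `a` and
`b` are unbiased and may be negative; small negative θ̂ near zero is the
expected behaviour under no differentiation and is retained internally,
with an optional display floor at 0 for reports (matching the convention
that printed F_ST ranges start at 0). The Nei-style `(H_T − H_S)/H_T`
ratio is provided as a cross-check statistic; on large balanced samples it
tracks θ̂ with correlation > 0.99 across a drift grid, but the two are
different estimators and are never asserted equal. Pairwise matrices are
reported at 4 decimals.

Implementation note: components are assembled from per-cohort tallies
(sample sizes, allele counts, heterozygote-carrier counts) computed once
per cohort and locus, so the full pairwise matrix over 23 cohorts costs
the same as one pass over the data. The implementation is verified against
an independent scalar transcription of the published formulas and against
hand-frozen values on a 10-individual toy.

## Non-exclusion probabilities

All five NE values share one probability model: HWE genotypes, unrelated
candidates, zero genotyping error, exclusion on genotype incompatibility
only. Zero error is the simplest defensible default — an error rate is a
laboratory property the package cannot know, and the published combined
values are reproduced without one. The normative engine is exact
enumeration over unordered genotypes (k alleles → k(k+1)/2 genotypes;
candidate sums are exact genotype-mass algebra, not sampling), feasible to
k ≥ 30. For NE-I and NE-SI the closed forms

```
NE-I  = 2(Σp²)² − Σp⁴
NE-SI = 1/4 + (1/2)Σp² + (1/2)(Σp²)² − (1/4)Σp⁴
```

are evaluated on every call and must agree with the enumeration to 1e−12
— a permanent guard against formula-transcription mistakes. For NE-2P the
admissible-allele rule is: the candidate second parent must carry the
offspring allele the known parent cannot explain; if the known parent
could explain both, either allele is admissible. Loci combine as products
(the panel loci sit on different chromosomes by design); accuracy is
1 − combined NE. The engines are validated against an independent
plain-loop enumeration and against 10⁶-draw Monte-Carlo simulation.

## Synthetic cohort generator

The generator produces tables with exactly the structure the estimators
assume, plus a ground-truth ledger, so every pipeline stage is testable by
parameter recovery:

* **Frequencies** — ancestral `p ~ Dirichlet(α)` per locus (α = 0.35 in
  the desk-scale preset, chosen from `E[1 − Σp²] = 1 − (α+1)/(kα+1)` to
  put expected gene diversity in the 0.65–0.9 band typical of these
  loci), or supplied explicitly.
* **Drift** — Balding–Nichols: cohort frequencies drawn from
  `Dirichlet(p(1−F)/F)`. Two geometries: `star` (default; every cohort an
  independent draw around the ancestral, so every cohort pair has
  expected pairwise θ = F — this is the calibrated geometry, verified by
  recovery at F ∈ {0.001, 0.005, 0.02}) and `chain` (a year-on-year
  random walk; adjacent cohorts then target θ ≈ F/2 and divergence grows
  with the birth-year gap, which is the geometry to use when emulating
  cumulative drift across years). The two targets — exact pairwise
  calibration and gap-dependent growth — cannot be met by a single
  geometry, hence the switch.
* **Inbreeding** — genotypes drawn from
  `P(ii) = p² + f p(1−p)`, `P(ij) = 2p_i p_j (1−f)`. Negative f
  (heterozygote excess) is supported down to the per-locus bound
  `−p_min/(1−p_min)`; exceeding it is an error that names the locus.
* **Defects** — missing calls, out-of-range alleles, three sex-anomaly
  kinds, and 2-/3-fold barcode duplicates (concordant or discordant) are
  injected into disjoint record sets chosen in a fixed priority order, so
  every injected record is counted under exactly one QC stage and the
  ledger predicts the QC report exactly — the ledger is the QC oracle.
* **Determinism** — one RNG stream keyed by the seed, drawn in a fixed
  documented order; the same seed reproduces the table bitwise.

The desk-scale preset mirrors the shape of a national cow-improvement
dataset: the real 11-locus panel with its reported allele counts (9–28),
23 birth-year cohorts (2001–2023) with the reported highly unequal size
profile scaled down by 100 (floor 50), a 68% female share, and defect
rates matching the reported preprocessing proportions (≈4% missing
calls, ≈9% missing sex markers, ≈2% sex mismatches, ≈2% duplicated
barcodes of which ≈12% are concordant). It deliberately does **not**
reproduce the real population's allele frequencies (not public), any
pedigree structure, linkage, mutation, or genotyping error — so passing
tests demonstrate estimator correctness under the model's assumptions,
not agreement with any particular real herd. The preset draws genotypes
at HWE (f = 0): the population it mimics is statistically
indistinguishable from equilibrium, and a global negative f would violate
the per-locus bound for rare alleles at arbitrary seeds; negative f
remains an explicit option for bound-safe panels.

## Numerical choices and problem sizes

* Frequency vectors must sum to 1 within 1e−12 (LocusFrequencies) or
  1e−9 (raw vectors handed to the NE engines, which renormalise).
* Monomorphic loci: H_exp = PIC = 0, ratio-F_IS undefined (NaN), every
  NE = 1.
* θ̂ with a zero component denominator is NaN (reported not-available);
  cohorts with fewer than 2 typed individuals at a locus are excluded
  from that locus with a warning.
* Recovery suites run at N = 10,000 individuals per cohort with 20
  replicates, judged at 3 Monte-Carlo standard errors of the replicate
  mean; the QC-ledger suite runs 100 random configurations of a few
  hundred records; the variance-shrinkage check spans cohort sizes
  100 → 10,000 (half-decade steps) and accepts a log–log slope of
  −1 ± 0.2. These sizes make the full suite run in well under a minute
  while keeping the 3-SE bands a small fraction of the effects tested.

## Known limitations

* No genotyping-error model anywhere (QC concordance, NE values).
* No rarefaction of allele counts: observed k depends on sample size, so
  desk-scale simulations show fewer alleles than the configured ladders.
* No HWE exact tests, no bootstrap CIs over loci, no likelihood-based
  parentage assignment (LOD scores) — exclusion summaries only.
* Genepop round-trips preserve barcode, cohort and genotypes; registered
  sex and sex-marker calls are not representable in Genepop.
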