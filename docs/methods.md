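# Methods

## Study design the package models

`famvar` models a two-stage rare-variant study in a complex disease with a
familial component. Stage one sequences the exomes of the most distantly
related affected members of multiplex pedigrees (families with ≥ 3 affected
members across generations) and filters the called variants down to genes
recurrently hit across families. Stage two takes candidate variants into an
unrelated case-control cohort, tests allelic association per variant, and
pools carriers of the panel into a cumulative (burden) comparison, since
individually the variants are too rare for single-variant power.

## Prioritization cascade

Per family, with a genotype matrix restricted to whole-exome-sequenced
affected members (the `sequenced` flag; an optional 7th PED column or a
sidecar list — when neither is given every affected member is assumed
sequenced):

- **shared heterozygous** — keep variants heterozygous in *every*
  sequenced affected member. The dominant model motivates the het-only
  rule; hom-alt calls do not qualify by default (`allow_hom_alt` relaxes
  this). A missing call excludes the variant (strict sharing): tolerance
  for untyped members is expressed through the sequenced flag, not through
  missingness, so that absence of evidence never counts as sharing.
- **protein-altering** — consequence ∈ {missense, nonsense, frameshift,
  canonical splice}; the closed vocabulary is mapped from common
  annotation-tool terms on ingest, unknown terms degrade to `other` with a
  warning.
- **rare** — frequency strictly below `max_frequency` (default 0.01) in
  every configured population source, a variant absent from a source
  passing that source's screen. AND across sources is the conservative
  default; `source_mode="any"` gives the either-source-suffices reading.
  Variants absent from *all* sources are counted as novel.
- **recurrence** — group survivors by gene (gene identity comes solely from
  the annotation table) and keep genes supported by ≥ `min_families`
  (default 2) distinct families; supporting variants may differ between
  families.

Stage sets form a descending chain per family by construction, and the
final set is invariant to the order of the two annotation filters (both are
pointwise predicates); both properties are tested. The filters are applied
in the order sharing → consequence → frequency.

## Segregation and penetrance

`tabulate_segregation` cross-classifies genotyped members of known
phenotype as carrier (het or hom-alt — segregation describes whatever is
observed) × affected. Members of unknown phenotype are excluded from the
cells and reported separately; genotyped-but-missing calls count as
untyped. Married-in individuals — structurally, founders whose every
co-parent is a non-founder (override per individual via `married_in`) — are
excluded from the complete-segregation verdict and affected married-in
non-carriers are tallied separately as phenocopies, since a spouse's
disease carries no information about the family's candidate allele.
Carrier penetrance is affected carriers / all carriers, undefined when no
member carries the allele.

## Association statistics

All tests operate on 2×2 tables built from genotype counts. The allele
basis counts minor alleles (het + 2·hom-alt) against the remaining 2n −
minor alleles; the carrier basis counts carrier individuals. Available
tests: Pearson χ² (1 df), Yates-corrected χ² ((|ad−bc|−N/2)² floored at 0),
and the two-sided Fisher exact test (sum of hypergeometric probabilities ≤
the observed table's, delegated to scipy and cross-checked in the tests
against exact-integer enumeration). The Yates statistic is the default
method: on the embedded published counts it reproduces the printed
single-variant p-values, while the printed combined-analysis p-values match
the uncorrected statistic — the recomputation report flags this rather than
switching defaults per row.

Odds ratios are cross-products ad/(bc); when a cell is zero, 0.5 is added
to every cell (Haldane–Anscombe) before the OR and CI are computed, and
never otherwise. Confidence intervals are Woolf (log-normal):
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). Bonferroni correction is min(1, m·p)
with m = 6 for single-variant runs (two variants × three phenotypes) and
m = 3 for combined runs, matching the multiplicities recoverable from the
published corrected p-values.

The cumulative-carrier analysis sums carriers across the panel per cohort.
The per-cohort denominator is the minimum per-variant n — the published
combined rows use exactly this value, and it approximates the count of
individuals typed on the complete panel when missingness nests. Counts-level
input assumes carrier sets are disjoint across variants (a safe assumption
at these frequencies); when raw calls are available,
`carriers_in_matrix` counts an individual carrying several panel variants
once. With no hom-alt genotypes the allele- and carrier-basis combined odds
ratios agree to < 0.5% relative difference (tested on the embedded counts).

The Hardy–Weinberg test is the exact conditional test: conditioning on the
observed allele counts, every heterozygote count of matching parity is
enumerated under the Levene distribution and the two-sided p-value is the
summed probability of configurations no more probable than the observed
one, with no mid-p adjustment. The implementation uses log-gamma
arithmetic; the test suite checks it against an independent exact-rational
oracle up to n = 200. Note the degenerate case: monomorphic margins admit a
single configuration, so the p-value is exactly 1.

## Synthetic-data generator

**What it emulates.** Family mode: a founding couple, married-in spouses in
every non-final generation, sibships of size max(1, Poisson(mean 2.5)),
three generations, ten families. A causal missense allele (population
frequency 4×10⁻⁴) enters `n_causal_families` (default 2) families through
one founder and is transmitted by gene dropping (each child inherits one
allele per parent uniformly at random). Affection status is drawn with
carrier penetrance f = 0.6 (echoing the 3-affected-of-5-carriers pattern
observed in the motivating family) and phenocopy rate φ = 0.05. Families
are ascertained by rejection sampling until ≥ 3 members are affected —
the study's selection criterion — and causal families additionally until
≥ 2 affected carriers exist. In causal families the sequenced flag is set
on affected carriers (the shared-variant screen's selection, which the
original study validated post hoc: its one affected non-carrier was typed
by follow-up Sanger sequencing, not exome sequencing); in background
families all affected are flagged. 200 background variants get log-uniform
allele frequencies on [10⁻⁵, 0.5], a realistic mixed consequence spectrum
(50% missense, 30% synonymous, 10% other, 10% truncating/splice), and
independent founder draws per family.

Cohort mode: control carriers ~ Binomial(n, q); case carrier probability
p\* solves p\*/(1−p\*) = OR·q/(1−q) per phenotype (a prevalence-free
retrospective design — carrier status is drawn directly at the case-control
level, not through a population liability model). Defaults are the
follow-up scale (2948 CD, 3077 UC, 7238 controls), panel carrier
frequencies 7×10⁻⁴ and 3×10⁻⁴, odds ratios anchored to the published
effects, genotypes missing independently at 0.5% (so call rates land just
above the 99% QC gate). Carriers are simulated heterozygous only: at q ~
10⁻³ the hom-alt probability q² is negligible and the published table
contains no hom-alt genotype. IBD counts are the union of the CD and UC
draws. CD and UC effects are independent per variant.

**What it does not emulate** — and hence what passing tests do not show
about real data: no linkage disequilibrium or haplotype structure, no
genotyping-batch or population-stratification artefacts, no relatedness
between cohort members, no genome-scale variant count (200 background
variants stand in for an exome's tens of thousands, so absolute stage
counts are not comparable to a real screen), and no sequencing error model
beyond simple missingness.

All randomness flows from a single config seed through tagged
`SeedSequence` substreams, making every output bitwise reproducible and
independent of evaluation order.

## Numerical and reporting choices

- Odds ratios are *truncated* (not rounded) to two decimals in reports;
  recomputation of the published table matches truncation (4.7991 → 4.79,
  2.7781 → 2.77, 1.7790 → 1.77) while frequencies match rounding
  (0.2782% → 0.28%). Frequencies are reported as percentages.
- Variant keys are normalized: uppercase alleles, shared suffix then prefix
  trimmed to a minimal representation with 1-based VCF coordinates.
  Multiallelic VCF records are split per alternate allele; a genotype
  containing the target allele plus any other allele recodes as
  heterozygous for the target, matching the cascade's per-allele dominant
  filter. Phase separators are ignored.
- The frequency threshold is strict (< 1%): a variant at exactly the
  threshold is removed.
- p-value comparisons in the printed-table report use one unit in the last
  significant printed digit, since the source prints trailing zeros beyond
  its real precision.
- Exact-test ties: the Fisher and HWE two-sided sums include configurations
  whose probability equals the observed one (with a 1 + 10⁻¹² relative
  guard against floating-point ties).

## Problem sizes used in checks

The recomputation of the published table is exact arithmetic on its printed
counts. Generator-based checks use 10 families × ~200 variants per dataset
with 10–20 replicate datasets for cascade sensitivity/specificity and chain
properties; Monte-Carlo studies use 500 replicates for odds-ratio recovery
and CI coverage and 2000 for type-I error, all at the full follow-up cohort
scale. Enumeration oracles cover all 2×2 tables with margins ≤ 12 and HWE
configurations up to n = 200.

## Known limitations

- The original exome-wide stage tallies (tens of thousands of shared
  variants down to 34 in 17 genes) depend on raw sequencing data that is
  not distributable; they are documented as non-reproducible and the
  cascade's behaviour is validated on generator ground truth instead.
- Two printed odds ratios (2.40, 1.80) and two printed case MAFs do not
  recompute from the printed genotype counts; the package reports the
  recomputed values and flags the cells (for one of them the printed CI
  matches the *recomputed* OR, corroborating a typesetting error). The
  source's CI method is unstated; Woolf intervals reproduce the combined
  rows exactly and the single-variant rows to within a few percent.
- No covariate adjustment, stratification correction, imputation, kinship
  inference, LOD-score linkage, or genome-wide multiple-testing machinery:
  the scope is the two-stage design above.
- Counts-level burden input cannot deduplicate multi-variant carriers;
  matrix-level input can.
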