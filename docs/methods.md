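# Methods

## Study design being modelled

The package models a two-phase founder-population case-control design
for rare germline variants in *RAD51C* and *RAD51D*. In the discovery
phase, exome variants from familial and early-onset sporadic
ovarian-cancer cases are filtered and prioritized into a small
candidate set. In the replication phase, carriers of each candidate are
counted in five study groups — ovarian-cancer families (49
participants from 44 families; the family is the counting unit),
hereditary breast-and-ovarian-cancer families (56), sporadic
ovarian-cancer cases (438), sequencing-based controls (1025) and
SNP-genotyping-based controls (8493) — and compared pairwise with
Fisher's exact test. Nine physical participants are known to belong to
two case groups, which motivates the permutation analysis.

## Variant prioritization

Genotype-call filters: depth ≥ 10 reads, variant allele fraction in
[0.20, 0.80] (bounds inclusive — only calls strictly outside are
excluded), base-quality pass. Variant filters: silent and intronic
consequences removed; reference-population MAF ≥ 0.01 removed. A
missing MAF is **kept**: for founder variants, absence from a
reference database is evidence of rarity, not commonness, so missing
is never coerced to zero anywhere in the package.

A variant is a candidate if it is loss-of-function (nonsense,
frameshift, canonical splice) or missense with (a) a ClinVar or ACMG
class among {pathogenic, likely pathogenic, VUS, conflicting} — a
"conflicting" aggregate is treated as VUS-equivalent — and (b)
support from the in-silico panel. Support (default `any_tool`
aggregation) means at least one conservation tool at threshold
(GERP ≥ 2.0, PhyloP ≥ 0.2, PhastCons ≥ 0.4), or at least one damage
tool (REVEL ≥ 0.4, MetaLR ≥ 0.4, MetaSVM ≥ 0.0, CONDEL ≥ 0.4,
CADD-Phred ≥ 20, PROVEAN), or the splice consensus (dbscSNV ADA **and**
RF ≥ 0.4, or MaxEntScan **and** HSF both splice-affecting).
Categorical labels take precedence over numeric scores when both are
present, because curated panels are typically label-level. A stricter
`all_categories` mode (every available evidence category must agree)
is provided for sensitivity analyses.

PROVEAN's direction is genuinely ambiguous in the literature the
thresholds come from: the tool's own convention is damaging at
score ≤ −2.5, and that is the default here
(`provean_damaging_low=True`); the opposite direction is available as
configuration. The packaged reference profiles are label-level, so the
choice does not affect them.

## Carrier statistics

Carrier frequency is carriers divided by the group's counting-unit
denominator; percentages are formatted half-up to one decimal (so
1/44 → 2.3, 15/438 → 3.4) and always derived, never stored. The
two-sided Fisher exact p is the classical "sum of probabilities not
exceeding the observed table's" definition over the hypergeometric
support, with a relative tie tolerance of 1e−7; this definition
reproduces the published 0.081 and 0.299 values exactly, which
doubling-style definitions do not. The hypergeometric pmf comes from
scipy; an exact integer-arithmetic enumeration oracle and
`scipy.stats.fisher_exact` independently confirm the p-values in the
tests. Odds ratios (sample OR with Woolf log-CI) are reported only
when all four cells are positive. No multiple-testing adjustment is
applied at this stage; family-wise error is the permutation module's
job.

## Permutation study

The pooled roster contains each physical person once; memberships are
kept as tags. Under the default `carrier` allocation unit, each
variant's observed carrier total is re-assigned as a uniform simple
random sample without replacement from the pool, independently across
variants; `variant_block` instead drops a variant's whole carrier set
into one group chosen with probability proportional to group size
(the main plausible alternative reading of "random allocation of the
observed variants"). Group counts are recomputed through the
membership structure: a duplicated person propagates carrier status to
both their groups, and any carrier inside a family marks that family
once while the denominator stays the number of families.

Each comparison is summarized by its naive Fisher p (a rate-difference
statistic is available as configuration). The permutation p-value uses
the add-one estimator (r + 1)/(B + 1), bounded below by 1/(B + 1); in
exhaustive mode (small pools) the exact tail r/n_allocations is
returned, and the observed allocation is a member of the enumeration
so the p-value is never zero. The FWER estimate is the fraction of
permutations where at least one naive p falls below α; joint
significance is the fraction where all do. All estimates carry
binomial Monte-Carlo standard errors. Randomness flows from a single
seed through counter-derived substreams (one per permutation), so
results are independent of execution order.

The original study's per-test permutation p-values and 6.7% FWER were
produced with an allocation scheme documented only in supplementary
material that is not reproducible from the main text; this package
therefore validates its permutation machinery by exhaustive-enumeration
equivalence and null calibration rather than by matching those numbers.

## Null calibration

`permutation_null_calibration` mirrors the study structure at reduced
scale: three case groups of 50, two control groups of 100, two
variants with 12 and 8 carriers placed uniformly (the null), and five
overlapping comparisons. Each replicate treats a fresh uniform
allocation as "observed" and runs a full permutation study (B = 2000);
200 replicates estimate the per-test rejection rate at α = 0.05. The
carrier statistic is discrete, so the rate sits at or slightly below α
(typically 0.03–0.06 in this design); sample sizes were chosen so the
achievable significance levels near α are dense enough for the rate to
be informative while a replicate completes in well under a second.

For the plain two-arm Fisher test, the exact rejection probability
under independent binomial sampling is computed by summing the joint
pmf over the count grid (`exact_two_arm_rejection_probability`). At
the replication-phase sizes (438 vs 1025) with a pooled null carrier
probability of 16/1463, the exact size is 0.0337 — conservative, as
expected for a discrete exact test — and the exact power at the
observed sporadic effect (15/438 vs 1/1025) is 0.9995. Simulations in
the tests are checked against these analytic values within Monte-Carlo
error, not against ad hoc bands.

## LOH model

A germline heterozygote has normal-tissue VAF near 0.5. If every
tumour cell has lost the wild-type allele, a tumour of purity p gives
an expected VAF of 1/(2 − p) (one variant allele per tumour cell; one
variant and one wild-type per admixed normal cell). The caller works
on the wild-type fraction wtf = 1 − tumour VAF with defaults:
complete loss wtf < 0.10, partial loss 0.10 ≤ wtf < 0.35, retained
otherwise; uninformative when tumour depth < 20 or the germline is not
credibly heterozygous (normal VAF outside [0.2, 0.8]). These
thresholds are explicit conventions of this package standing in for
visual chromatogram inspection — the original study states no numeric
criterion — and are fully configurable. A 1e−9 guard keeps
float-rounded boundary values (e.g. 1 − 0.9) on the inclusive side.
The noise-free decision boundary for complete loss is purity
> 2 − 1/(1 − 0.10) = 8/9, which the synthetic round-trip tests verify.
Partial loss is interpreted as allelic imbalance compatible with
contaminating normal stroma.

## Clinical comparisons

Descriptives use the sample standard deviation (n − 1); a single
value has no SD rather than SD 0. "Diagnosed before age X" is a strict
inequality with the percent rounded half-up to an integer. The
two-group test is the pooled-variance Student's t (the plain
"unpaired t-test" convention), two-sided, with the 95% CI of the mean
difference from the pooled standard error; Welch's correction is a
flag. Zero variance in both groups with equal means returns t = 0,
p = 1; with unequal means it raises rather than reporting an infinite
statistic. The original per-carrier ages and survival are not public,
so this module is validated against independently coded textbook
formulas and synthetic data, not against the published p-values.

## Synthetic generators

All generators are pure functions of (spec, seed), with NumPy's PCG64.
Cohort generation defaults to exact-count carrier placement
(hypergeometric design) so fixture-level tests are deterministic:
carriers are placed one per counting unit, on participants whose only
membership is the target group, with units disjoint across variants —
this reproduces the declared counts with probability 1 and mirrors the
observed data, in which no carrier was recruited twice and no carrier
held two candidate variants. Probabilistic placement (independent
Bernoulli per unit) is available for power studies. Duplicate
recruitment merges randomly chosen slots from two case groups into one
physical person. Decoy variant panels draw each predictor score
independently — only threshold crossings matter to the rules engine,
so inter-tool correlation is deliberately out of scope — either
strictly below every threshold (exact recovery of planted candidates
by construction) or straddling the thresholds (graceful degradation).
Decoy MAFs mix mass above and below 0.01 plus a missing fraction.
Synthetic LOH observations add binomial read-sampling noise at the
specified depth around the closed-form expected VAF; clinical ages are
truncated normal on [25, 90] by resampling.

What the generators do **not** emulate: linkage between variants,
relatedness beyond family tags, predictor-score correlation,
sequencing artefacts, or population stratification. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated sampling models, not robustness to those real-data
complications.

## Problem sizes and numerical choices

The default test suite runs the permutation calibration at 200
replicates × 2000 permutations and the oracle checks at 1000 random
tables (N ≤ 40), chosen to give 3-SE Monte-Carlo bands tight enough to
be meaningful while keeping a full run around a minute. Fisher
p-values are cached by table (the permutation study re-encounters few
distinct tables), exact enumeration is used wherever the allocation
space is ≤ ~300k, and all percentage formatting uses decimal
round-half-up to match publication style. Reported permutation
p-values are floored at 1/(B + 1) and never zero.

## Known limitations

- The permutation allocation scheme is a reconstruction; two plausible
  units (carrier-level, variant-block) are implemented and neither is
  asserted to be the original.
- LOH thresholds are conventions, not published cut-offs; calls on the
  packaged encoded states depend on the representative fractions
  chosen for each state label.
- The cohort generator cannot represent a person belonging to two
  family-counted groups with different families; duplicates keep the
  family of their first group.
- HGVS strings are carried verbatim (GRCh37); no normalization or
  transcript validation is attempted.
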