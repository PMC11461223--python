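# Methods

## Study design being modeled

The package analyzes a twin cohort on two nested samples. The full
genotyped sample (430 twins, 215 pairs, 75.8% monozygotic by default)
feeds a candidate-gene association battery for the *COMT* rs4680
(Val158Met) polymorphism under a dominant coding: carriers of at least one
Val allele (Val+) against Met/Met homozygotes (Met+). The epigenetic
subsample — 35 MZ pairs with complete pyrosequencing data — feeds a
discordant-pair analysis relating percent DNA methylation at 5 CpG sites
of the *MB-COMT* promoter to NEO-PI-R trait expression. MZ co-twins share
their genotype, so within-pair trait differences isolate non-genetic
variation; ranking co-twins by methylation and asking whether the
higher-methylation twin tends to score lower (or higher) operationalizes
an epigenetic association free of between-family confounding.

## SNP battery

For each of the 35 NEO-PI-R scales (5 domains scored 0–192, 30 facets
scored 0–32) the Met+/Val+ comparison is routed by two assumption gates:

* normality: Shapiro–Wilk per genotype group (the *t*-test assumption is
  per-group, so pooled testing is deliberately avoided);
* homogeneity of variances: Levene's test, mean-centered.

Both gates run at α = 0.05 (configurable). A normality failure in either
group routes to the Mann–Whitney *U* test; otherwise a homogeneity failure
routes to Welch's *t*; otherwise Student's *t*. The gate tests themselves
are a design choice — the procedure being reproduced names the conditions
but not the tests — and match common desktop-statistics defaults.

*U* is computed for the Met+ group (cross-pairs won plus half-credit for
ties), so the rank-biserial effect r = 2U/(n₁n₂) − 1 is positive exactly
when Met+ tends higher; Cohen's *d* uses the pooled SD with the same sign
convention. CIs: noncentral-*t* inversion for *d*; for *r*, a normal
approximation on *U* with null variance n₁n₂(n₁+n₂+1)/12, mapped through
the linear identity and clipped to [−1, 1] (the exact CI method behind the
published intervals is unstated; this approximation reproduces them to
~0.005). The Mann–Whitney p-value uses the exact null distribution when
both groups have n ≤ 20 and no ties, otherwise the tie-corrected normal
approximation with continuity correction.

Bonferroni adjustment is min(1, m·p) with family size m = 2 by default,
because every published (p, adjusted-p) pair follows that convention; m is
a knob, and why the family is 2 is unknown.

The Hardy-Weinberg check estimates the Met allele frequency from the data,
so the chi-square has 1 df; a `report_df` label exists purely to mirror
reports that print df = 2 and never changes the computation. The published
HWE chi-square values are not recoverable from the published genotype
counts under this (standard) test; the package does not chase them.

Co-twins are treated as independent observations in this arm — the
product n₁n₂ = 129 × 301 underlying the published effect sizes implies the
same — and the clustering caveat is documented, not corrected.

## Discordant-pair batteries

For each (CpG, scale, alternative) cell the co-twins of each usable pair
are ranked by methylation (H/L; an exact tie or missing value excludes the
pair for that CpG only) and classified by the within-pair trait
comparison. The hypotheses are formulated on the probabilities p₁ (a twin
has higher methylation and the lower trait score than its sibling) and p₂
(higher methylation, higher score): alternative "greater" tests
H1: p₁ > p₂ and treats trait ties as "not higher" (success column);
"less" tests H1: p₁ < p₂ and treats ties as "not lower" (failure column).
Each pair contributes one observation to the H row and one to the L row,
giving a 2×2 table with equal fixed row sizes whose success column is the
"lower trait" side; Barnard's test is applied with the same-named
alternative. The full battery is 5 × 35 × 2 = 350 cells, reported with
raw p-values (no multiplicity adjustment, by design; a Benjamini–Hochberg
column can be added downstream without altering defaults).

**Known operating characteristic.** The mirrored construction makes the
two rows of each table perfectly dependent (without trait ties,
x₂ = n − x₁). Barnard's size guarantee assumes independent binomial rows,
and it does not transfer: under a pairwise null (orientation fair coin per
pair) the battery rejects at α = 0.05 about 9.5% of the time (measured
over 200 simulated 35-pair cohorts; predictable in closed form from
P(Bin(35, ½) ≥ 22)). The construction is replicated faithfully because it
*is* the analyzed procedure; consumers should read the battery's p-values
as ordering evidence across cells rather than as calibrated error rates.
The alternative one-observation-per-pair construction is available behind
`pair_contribution="index_twin"`.

## Barnard's unconditional exact test

Ordering statistic: pooled-variance Wald/score statistic, the convention
of the scientific-Python implementation ecosystem, so results are
comparable; T = 0 by convention when the pooled proportion is degenerate
(no evidence of direction; one-sided p = 1 for an all-zero table). Ties in
T are included in the extreme set; the two-sided test orders by |T| (not
by doubling). The nuisance supremum is searched on a uniform 1001-point
grid over (10⁻⁶, 1 − 10⁻⁶) followed by bounded scalar maximization between
the neighbors of the best grid point (p(π) restricted to a fixed extreme
set is a polynomial with few maxima at these sizes; doubling the grid
changes p by < 10⁻⁴, and the refined value matches a 100,001-point
brute-force oracle to < 10⁻⁶ across random tables with n ≤ 12). The exact
size guarantee (rejection probability ≤ α for every π) is verified by
exhaustive enumeration for n₁ = n₂ ≤ 10 in the acceptance suite.
Results are memoized on table counts, which is what makes 350-cell × many-
seed Monte-Carlo runs affordable.

An independent cross-check against `scipy.stats.barnard_exact` (feeding
the transposed table — scipy fixes column totals) agrees to ~10⁻⁵
one-sided, the limit of scipy's stochastic supremum search; scipy's
two-sided p can differ visibly because its float-strict `>=` excludes the
exactly mirrored table from the |T| tie set.

## Synthetic cohort generator

The generator's defaults are the study conditions: 215 pairs (430 twins),
75.8% MZ, 35 epigenetic pairs, Met allele frequency 482/860, ages ~N(24.7,
7.7²) clipped to [18, 60], 74.4% female.

* **Genotypes**: i.i.d. HWE draws (p², 2pq, q²); one draw per MZ pair,
  independent draws per DZ twin (shared parents are not modeled; DZ pairs
  never enter the epigenetic arm).
* **Traits**: bivariate normal per pair with common mean/SD and
  correlation `icc_mz` (default 0.5 per scale), rounded and clipped to the
  scale range. Domain means/SDs default to the published descriptive
  moments; facets use the heuristic mean = domain/6, SD = domain/√6
  (facet-level moments are not published).
* **Methylation**: zero-inflated lognormal clipped to [0, 100]; a shared
  and a unique standard-normal component on the log scale give within-pair
  correlation ≈ `meth_pair_corr` (default 0.4 — no published estimate
  exists; this value is arbitrary and flagged as such). Default log-means
  target the five published per-site means with log-SD 0.8 and 2%
  zero-mass. Note the finite-sample behavior: at the study's n = 70 the
  sample skewness of this family sits in the published 1–3 range, while
  its asymptotic skewness is ≈ 3.7 — sample skewness of heavy-tailed data
  is strongly downward-biased, so moment targets are checked at study
  size.
* **Planted discordance**: within each epigenetic pair the two trait
  values may be swapped so that, with probability 0.5 + δ, the
  higher-methylation twin carries the value favored by the named battery
  alternative ("greater" ⇒ the lower score). Swapping preserves each
  pair's multiset of values, hence all marginals. `direction` deliberately
  names the *detecting alternative*, keeping recovery experiments
  self-describing.
* **Group shift**: a crude Met+ mean shift in SD units on one scale, for
  power checks of the SNP arm only.

Randomness derives from one seed via named substreams
(`default_rng([seed, stream, index])`), so adding a scale or CpG never
perturbs other draws, and identical configs give byte-identical cohorts.

What the generator does *not* emulate: ACE variance decomposition, real
genotype→trait effects, facet intercorrelation structure, sex/age effects
on traits or methylation, assay batch effects. Passing recovery tests
therefore show the *procedures* behave as designed under the assumed
structure, not that real data would satisfy that structure.

## Problem sizes used in the checks

Monte-Carlo checks run at the study's own sizes (35-pair epigenetic
cohorts, 430-twin SNP cohorts): 200 null cohorts for battery calibration,
500 seeds for planted-effect ranking (δ = 0.35), 100 seeds for SNP power
(0.4 SD), 200 random tables against the dense-grid oracle, and exhaustive
table enumeration up to n = 10 for the size guarantee.

## Degenerate inputs and conventions

Constant samples: descriptives raise (skewness undefined); the variance
gate passes two equal constant samples by convention; both-groups-constant
equal-mean *t* is 0 with p = 1. Empty genotype groups abort the battery;
scales with too little data yield a flagged `insufficient_data` row rather
than disappearing. Result CSVs serialize p-values to 4 decimals and effect
sizes to 3 (float formatting, banker's rounding).

## Limitations

Beyond the calibration caveat above: the rank-biserial CI method is an
approximation chosen for transparency, not an exact match to any
particular software's intervals; the exact Mann–Whitney p-value is skipped
in favor of the asymptotic one whenever ties are present; and zygosity,
scale scores, and methylation percentages are taken as given inputs — no
measurement-error model is attached to any of them.
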