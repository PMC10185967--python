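# Methods

## Scope and data model

`mmnet` analyses one-row-per-participant cohorts of adults aged 65+ with a
fixed panel of 15 chronic diseases (angina pectoris, arthritis, asthma,
cancer, CKD, depression, diabetes, hyperlipidemia, hypertension, liver
disease, myocardial infarction, renal failure, stroke, thyroid disease,
tuberculosis), an EQ-5D-3L utility index, survey weights, and categorical
covariates. Cancer sites and hepatitis subtypes are assumed collapsed into
single flags upstream. CKD is defined from renal function as
eGFR < 60 mL/min/1.73 m² (strict inequality; `ckd_from_egfr` takes the
eGFR as given and does not choose a creatinine equation).

## EQ-5D-3L scoring and HRQoL groups

The index of a state (levels 1–3 on mobility, self-care, usual activities,
pain/discomfort, anxiety/depression) is the additive N3 model:
`1 − c·[any>1] − Σ δ_d(level_d) − n3·[any=3]`. Value sets are pluggable
config objects; the bundled `korean_3l` set is *synthetic*: it carries the
magnitudes of the published Korean value set but its exact coefficients are
not public in the summary sources this package works from, so the set is
calibrated to the documented attainable range [−0.17, 1.00] exactly. All
quantitative claims in the test suite use either the scale endpoints or a
transparent toy set.

HRQoL groups: **poor** iff index ≤ 0.721 (ties poor), **good** iff index
= 1.00 exactly, **normal** otherwise. The 0.721 constant is the lowest-5%
cutpoint of the full adult survey population and is treated as a fixed
input; `derive_cutoff` re-derives an empirical cutpoint when wanted, using
the inverted-CDF (lower order statistic) convention — the "lowest k%"
reading, under which 100 equally spaced values 0.01…1.00 give exactly the
5th value at the 5% quantile. The interpolating type-7 convention was
considered and rejected because it does not reproduce that order-statistic
reading.

## Association rules and networks

Rules are strictly pairwise (every published statistic is a two-disease
rule). Both directed rules of a pair are always emitted together; the
canonical order is support desc, lift desc, then pair label, so ties are
deterministic. `top_rules` counts *directed* rules (k = 20 is ten pairs)
and never splits a pair. `min_support` defaults to 0 — truncation is a
presentation concern, not a mining concern. Zero-marginal pairs have
undefined (NaN, masked) confidence/lift, never 0. Internal statistics are
full precision; printed percentages are rounded half-up at one decimal in
the formatting layer only (half-up reproduces every checked published
cell, e.g. 95/457 → 20.8).

Node strength sums supports (proportion scale, 0–1) over **all** 14
partners regardless of the display edge threshold, so it is
threshold-invariant; the threshold only filters exported edges. Graphs are
exported as GraphML (namespace-valid, round-trippable) or CSV edge lists
plus a node attribute table; layout and visual encodings are out of scope.

Descriptive stratified tables are unweighted counts (verified against the
published cells, e.g. 139/457 → 30.4%); weights enter only the regression.
Across-group comparisons use the chi-square test of independence without
continuity correction; expected cells below 1 warn but still return.

## Published-count worked example

The bundled reference tables fix each poor stratum's marginal counts and
the joint counts of its ten strongest pairs. Unpublished joint counts are
filled at the independence expectation and the resulting count matrix is
labelled synthetic. Printed cells are half-up rounded, so a printed support
is compatible with more than one integer joint count;
`reconstruct_joint_count` searches a ±3 window around `support × n` and
keeps the integer whose recomputed support, both confidences, and lift all
round back to the printed cells. With that reconstruction, the rule engine
reproduces all forty printed rule rows exactly at one decimal.

## Synthetic cohort generator

The generator's purpose is ground truth for the estimators, per sex pool
(3 × `n_per_stratum` records each):

1. **Diseases.** A Gaussian copula: flag j = 1 iff Z_j < Φ⁻¹(p_j) with Z
   multivariate normal under `latent_corr`. Marginals are exact by
   construction; the mapping from latent correlation to achieved lift is
   the bivariate-normal orthant probability (`expected_pair_lift`), which
   is the oracle the tests check against. The matrix is validated as
   symmetric, unit-diagonal and PSD; mild indefiniteness (smallest
   eigenvalue > −0.05) is repaired by eigenvalue clipping with a warning.
   Default: a mild 0.08 background correlation plus boosts for clinically
   clustered pairs (metabolic, renal–thyroid, cardiac, respiratory),
   chosen once to give published-magnitude supports and lifts.
2. **Per-sex marginals.** Each sex uses the share-weighted mixture of its
   three configured stratum prevalence rows (defaults taken from the
   published stratified counts). The stratified prevalence gradient in the
   output is then *emergent* from the burden→HRQoL link rather than
   imposed per stratum: with fixed stratum-conditional prevalences, a
   logistic burden link could not also hold, and the link is the quantity
   the estimators must recover. Marginal-recovery guarantees therefore
   apply to each sex pool (and to every direct `sample_correlated_binary`
   call), not to the emergent strata.
3. **HRQoL.** Poor is Bernoulli(expit(α + β_m)) on the multimorbidity
   category m ∈ {0,1,2,≥3}; β = (0, 0.39, 0.63, 0.99) by default (adjusted
   odds ratios ≈ 1.47, 1.88, 2.70), and α is calibrated by root-finding so
   the realized poor share matches the target. Non-poor records are good
   (index exactly 1.00) with the conditional probability implied by the
   configured good mass, else normal. Because covariates are generated
   independently, the category-only (or category + demographics) model is
   correctly specified and β is recoverable without confounding bias.
4. **Index.** Continuous indices come from a scaled Beta(7.17, 1.5) on
   [−0.17, 1), truncated below/above the 0.721 cutpoint for poor/normal.
   The shapes are calibrated so the continuous part puts ≈ 25.8% of its
   mass below the cutpoint, giving overall good/normal/poor shares
   ≈ 44.9 / 40.9 / 14.2% — the shares reported for the 65+ population
   (the often-quoted 5% figure describes the full adult survey and would
   understate the poor share of an older-adult cohort).
5. **Weights and covariates.** Log-normal weights with configurable CV
   (default 0.5), normalized to mean 1 per sex pool — no weight
   distribution is documented for the source survey, so log-normal is a
   package choice. Covariates (marital, income, …, stress, with small
   explicit "missing" shares) are drawn independently from realistic
   marginal frequencies.

Everything is driven by one `SeedSequence`; identical config + seed gives
bit-identical cohorts.

### What the generator does *not* emulate

Multistage cluster sampling geometry (cluster ids are random labels, used
only to exercise cluster-robust variance); covariate–disease and
covariate–HRQoL confounding; item-level EQ-5D responses (the index is
drawn directly, and is continuous where the real index takes finitely many
values); longitudinal structure. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
design features the generator omits.

## Survey-weighted regression

Weighted logistic regression by IRLS (relative tolerance 1e-8, ≤ 50
iterations), maximizing the weight-multiplied Bernoulli likelihood.
Variance is the sandwich estimator: heteroscedasticity-robust by default,
cluster-aggregated with a G/(G−1) factor when cluster ids are given. This
is a linearization stand-in for full survey-design variance — point
estimates equal the design-weighted fit, but stratification and finite
population corrections are not modelled, so published survey CIs are
context rather than exact targets. Coefficients with |β| > 30 raise a
separation error naming the term; reference levels (age 65–69, male,
married, high income, employed, college+, normal BMI, non-smoker,
non-drinker, walking, optimal sleep, no stress, no disease) are dropped
from the design. Records with missing covariate levels are deleted
listwise within the regression only, with a logged count. Global weight
rescaling leaves both β and the robust SE unchanged.

## Problem sizes and numerical choices

Test-suite and acceptance runs use cohorts of 1.5k–102k records, 10⁵
draws for independence/orthant checks, and 200 replicates of n = 5,000 for
CI coverage — sizes at which binomial noise is well inside the asserted
bands (e.g. the independence-law band [0.95, 1.05] is checked at moderate
prevalences 0.3–0.6, where every pair's expected joint count keeps the
lift's sampling SD below ~0.011; at rare-disease prevalences that band
would be a test of noise, not of the mechanism). Tie-breaks, rounding
conventions, and masking rules are as above; degenerate inputs (empty
strata, marginals of 0/1, empty quantile vectors, rank-deficient designs)
raise informative errors rather than propagating NaNs.

## Known limitations

- The bundled value set is representative, not the official Korean
  tariff; analyses needing the official coefficients must supply them as
  a config.
- The generator's latent correlation defaults reproduce published
  magnitudes of supports/lifts, not exact cells; only the worked-example
  layer (published counts in, statistics out) is exact.
- Cross-sectional only; nothing here supports causal claims about disease
  co-occurrence.
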