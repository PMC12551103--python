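# Methods

## Scope and shape

`cfnbs` implements a complete in-silico counterpart of a two-tier
IRT → *CFTR*-panel newborn-screening algorithm: synthetic registry
generation, daily trimmed floating-IRT cut-off estimation, screening and
outcome classification, cut-off and panel counterfactuals, and equity
statistics. The tier-1 rules and the screener are fit/predict-shaped, so they
are exposed as scikit-learn style estimators (`CutoffModel`,
`TwoTierScreener`) with `fit`, `predict`/`transform` and
`get_params`/`set_params`; everything else (fixture construction, odds
ratios, reporting) is plain functions over pandas DataFrames.

## The screening model

Tier 1 compares a specimen's IRT with the effective cut-off on its
collection day; positivity is inclusive (≥) everywhere. The floating rule is
the day's q-th percentile of trimmed IRT values; the hybrid rule caps it with
a back-up fixed value, `min(floating, fixed)`, and falls back to the fixed
value on days with no floating estimate. Tier 2 counts the infant's alleles
found on the variant panel; matching is exact string comparison after
whitespace normalisation — no HGVS/legacy nomenclature translation is
attempted, because silent mistranslation is worse than requiring the panel
author to use the registry's naming. A panel homozygote counts as two
detections, consistent with two-variant referral practice.

Outcome classification anchors birth at `specimen_date − 2 days` (heel
pricks are collected at 24–48 h of age; the offset is configurable). A
diagnosis strictly later than 28 days of age despite a positive screen is
*delayed*; day 28 is on time. CF children with negative screens are *missed*,
split by which tier failed. A CF child with a positive screen but no recorded
diagnosis date is flagged with an `undiagnosed` sentinel rather than dropped,
so outcome categories always partition the CF cohort. Delay *reasons* are
input data (an optional registry column), never inferred: in real programmes
they come from chart review, which a simulation cannot replicate.

## Percentile estimation

The quantile estimator is linear interpolation (`numpy`'s default): with
sorted `x[1..n]` and `h = (n−1)q/100 + 1`, the estimate interpolates between
`x[⌊h⌋]` and `x[⌊h⌋+1]`. A nearest-rank alternative (`inverted_cdf`) sits
behind the `estimator` switch for sensitivity analysis. The published
laboratory recipe this models is cited to a standards appendix whose details
are not public, so the implementation is explicit and configurable rather
than claiming equivalence.

Outliers ≥ 170 ng/mL are removed before estimation only. Days are grouped by
calendar `specimen_date` (collection vs. accession dating is not modelled).
Days with fewer than `min_daily_n = 50` trimmed specimens pool backwards
over prior days in the series until the count is reached (`pooled_flag`
set); a day that cannot reach the minimum even after pooling the whole
history has no cut-off (NaN). The default evaluation is retrospective — a
specimen is included in its own day's percentile, matching a historic
re-analysis; 50 is a round default giving a usable daily 95th percentile
while letting sparse days pool.

Seasons are meteorological: spring Mar–May, summer Jun–Aug, fall Sep–Nov,
winter Dec–Feb, with December labelled into the following January's winter.

## Synthetic cohorts

The generator draws `log IRT ~ Normal(μ, σ)` with

```
μ = log_irt_mu + log s(date) + log kit_effect + has_cf·log cf_irt_shift
    + (has_cf ∧ MI)·log mi_irt_suppression
```

where `s(date) = 1 + A·cos(2π(doy − 15)/365.25)` peaks mid-January and
troughs mid-July. Defaults (all synthetic choices, not estimates from any
real registry):

| parameter | default | why |
|---|---|---|
| `log_irt_mu`, `log_irt_sigma` | 3.267, 0.45 | median ≈ 26 ng/mL and population 95th percentile ≈ 55 ng/mL, putting the fixed cut-off at the conventional 95th–99th-percentile position |
| `seasonal_amplitude` A | 0.06 | a visible (~12% peak-to-trough) summer-lower seasonal swing |
| `kit_effects` | 3 kits, ×0.92–×1.10 | kit-to-kit reagent variation of the order seen in IRT assays |
| `cf_irt_shift` | ×4.0 | CF cases mostly, but not always, exceed the cut-off |
| `mi_fraction`, `mi_irt_suppression` | 0.18, ×0.35 | a meconium-ileus subgroup whose suppressed IRT often falls below the cut-off |
| `cf_prevalence` | 0.00025 | ≈ 1 in 4,000 births |
| `delay_model` | lognormal ages, median 20 d (reference) / 28 d (minoritized) | sweat-test scheduling friction concentrated in minoritized groups |

Ancestry is a categorical over `"Race|Ethnicity"` keys; *CFTR* alleles are
drawn i.i.d. per ancestry from frequency tables whose off-panel mass is
concentrated in minoritized groups, reproducing the panel-coverage gap the
equity analysis is about. Kits are assigned uniformly at random per specimen
(deliberately unconfounded with season, so kit and season effects are
separately recoverable).

What the generator does *not* emulate: birth-cohort drift over years,
assay-lot changes mid-kit, correlated family structure (sibling cases),
missing demographic data, or any real allele-frequency estimates. Passing
tests therefore demonstrate internal consistency of the algorithmic
machinery, not predictive accuracy for any real screening programme.

## The deterministic cohort fixture

`make_table1_fixture()` enumerates (no randomness) a 390-child CF registry
whose demographic margins reproduce a published statewide cohort table
cell-by-cell: 18 missed screens (12 low-IRT, 6 genetics), 30 delayed
diagnoses, and the printed race/ethnicity/sex counts of every column; 4 of
the 12 low-IRT missed have meconium ileus, the 3 minoritized low-IRT missed
are the 3 Black children, 4 of 6 genetics-missed are Hispanic and 5 of 6
minoritized, 13 of 30 delayed are minoritized, and 74 children (19%) are
minoritized overall. The source table's missed column is internally
inconsistent for two race cells (it prints Black 3 and Multiracial 1 where
its own sub-columns force 4 and 0); the fixture follows the sub-columns,
which the narrative case detail corroborates. The race×ethnicity joint
distribution is only partially determined by the margins; unforced joint
cells are arbitrary, fixed, and documented in the fixture source. IRT values
are representative constants consistent with each record's category. Shipped
panel files are fictitious stand-ins constructed so the six genetics-missed
genotypes reproduce the published detection pattern (4/6 on the 139-like
panel, 5/6 on the 689-like with one single-variant detection, 5/6 on the
NGS-like panel, which — like real NGS screening — misses the large-deletion
case).

## Equity statistics

Odds ratios are computed closed-form, `OR = ad/bc`, which for a binary
exposure equals the univariable logistic-regression estimate (the test suite
verifies this against an iteratively fitted logistic model to 1e-6 in
log-OR). CIs are Wald on the log scale; p-values are two-sided Wald. Zero
cells get the Haldane–Anscombe +0.5 added to all four cells, flagged
`corrected` in the output. Three outcome contrasts mirror the standard
reporting layout — delayed-or-missed, missed-only, delayed-only, each versus
on-time — with the excluded category dropped from *both* arms, so the
denominators differ by contrast and are derived, not hard-coded. The pooled
"other race" group is OtherRace ∪ Multiracial versus a White reference;
ethnicity is Hispanic versus NonHispanic. Raw p-values are reported;
"< 0.001"-style formatting belongs to the presentation layer. Rank
comparisons use the Wilcoxon rank-sum test (exact enumeration when both
n ≤ 8 and there are no ties, tie-corrected normal approximation otherwise)
and Kruskal–Wallis for > 2 groups, both via scipy.

## Numerical and design choices

- Sizes used by the default test/acceptance runs: 50,000-specimen streams
  for flag-rate calibration, 40,000-infant one-year cohorts for seasonal
  recovery, 1,000 simulated 269-child cohorts for OR recovery, 2,000 tables
  for CI coverage — large enough for the binomial/Monte-Carlo bounds the
  tests assert, and each runs in seconds.
- Determinism: one `numpy` Generator seeded from the run seed; the
  acceptance script spawns independent substreams per component so adding a
  component never perturbs another's draws. Fixed seed ⇒ byte-identical
  registry CSVs.
- Every output CSV carries a `# config_hash=` header (SHA-256 of the
  canonical JSON config, key-order independent) for provenance; the loader
  skips `#` lines.
- Degenerate inputs: empty percentile samples, all-zero contingency tables,
  empty rank-test groups and unknown kits/ancestries raise typed errors;
  empty registries produce all-zero summaries rather than failing.

## Known limitations

- The fixture's IRT values and diagnosis ages are representative constants:
  medians and IQRs of the real cohort's age-at-diagnosis distributions are
  not reproduced, only their orderings (one-variant delayed cases older at
  diagnosis than two-variant).
- Floating cut-offs computed *from a CF-only registry* (e.g. the fixture)
  describe that registry's stream, not a population stream; population-scale
  floating-cut-off questions should use a generated cohort as the stream.
- No multivariable or adjusted models, no multiple-testing correction, no
  survival-time modelling of diagnosis age — the analysis is deliberately
  univariable.
- Variant matching is purely lexical; panels mixing legacy and cDNA names
  for the same allele will undercount.
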