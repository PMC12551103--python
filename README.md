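# cfnbs — two-tier cystic-fibrosis newborn-screening simulation

`cfnbs` models and evaluates a two-tier newborn-screening (NBS) algorithm for
cystic fibrosis (CF): a first tier that compares immunoreactive trypsinogen
(IRT) measured in dried blood spots against a cut-off, and a second tier that
genotypes elevated-IRT specimens against a panel of *CFTR* variants. It is
written for screening-programme analysts and biostatisticians who want to ask
counterfactual questions of a screening registry: how many infants would a
floating (daily-percentile) cut-off send to genetic testing? which children
with CF would still be missed? how are missed and delayed diagnoses
distributed across race and ethnicity?

## The model

**Tier 1.** A specimen with IRT ≥ c on its collection day proceeds to
genotyping. Three cut-off rules are supported:

- *fixed*: c = c₀ (e.g. 55 ng/mL);
- *floating*: c = the day's trimmed q-th percentile Q̂_q (outliers
  ≥ 170 ng/mL are removed before estimation; q is typically 95 or 96;
  days with too few specimens pool backwards);
- *hybrid*: c = min(Q̂_q, c₀), a floating rule whose back-up fixed value
  stops an unusually high daily percentile from raising the cut-off.

Quantiles use the linear-interpolation estimator: with sorted x₍₁₎…x₍ₙ₎ and
h = (n−1)q/100 + 1, Q̂_q = x₍⌊h⌋₎ + (h−⌊h⌋)(x₍⌊h⌋+1₎ − x₍⌊h⌋₎). Trimming
affects estimation only — an IRT of 400 ng/mL still screens positive.

**Tier 2.** The infant's genotype g (0–2 variant names) is intersected with
the panel P; the detected count is |g ∩ P| counting both alleles, so a panel
homozygote counts 2. Zero detections is reported as a *negative* screen even
though IRT was elevated; one detection routes to sweat-chloride testing
(≥ 60 mmol/L CF-range, 30–59 intermediate, < 30 negative, QNS = quantity not
sufficient); two detections route directly to a CF centre.

**Outcomes.** A child with CF whose screen was negative is *missed* — either
`missed_low_irt` (tier 1) or `missed_genetics` (tier 2). A child with CF, a
positive screen, and a diagnosis more than 28 days after birth is *delayed*
(day 28 itself is on time). Equity contrasts are univariable odds ratios
OR = ad/bc from 2×2 group-by-outcome tables with Wald 95% CIs
exp(ln OR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d), and Haldane–Anscombe +0.5
correction when a cell is zero.

The synthetic-cohort generator draws IRT from a lognormal whose log-mean is
shifted multiplicatively by season (sinusoid peaking mid-January), reagent
kit, CF status, and meconium ileus (which suppresses IRT); *CFTR* alleles
come from ancestry-specific frequency tables whose off-panel mass is
concentrated in minoritized groups. See `docs/methods.md` for every
parameter and its default.

## Worked example

```python
from cfnbs import CutoffModel, classify_cohort, fixture_panel, make_table1_fixture, or_table

registry = make_table1_fixture()          # deterministic 390-child CF cohort
classified = classify_cohort(registry, fixture_panel("core"),
                             CutoffModel(mode="fixed", fixed_value=55))
print(classified.loc[classified["has_cf"], "category"].value_counts())

table = or_table(classified).set_index(["contrast", "group"])
print(table.loc[("delayed_or_missed", "Hispanic")])
```

prints

```
category
on_time            342
delayed             30
missed_low_irt      12
missed_genetics      6
```

i.e. 18 of the 390 children with CF (4.6%) had a false-negative screen — 12
below the IRT cut-off, 6 with no panel variant detected — and 30 were
diagnosed after 28 days despite a positive screen. The Hispanic-vs-non-Hispanic
odds ratio for a delayed-or-missed diagnosis in this cohort is 5.03
(95% CI 2.15–11.77, p = 0.0002): Hispanic children have five-fold higher odds
of a late or missed diagnosis than non-Hispanic children.

The same analyses are available from the shell:

```bash
nbs-sim simulate --n 50000 --seed 1 --out registry.csv
nbs-sim percentiles --registry registry.csv --q 95 --season-summary
nbs-sim screen --fixture --panel src/cfnbs/data/panel_core.txt
nbs-sim evaluate-cutoffs --fixture --panel src/cfnbs/data/panel_core.txt \
    --strategy fixed:55 --strategy floating:96 --strategy hybrid:96:60
nbs-sim run --config config.yaml
```

Panel files are plain text, one variant legacy name per line, `#` comments
allowed. The shipped panels under `src/cfnbs/data/` are small fictitious
stand-ins for the commercial 39/139/689-variant and hypothetical NGS panels,
whose true contents are laboratory-specific.

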