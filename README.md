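# hemimorph

A tested, reusable pipeline for comparing regional brain morphometry between
a post-surgical patient cohort (single preserved hemisphere per patient) and
controls (both hemispheres):

- **core model & IO** — a tidy per-participant/region/measure table with
  strict vocabulary enforcement (34 Desikan-Killiany cortical parcels,
  9 subcortical structures, 3 gross volumes), long CSV/TSV readers/writers,
  and a FreeSurfer-dialect `aparc`/`aseg` stats reader;
- **synthetic cohorts** — a generator that instantiates the analysis' own
  linear model (group, age, gender, additive + multiplicative scanner
  effects) so every stage is testable offline, plus the fixed 32-patient
  study roster used by the cohort statistics;
- **preprocessing** — measure-specific normalization (CSA by
  within-hemisphere mean parcel area; CV and subcortical volumes by total
  hemisphere volume GM+WM+LV, subcortical as percentages; CxT and gross
  volumes untouched) and 5th/95th-percentile winsorization stratified by
  group and hemisphere;
- **harmonization** — an empirical-Bayes location/scale model that removes
  additive and multiplicative scanner effects while preserving group, age,
  and gender structure;
- **univariate inference** — per-feature permutation-null GLM (group +
  age + gender, |β| exceedance p over label shuffles, optional exhaustive
  enumeration), Benjamini-Hochberg correction per measure family, and a
  BIC-approximation Bayes factor with 0.33/3 evidence bands;
- **multivariate classification** — pure-forward binary logistic regression
  with Rao score entry tests (p < 0.05), Nagelkerke R² with
  weak/moderate/strong bands and a 0.25 reporting floor;
- **cohort statistics** — ANOVA-F / pooled two-proportion-z matching tests,
  median/MAD summaries, and a gross-vs-regional Pearson correlation screen;
- **orchestration** — three contrasts × five feature families end to end,
  a resection-only sensitivity filter, JSON/CSV reports, and a markdown
  summary.

## Test

```sh
python -m pytest -q tests/
```

One acceptance test
(`test_acceptance.py::TestWorkedExamples::test_resection_only_counts_preserved_rh`)
is deliberately failing: it asserts a published ablation/resection split
that the printed patient roster cannot reproduce under the stated
classification rule. See the test docstring.

## CLI

All stages are exposed through one entry point:

```sh
hemimorph simulate --out table.csv --seed 3
hemimorph preprocess --in table.csv --out norm.csv --winsor 5,95
hemimorph harmonize --in norm.csv --out harm.csv --model model.json
hemimorph analyze --in harm.csv --contrast RHpat_vs_RHctrl --n-perm 1000 --seed 7 --out results.csv
hemimorph classify --in harm.csv --outcome RHpat_vs_RHctrl --family cxt --out selection.json
hemimorph cohort-report --roster roster.csv --control-females 24 --control-n 51 --out match.json
hemimorph xcorr --in harm.csv --subset all --alpha 0.0002 --out xcorr.csv
hemimorph run-study --in table.csv --out-dir study/ --n-perm 1000 --seed 1
hemimorph render --report study/report.json --out summary.md
```

Contrasts are `LHpat_vs_LHctrl`, `RHpat_vs_RHctrl`, `RHpat_vs_LHpat`;
families are `gross`, `cxt`, `csa`, `cv`, `subcortical`; the multivariate
outcomes add `ilae_high_vs_low` (patients only).

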