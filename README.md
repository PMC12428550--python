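# dxtrust

Trust scoring and override decisions for AI-generated clinical diagnoses.

AI decision-support systems for diagnosis are routinely second-guessed:
when a model's stated confidence is poorly calibrated and its reasoning is
opaque, clinicians override most of its suggestions and the system loses
its value. `dxtrust` implements a dynamic, auditable acceptance rule for
this setting — developed around cardiovascular admissions, where each case
pairs an AI-generated diagnosis (AIDx) with the clinician-documented
reference diagnosis (hDx) — together with the statistical machinery needed
to evaluate it on a cohort. It is aimed at researchers and clinical-AI
engineers who need an explicit, reviewable override policy rather than a
fixed confidence cutoff.

## The scoring rule

Each case receives a composite trust score

```
S_final = wc · S_conf + ws · S_sim + wl · S_len
```

- **S_conf** — the model's stated confidence (a percentage), normalized
  onto [0.5, 1.0]. The admissible band is 70–99%: anything below 70% is
  overridden outright, with no appeal to the other factors.
- **S_sim** — similarity between AIDx and hDx in [0, 1]: exact match after
  text normalization (lowercase, punctuation stripped, stopwords removed,
  Porter stemming) short-circuits to 1.0, otherwise a pluggable backend
  scores the pair (default: term-frequency cosine). A similarity below the
  0.10 cut-point forces an override as a text-quality constraint.
- **S_len** — a length prior: 1.0 for diagnoses of 30–100 characters,
  0.7 otherwise, discouraging vague or run-on outputs.

The weights and the acceptance threshold depend on the model's self-rated
transparency level — weaker explanations demand a stronger score:

| Transparency | wc | ws | wl | threshold |
|---|---|---|---|---|
| High | 0.50 | 0.30 | 0.20 | 0.55 |
| Moderate | 0.60 | 0.30 | 0.10 | 0.65 |
| Low | 0.40 | 0.50 | 0.10 | 0.70 |

The decision is `override = 1 if S_final < threshold else 0` (a score
exactly at the threshold is accepted). Transparency never acts as an
independent factor: it tunes the bar, but cannot rescue low confidence or
low similarity.

Around this rule the package provides:

- **Cohort statistics** — override rates with Wilson score 95% intervals,
  contingency tables, Pearson's χ² test of independence with Cramér's V,
  the transparency × confidence interaction grid, and pairwise post hoc
  comparisons (Tukey HSD on the binary override indicator, or
  two-proportion z-tests with Holm adjustment).
- **Threshold calibration** — deterministic grid search of per-transparency
  thresholds under an asymmetric loss in which a false acceptance (accepting
  an incorrect AI diagnosis) costs twice an unnecessary override.
- **Synthetic cohorts** — a seeded generator reproducing the stratified
  structure of the reference evaluation (transparency × confidence strata,
  latent correctness, Beta-mixture similarity, cardiovascular diagnosis
  texts), plus the reference evaluation's stratum counts embedded as exact
  fixtures.
- **A CLI and audit log** — `score`, `evaluate`, `calibrate`, `simulate`
  subcommands over delimited text files, each scored case appending one
  JSON audit record (confidence, transparency, similarity, applied
  threshold, composite score, gates, decision, config fingerprint).

## Worked example

```
$ dxtrust simulate --output cohort.csv --seed 1
wrote 6689 cases to cohort.csv (seed 1)

$ dxtrust score --input cohort.csv --output decisions.csv
scored 6689 cases: 1399 overridden (20.9%)

$ dxtrust evaluate --input decisions.csv
Overall override rate: 20.9% (1399/6689); 95% CI: 20.0-21.9%

Override rate by transparency level
level    override_rate_pct  k     n     ci_low_pct  ci_high_pct
LOW      75.2               118   157   67.9        81.3
MODERATE 36.4               1204  3307  34.8        38.1
HIGH     2.4                77    3225  1.9         3.0

Override rate by confidence range
range  override_rate_pct  k     n     ci_low_pct  ci_high_pct
70-79  100.0              148   148   97.5        100.0
80-89  28.9               1246  4309  27.6        30.3
90-99  0.2                5     2232  0.1         0.5

Chi-square test: statistic=1428.45 df=2 p=<0.0001 cramers_v=0.462
```

The simulated cohort reproduces the qualitative structure of the reference
evaluation: low-confidence cases (70–79%) are rejected almost universally,
high-confidence cases (90–99%) almost never, and at moderate confidence
the override rate falls as transparency rises (here 57.1% → 35.7% → 6.9%
across low/moderate/high in the 80–89 band). The χ² test confirms a strong
transparency–override association. Absolute rates differ from the original
cohort because the generator's similarity noise is a stated idealization,
not a fit to the source data.

The same workflow is available as a library:

```python
from dxtrust import CaseRecord, TransparencyLevel, decide

case = CaseRecord(
    case_id="A1",
    ai_dx="acute exacerbation of chronic systolic heart failure",
    human_dx="chronic systolic heart failure",
    confidence_pct=88.0,
    transparency=TransparencyLevel.MODERATE,
)
d = decide(case, backend="token-cosine")
print(d.override, d.reason.value, round(d.breakdown.s_final, 3))
# 0 accepted 0.831
```

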