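# Methods

## The decision model

`dxtrust` decides whether to accept or override an AI-generated diagnosis
using a composite trust score

S_final = wc · S_conf + ws · S_sim + wl · S_len,

compared against an acceptance threshold selected by the model's
self-rated transparency level (low / moderate / high). The rule is
override = 1 iff S_final < threshold; equality accepts, since the override
condition is a strict inequality. Two gates dominate the weighted sum:

1. **Confidence gate.** A stated confidence below 70% overrides
   immediately. Transparency is a gate modifier, never an independent
   factor — no combination of similarity, length or explainability can
   accept a sub-70% case.
2. **Similarity gate** (default mode `hard`). Similarity strictly below
   0.10 overrides, treating near-zero textual agreement as a quality
   defect rather than a score component. An alternative `clamp` mode
   instead floors S_sim at 0.10 and lets the weighted sum decide; it is
   provided because the source description of the 0.10 minimum admits
   either reading, and the two modes bracket the behavior.

### Score components

- **S_conf.** Stated confidence is given only as a percentage in the
  admissible band [70, 99]; its normalized codomain is [0.5, 1.0]. The
  exact normalization map is a genuinely open design point: the default is
  the affine map `0.5 + 0.5·(c − 70)/29`, chosen because it is the unique
  monotone linear map realizing both stated endpoints over the stated
  band. A `fraction` mode (`c/100` clamped to [0.5, 1.0]) is provided for
  sensitivity analysis. Confidences above 99% (which the generation
  protocol should never emit but real inputs might) are clamped to 99 with
  a warning; sub-70 values are handled by the gate, not the map.
- **S_sim.** Computed on normalized text: lowercase, punctuation stripped,
  whitespace tokenization, English stopword removal, Porter stemming. The
  stopword list and the stemmer are frozen in the package (the stemmer is
  a from-scratch implementation of the classic Porter algorithm, verified
  against its canonical vocabulary) so similarity scores are bit-stable
  across installations. If the normalized surfaces of the two diagnoses
  are identical and nonempty the score is 1.0 without consulting any
  backend; otherwise a named backend scores the pair and the result is
  clamped into [0, 1]. The default backend is term-frequency cosine —
  deterministic, dependency-free, and symmetric. A sentence-embedding
  backend can be registered under the same contract; embedding cosines can
  be negative, hence the clamp (the score enters a rule whose cut-point
  assumes nonnegativity).
- **S_len.** Binary: 1.0 for diagnoses of 30–100 characters inclusive,
  0.7 otherwise. Length is measured on the trimmed, whitespace-collapsed
  surface string — the band describes the text a clinician reads, not the
  stemmed token sequence.

### Default profiles

High transparency: wc = 0.50, ws = 0.30, wl = 0.20, threshold = 0.55.
Moderate: 0.60 / 0.30 / 0.10, threshold = 0.65. Low: 0.40 / 0.50 / 0.10,
threshold = 0.70. Confidence carries the largest weight everywhere; the
threshold ordering 0.70 > 0.65 > 0.55 encodes the conservative posture of
raising the bar when explanations are weaker. Input labels "Minimal",
"High Confidence" and "High Explainability + High Confidence" map onto the
low and high levels respectively; the merged high label reflects how the
generating model co-reports explainability and certainty.

## Statistical evaluation

The primary cohort measure is the override rate, reported overall and
within strata (transparency level; stated-confidence bands 70–79, 80–89,
90–99; and their interaction grid).

- **Intervals.** All proportions carry Wilson score intervals. The method
  is a package choice — the reference evaluation never names its interval
  method — adopted because the Wilson interval reproduces every reference
  interval at one decimal, at large n (1631/3307 → 47.6–51.0%) and small n
  (31/56 → 42.4–67.6%) alike, and because it remains sensible at the 0%
  and 100% cells that actually occur in the extreme confidence bands. The
  analytic bounds at k = 0 and k = n are snapped to exactly 0 and 1.
- **Association.** Pearson's χ² test of independence without continuity
  correction (the tables are 3×2; the reference expected counts match the
  plain E = row·col/N), with Cramér's V = sqrt(χ²/(N·(min(r,c)−1))) as the
  effect size. Expected-count margins equal observed margins exactly.
- **Post hoc.** Pairwise comparisons between strata use Tukey's HSD
  applied to the binary override indicator, so group means are override
  proportions and mean differences are proportion differences. Applying a
  homoscedastic studentized-range test to Bernoulli responses is
  statistically unusual (variances are p(1−p)); it is implemented as
  specified for comparability, and a two-proportion z-test with Holm
  adjustment is available as `method="ztest"` for users who prefer a
  proportion-appropriate test. Groups with fewer than two observations
  are excluded with a warning.

## Threshold calibration

The acceptance thresholds are tuned per transparency level by exhaustive
grid search (default grid [0.30, 0.95] in steps of 0.01) under the
asymmetric loss

loss = c_FA · #(accepted ∧ incorrect) + c_OV · #(overridden ∧ correct),

with default costs 2 : 1 — the direction (false acceptances cost more)
is a clinical-risk statement; the magnitude is a package default. The
search is deterministic: each case's score and gates are computed once
(they do not depend on the threshold), the loss curve follows by
vectorized comparison, and ties are broken toward the higher, more
conservative threshold. A consequence worth noting: on a cohort where
every case is correct, every threshold at or below the minimum score is
lossless, and the tie-break returns the highest such grid point — still
zero overrides, but not the grid minimum. Scores analytically equal to a
grid threshold are kept from flipping on floating-point rounding by a
1e-9 comparison tolerance. For unlabeled real data a configurable
correctness rule (similarity ≥ 0.5 after the exact-match short-circuit)
stands in for the latent label; synthetic cohorts carry the label
directly. Weights are not jointly optimized — the search varies only the
thresholds, holding the deployed weights fixed.

## Synthetic cohorts

The original cohort (6689 cardiovascular admissions with clinical notes)
cannot be redistributed, so the generator emulates its stratified
structure rather than its content:

- **Strata.** Fixed sizes per (transparency level × confidence range)
  cell — never sampled — defaulting to the reference interaction-cell
  sizes. The reference cells as printed total 6677, twelve short of the
  cohort total, with the shortfall in the moderate-transparency row; the
  default assigns those twelve to that row's largest cell (80–89,
  3182 → 3194) so the transparency margins (157/3307/3225) and the total
  6689 are honored. The embedded fixture tables preserve the printed
  values verbatim; no reconciliation can satisfy every printed margin at
  once.
- **Per case.** Stated confidence is a uniform integer within the
  stratum's band (only band membership is known). A latent correctness
  indicator is Bernoulli with the stratum's probability, defaulting to
  the complement of the cell's reference override propensity. Similarity
  is drawn from Beta(8, 2) for correct and Beta(2, 6) for incorrect cases
  — the correct-case distribution stochastically dominates, which the
  config validates — and is carried on the record as a precomputed score.
  Diagnosis text pairs come from a cardiovascular vocabulary (condition
  families plus subtypes, expanded through qualifier templates into the
  30–100-character band): correct cases pair the reference text with a
  lightly perturbed copy, incorrect cases with a different condition, so
  the similarity module can be exercised on the same cohort through a
  second, text-based path.
- **Determinism.** One `numpy` generator seeded from the config drives
  every draw; identical configs produce identical cohorts.

What passing tests on these cohorts do and do not show: they validate the
decision rule's structure (gate dominance, monotone override gradients
across confidence and transparency, parameter recovery) but not clinical
performance. The generator knows nothing of real note text, coding
practice, or the true joint distribution of similarity given confidence
and transparency — absolute override rates on synthetic cohorts
(≈ 21% overall) therefore differ from the reference 33.29%, while the
qualitative orderings are robust across seeds.

## Problem sizes and numerical choices

The test suite and acceptance script use the full 6689-case default
cohort for end-to-end checks, 1000 replicates of a 500-case stratum
(p = 0.3) for Wilson coverage (exact coverage at that design point is
95.5%), and a 5000-case planted-separation cohort for calibration
recovery; the whole suite runs in well under a minute. Other numerical
choices of note: score/threshold comparisons in `decide` are exact (the
strict-inequality tie rule is part of the model), Wilson bounds are
snapped at the degenerate cells, and report percentages are rendered at
one decimal to match the evaluation tables.

## Known limitations

- Transparency is the generating model's self-rating; the package treats
  it as an input label and does not model rating behavior.
- The Tukey-on-binary post hoc test is reproduced as specified; its
  assumptions are imperfect for proportions (see above).
- The confidence normalization map and the similarity-gate mode are
  principled defaults for under-specified details; both are configurable
  and the alternatives are first-class.
- No development/validation split is modeled for calibration; the search
  optimizes on the cohort it is given.
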