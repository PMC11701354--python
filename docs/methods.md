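# Methods

## The triage model

Stage 1 is a deterministic decision rule, not a fitted classifier. Each
indicator is a univariate predicate over one patient-record field (the
single exception, "leg pain ≥ back pain", compares two fields and is
documented as bivariate); the rule verdict is the conjunction of all
indicators. Indicators carry a role: *including* indicators state a
condition that must be present, *excluding* indicators a contraindication
that must be absent — internally both are stored as the predicate of the
required state, so "widespread pain — no" is `widespread_pain == false`
and "age ≤ 18 excludes" is `age_years > 18`. Every indicator is always
evaluated (no short-circuiting) so the per-indicator satisfaction vector
is complete for reporting and audit.

Threshold semantics are literal: DN4 strictly greater than 3 (first
satisfied at 4 on the integer scale); pain duration ≥ 3 months, NPRS
leg ≥ 5 and leg ≥ back inclusive. `evaluate_boundaries` reports the
minimal satisfying value per numeric indicator so these conventions are
machine-checkable.

Two rule profiles ship as YAML data. The `default` profile has six
including and seven excluding indicators. The `five_indicator` profile
drops the prior-back-surgery requirement: summaries of this class of tool
sometimes list only the five symptom-based indicators, and how strictly a
prior-surgery criterion should be applied is a genuinely open clinical
question, so both variants are provided rather than resolving it
silently.

Missing data: only the DN4 may be missing (it is a recent addition to
outcome registries). Under the default `missing_policy="review"`, a
record that fails *only* through missing fields is negative but flagged
`needs_manual_review`; under `"fail"` it is a plain negative. No
imputation is attempted.

Stage 2 (orthopaedic review of stage-1 positives) and the referral
decision are external labels. In data mode they come from a reference
CSV; in synthetic mode they are latent Bernoulli gates. The funnel
enforces nesting: referred ⊆ fast-track ⊆ stage-1 positive ⊆ assessed.

## Evaluation statistics

**Accuracy.** The triage indication (fast-track decision) is crossed with
the referral decision into a 2×2 table; Se = tp/(tp+fn),
Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn). A metric with an
empty denominator is an explicit `UNDEFINED` marker, never NaN or 0.
Percentages are rounded half-up to one decimal for reporting; raw
proportions are kept in machine output.

**Confidence intervals.** The CI method is selectable and every estimate
names the method used. Default is Clopper–Pearson (exact beta quantiles,
via statsmodels); Wilson score is available; the rule of three applies
only to boundary counts (k = 0 or k = n), where the 95% bound on the
empty side is 3/n. Published intervals for screening tools of this kind
are frequently not reproducible from any single standard method, so
transparency about the method was preferred over mimicking any
particular printed interval; point estimates are the comparable
quantities. Boundary bounds (k = 0 lower, k = n upper) are snapped to
exactly 0 and 1 to avoid float round-off.

**Agreement.** Cohen's κ, Fleiss' κ and the specific-agreement
proportions are implemented directly (the formulas are three lines each)
because the package needs conventions libraries do not provide: when
p_e = 1 — which forces p_o = 1 — κ is defined as 1 rather than NaN, and
empty-denominator agreement components propagate the `UNDEFINED` marker.
`sklearn.metrics.cohen_kappa_score` and
`statsmodels.stats.inter_rater.fleiss_kappa` serve as independent oracles
in the test suite (agreement to 1e-12), keeping implementation and check
on separate routes. Fleiss' κ with two raters equals Scott's π
(tested). A rater pair is flagged reliable iff κ ≥ 0.70. Multi-rater
positive/negative/overall agreement is pooled as the unweighted mean over
rater pairs — pooling schemes vary in the literature and the output
labels the scheme. Weighted κ, >2 categories and κ confidence intervals
are out of scope (the triage conclusion is binary).

**SUS.** Brooke's transform: odd items contribute (value − 1), even
items (5 − value), sum × 2.5, range 0–100. The transform is affine in
the items, so the group mean equals the transform of the per-item means
— this identity is exact and is property-tested. SD uses the sample
(n − 1) convention and is `UNDEFINED` for one respondent. Per-item
results are compared to the published Sauro–Lewis item benchmarks with
strict inequalities (odd: mean > benchmark; even: mean < benchmark).
The total score maps to Bangor's adjective scale (nearest anchor) and
the Sauro–Lewis curved letter grades; both band tables are package data
(`data/grade_bands.yaml`), with 68 — the published all-studies average —
as the above-average threshold. Note that under the published curved
grading a score of 74.2 falls in band B (74.1–77.1); secondary sources
sometimes label such scores "B+", but this package follows the published
band edges.

## The synthetic generators

The cohort generator emulates a heterogeneous orthopaedic waiting list.
Study conditions: 1025 patients per cohort, of whom a fraction 90/1025 is
latently stage-1 qualifying; 20/90 of those pass the orthopaedic review;
8/20 of those are referred. These funnel proportions are the generator's
defaults, and a law-of-large-numbers test at n = 10⁵ checks their
recovery within 3 binomial SD.

Marginal PROM distributions for real waiting-list cohorts are not
publicly available, so the defaults are deliberately simple placeholders,
fully overridable in `Marginals`: NPRS scores uniform-discrete on their
scales (leg ∈ {5..10} and back ≤ leg for qualifying patients), DN4 ~
binomial(10, p) with p = 0.65 for qualifying (truncated to > 3) and 0.30
for background patients, pain duration log-normal with median 24 months
(truncated to ≥ 3 for qualifying), age normal(55, 14), exclusion flags
at 5% each and conservative-treatment response at 30% in the background
population. Qualifying patients satisfy every indicator by construction;
background draws that accidentally satisfy the rule are re-spoiled by
violating one randomly chosen indicator, so latent qualifying status and
rule verdict coincide exactly (cross-module test). DN4 missingness is
missing-completely-at-random over the whole cohort at `dn4_missing_rate`
(default 0, so accuracy tests are clean).

What the generator does **not** emulate: correlation between PROMs
beyond what the funnel requires, clinically structured stage-2 decisions
(they are Bernoulli gates, because the orthopaedic review is a holistic
judgement with no published mechanism), secular drift, or informative
missingness. Passing tests therefore demonstrate that the machinery is
correct under the stated sampling model, not that the tool performs at
any particular level on real patients. One structural consequence:
because simulated referral is nested inside the fast-track gate, the
synthetic 2×2 table has fn = 0 by construction — simulated sensitivity
is always 100% and is a property of the simulation design, not evidence.

The rater simulator is a latent-class model: rater r calls a truly
eligible subject positive with probability `p_correct_positive` and a
truly ineligible subject negative with `p_correct_negative`, calls
conditionally independent given the latent label. This admits closed-form
expected kappas from the 2×2 cell probabilities, which the simulation
tests recover at n = 50 000 within Monte-Carlo error (±0.02). The
pipeline's default reliability exercise rates a 50-patient subsample,
stratified to roughly half eligible subjects (a reliability study run at
the raw ~9% waiting-list prevalence would make κ uninformative), with
four raters of mixed accuracy (0.97/0.97, 0.96/0.96, 0.82/0.85,
0.90/0.92) chosen once to span the good-to-excellent agreement range
clinician panels typically show. The published rating data of any real
exercise are not reproduced — per-rater accuracies are not identifiable
from summary kappas — so reliability values in synthetic reports are
illustrative.

The SUS generator inverts the scoring problem: given per-item mean
targets it builds integer 1–5 columns whose sums hit the nearest
achievable integer total (error if no total matches the target within
0.005, half a unit of two-decimal printing), then shuffles within
columns. Its default targets are the published six-user item subscores
(4.17, 2.17, 4.17, 1.83, 3.50, 2.17, 4.17, 2.17, 3.83, 1.83), whose
transform reconstructs the published mean of 74.2; per-respondent score
dispersion is *not* controlled (only item means are), so the simulated
SD does not reproduce any published SD.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` with mandatory
  seeds; sub-streams in the pipeline are derived with `SeedSequence`
  spawn keys, so identical config + seed gives byte-identical JSON
  reports.
* Problem sizes in the test suite (10⁵-patient funnel check, 5 × 10⁴
  subject rater simulations, 10⁴-record brute-force cross-checks,
  exhaustive 2¹³ truth-table enumeration) were chosen as the smallest
  sizes at which the 3-SD / ±0.02 Monte-Carlo tolerances are comfortably
  discriminating.
* CSV dialect: UTF-8, comma separator, header row, booleans as
  `true`/`false`, empty cell = missing.
* The public API is functions over small frozen dataclasses / pydantic
  models rather than fit/transform estimator classes: nothing in the
  method has trainable state, so estimator semantics would be hollow.

## Known limitations

* The rule treats "absolute contraindications" and "widespread pain" as
  boolean inputs; their operational definitions are a clinical-governance
  matter outside this package.
* Stage-2 realism is the main gap between simulation and reality (see
  above); consequently synthetic accuracy metrics other than specificity
  are structurally optimistic.
* No ROC/threshold analysis: the rule is binary by construction.
* Reported kappas/agreements of any specific historical rating exercise
  cannot be regenerated without the underlying rating matrices.
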