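# scs-triage

Two-stage triage for early referral to spinal cord stimulation (SCS),
packaged as a rule engine, a synthetic-cohort simulator, and the full
evaluation battery used to validate such a tool.

## The problem

Patients with chronic low back and leg pain (CLBLP) can wait many months
for an orthopaedic consult. A subset of them — typically patients with
leg-dominant neuropathic pain after back surgery who have exhausted
conservative treatment — are candidates for spinal cord stimulation and
gain nothing from that wait. A triage tool applied to the waiting list,
using only patient-reported outcome measures (PROMs) and referral
information, can pull those patients onto a fast track.

This package implements that triage as a two-stage screen and the
statistics needed to evaluate it:

* **Stage 1 (rule engine)** — a strict conjunction of declarative
  indicators over a patient record. The default profile has six including
  indicators (prior back surgery; pain location leg/mixed; DN4 > 3;
  pain duration ≥ 3 months; NPRS leg ≥ NPRS back; NPRS leg ≥ 5) and seven
  excluding indicators (absolute contraindications, widespread pain,
  alcohol/drug abuse, response to PRF/TENS/medication, prior SCS,
  anatomic abnormalities, age ≤ 18). A patient is stage-1 positive only
  if every including indicator is present and every excluding indicator
  absent. Rules are YAML data, not code.
* **Stage 2** — an orthopaedic review of the stage-1 positives, treated
  as an external label (real data or a latent Bernoulli gate in
  simulation); stage-2 passes enter the fast track, and some are referred
  to the chronic pain department.
* **Evaluation** — diagnostic accuracy of the triage indication against
  the referral decision (Se, Sp, PPV, NPV from a 2×2 table with
  Clopper–Pearson, Wilson or rule-of-three 95% CIs); inter-/intra-rater
  reliability (Cohen's κ, Fleiss' κ, overall/positive/negative specific
  agreement, reliability threshold κ ≥ 0.70); and System Usability Scale
  scoring with per-item benchmarks and Bangor / Sauro–Lewis grading.

For the agreement statistics, with observed agreement p_o and chance
agreement p_e, κ = (p_o − p_e)/(1 − p_e); Cohen's κ takes p_e from the
two raters' own marginals, Fleiss' κ from pooled marginals (Scott's π for
two raters). Specific agreement for a paired 2×2 table with cells
a, b, c, d is 2a/(2a+b+c) (positive) and 2d/(2d+b+c) (negative).

## Worked example

Predictive accuracy from the 2×2 counts of a waiting-list screen in which
20 patients received a triage indication, 8 of whom were referred, and
none of the 1005 triage negatives were:

```python
from scs_triage import ContingencyTable2x2, accuracy_metrics
print(accuracy_metrics(ContingencyTable2x2(tp=8, fp=12, fn=0, tn=1005)).to_text())
```

```
Predictive accuracy (triage indication vs. reference referral)
  counts: tp=8 fp=12 fn=0 tn=1005
  sensitivity: 100.0% (95% CI 63.1-100.0, clopper_pearson)
  specificity: 98.8% (95% CI 97.9-99.4, clopper_pearson)
  positive predictive value: 40.0% (95% CI 19.1-63.9, clopper_pearson)
  negative predictive value: 100.0% (95% CI 99.6-100.0, clopper_pearson)
```

Sensitivity 100% means no referred patient was missed by the triage;
PPV 40% means 4 in 10 fast-tracked patients were ultimately referred —
acceptable for a screen whose cost of a false positive is one early
consult. A full synthetic evaluation run (cohort, funnel, accuracy,
reliability, usability) is one call:

```python
from scs_triage.pipeline import RunConfig, run
print(run(RunConfig(seed=42)).to_text())
```

```
Evaluation report (seed 42)
  funnel: 1025 assessed -> 84 stage-1 positive -> 22 fast-track -> 7 referred
Predictive accuracy (triage indication vs. reference referral)
  counts: tp=7 fp=15 fn=0 tn=1003
  sensitivity: 100.0% (95% CI 59.0-100.0, clopper_pearson)
  specificity: 98.5% (95% CI 97.6-99.2, clopper_pearson)
  positive predictive value: 31.8% (95% CI 13.9-54.9, clopper_pearson)
  negative predictive value: 100.0% (95% CI 99.6-100.0, clopper_pearson)
  inter-rater: Fleiss kappa 0.78; pairwise Cohen kappa 0.92, 0.76, 0.72, 0.84, 0.80, 0.64
  intra-rater: Cohen kappa 0.92
  usability: mean SUS 74.2 ('good'/B)
```

The funnel counts fluctuate around their expectations (90, 20, 8 per 1025
assessed) with binomial noise; the usability block scores a six-user SUS
response set whose item means match the published per-item subscores.

There is also a CLI (`triage generate`, `triage run`, `triage triage`,
`triage accuracy`, `triage agree`, `triage sus`, `triage reproduce`); see
`triage --help`.

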