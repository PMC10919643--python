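# Methods

## Scope and model

`dicscore` implements five rule-based diagnostic scores for disseminated
intravascular coagulation (DIC) — KSTH, ISTH overt DIC, JAAM, revised JAAM
(R-JAAM) and JMHW — over a single patient-day of coagulation labs, and
evaluates their DIC calls as predictors of in-hospital mortality.  Each
rubric is a weighted sum of banded items with an integer positivity
threshold:

| item | KSTH | ISTH | JAAM | JMHW |
|---|---|---|---|---|
| platelets, ×10⁹/L | ≤100 → 1 | ≤100 → 1, ≤50 → 2 | [80,120) or >30% 24-h drop → 1; <80 or >50% drop → 3 | (80,120] → 1, (50,80] → 2, ≤50 → 3 |
| PT | prolongation ≥3 s → 1 | ≥3 s → 1, ≥6 s → 2 | ratio ≥1.2 → 1 | ratio [1.25,1.67) → 1, ≥1.67 → 2 |
| aPTT | prolongation ≥5 s → 1 | — | — | — |
| fibrin marker, μg/mL | D-dimer ≥1.0 → 1 | D-dimer [1,5) → 2, ≥5 → 3 | FDP [10,25) → 1, ≥25 → 3 | FDP [10,20) → 1, [20,40) → 2, ≥40 → 3 |
| fibrinogen, g/L | ≤1.5 → 1 | ≤1.0 → 1 | ≤3.5 → 1 | (1.0,1.5] → 1, ≤1.0 → 2 |
| SIRS | — | — | ≥3 → 1 | — |
| clinical items | — | — | — | underlying disease / bleeding / organ failure, 1 each |
| DIC at total ≥ | 3 | 5 | 5 | 7 |

R-JAAM is JAAM with the fibrinogen item removed, evaluated at the same
threshold (no separately published cut-off exists; the threshold is a policy
knob).  KSTH and ISTH band D-dimer; the JAAM family and JMHW band FDP — no
cross-substitution by default, because the two fibrin-related markers are
not numerically interchangeable.  An opt-in policy flag
(`fibrin_marker_fallback`) allows scoring the other marker against the same
bands with an attached warning, for exploratory work on incomplete panels.

### Boundary conventions

Published rubric tables often print touching bands ("80–120" next to
"50–80").  Every band here is half-open so each value maps to exactly one
band: for falling markers (platelets, fibrinogen) the more severe band takes
the shared endpoint (e.g. JMHW platelets ≤50 scores 3 and (50, 80] scores
2); for rising markers (PT ratio, FDP) bands are closed on their listed
lower bound (e.g. PT ratio [1.25, 1.67) scores 1).  The complete convention
table is `dicscore.policy.BOUNDARY_CONVENTIONS` and is embedded in every
report for provenance.  Band-edge behaviour is pinned by dedicated tests and
by factorial-grid comparison against literal nested-conditional
re-implementations of each rubric.

### PT handling

The KSTH/ISTH PT items are interpreted as *prolongation* over a laboratory
reference PT (patient − reference, seconds); JAAM and JMHW use the PT
*ratio* (patient / reference).  Records may carry their own reference PT and
aPTT; otherwise the policy defaults apply (12.0 s PT, 30.0 s aPTT — typical
laboratory midpoints, intended to be overridden with site values).  This
interpretation matches the standard usage of these criteria, whose compact
published tables presume it.

### SIRS

The SIRS sub-score (a JAAM input) uses the standard consensus thresholds:
one point each for temperature >38 or <36 °C, heart rate >90/min,
respiratory rate >20/min, WBC >12 or <4 ×10⁹/L, with strict inequalities (a
value exactly at a threshold scores 0).  The band-count (>10% immature
neutrophils) arm of the WBC criterion is omitted because differential counts
are not part of the record schema.  Missing components contribute 0 with a
warning; all four missing is an error.  A precomputed SIRS value on the
record takes precedence over derivation from vitals.

### Missing data

The default missing-marker policy is `strict`: a criterion whose required
marker is absent raises an error naming the marker and criterion, and
`score_all` reports which criteria succeeded and which failed.  The
alternative `score_zero_with_warning` mode scores absent components 0 for
exploratory use — silent zeros bias totals downward, so this is never the
default.  The JAAM platelet-drop clauses are active only when a prior-24-h
platelet value exists; otherwise only the absolute bands apply and a warning
is attached (single-day data rarely has trend information).

## Evaluation

The condition-positive state is in-hospital death, the test-positive state
is the DIC call; sensitivity, specificity, PPV, NPV and accuracy are
computed from the resulting 2×2 table with the defining fractions retained
on every metric.  Zero-denominator metrics are flagged undefined, never
reported as 0 or 1.  Patients with unknown outcome are dropped with a logged
count.  Two identities are asserted in the test suite on randomized tables:
accuracy = sens·prev + spec·(1−prev) and the Bayes relation
PPV = sens·prev / (sens·prev + (1−spec)(1−prev)).

Percent display: diagnostic metrics are truncated toward zero at one
decimal (147/154 → 95.4); prevalence and the discharged/expired splits are
conventionally rounded (107/142 → 75.4).  Clinical reports of this kind mix
both conventions; each table type here follows the convention its published
counterparts evidently use, the choice is stated in the report footer, and
full-precision values are always available programmatically.

Group comparisons (survivors vs non-survivors) dispatch on the declared
variable kind: dichotomous → Pearson chi-square without continuity
correction, switching to Fisher's exact test when any expected cell count is
below 5; continuous-normal → Student's two-sample t-test with mean ± sd
summaries; continuous-skewed → two-sided Mann–Whitney U with median (IQR)
summaries.  All p-values are two-sided.  Whether a given published analysis
used continuity correction is generally unstated, so reproductions of
published p-values should be direction-checked rather than digit-matched.

## Synthetic cohort generator

The generator emulates a retrospective sepsis cohort under clinical
suspicion of DIC.  The outcome is drawn first (Bernoulli, default
in-hospital mortality 69.4%, default n = 222); all markers, vitals and flags
are then drawn from outcome-conditional distributions.

* **Families.** Positive, right-skewed markers (platelets, PT, aPTT,
  D-dimer, FDP, fibrinogen, WBC, heart rate, respiratory rate, lactate) are
  lognormal; temperature and mean arterial pressure are normal.  Lognormal
  parameters are solved from per-group median/IQR summaries: μ = ln(median),
  σ = (ln q₃ − ln q₁)/(2 z₀.₇₅) with z₀.₇₅ ≈ 0.6745.
* **Censoring.** FDP is left-censored at the assay floor of 5 μg/mL with the
  underlying log-median at the floor, which reproduces degenerate published
  quantiles of the form 5.0 (5.0–16.2); σ is then solved one-sided from the
  upper quartile.
* **Units.** Fibrinogen is calibrated in mg/dL (the scale of the published
  summaries) and divided by 100 at generation, so records carry g/L.
* **Calibration targets** (survivor / non-survivor medians): platelets
  82/55 ×10⁹/L, PT 16.2/20.3 s, aPTT 35.0/40.7 s, D-dimer 6.0/7.7 μg/mL,
  FDP 5.0/5.0 μg/mL, fibrinogen 258/216 mg/dL, plus vitals, lactate, SOFA
  (normal, median 8 vs 13) and dialysis/ventilation/septic-shock flag rates
  (19.1/39.0, 22.1/48.1, 80.9/99.4 %).
* **Unpublished quantities, chosen once.** WBC has no per-group summary;
  it is lognormal with medians 12 (8–18) vs 15 (9–22) ×10⁹/L — plausible
  sepsis leukocytosis.  The three JMHW clinical items have no published
  rates; defaults are underlying disease 0.60/0.70, bleeding 0.10/0.20,
  organ failure 0.70/0.90 (survivor/non-survivor) for a cohort in which
  nearly all patients have sepsis-associated organ dysfunction.
* **SIRS** is drawn from a per-group integer distribution matching
  median (IQR) 3 (2–3) vs 3 (3–4) rather than derived from the generated
  vitals, avoiding double-specification of the same information; a
  `sirs_mode="derive"` option exists for consistency testing.
* **Assessment day** follows the published mix — 44.3 / 33.3 / 13.1 / 4.2 /
  3.4 % on days 1–5 — with the ~1.7% remainder spread evenly over days 6, 8,
  10 and 11 (the published remainder is four individual patients; the even
  spread is an implementation choice).
* **Platelet trend.** A prior-24-h platelet value is generated for a
  configurable 30% of records via a multiplicative drop factor
  (drop ~ N(0.15, 0.20) truncated to [−0.5, 0.85]), exercising the JAAM
  drop clauses; no published trend data exists.
* **Independence.** Markers are independent given the outcome group — no
  published correlation structure exists to calibrate against.  This is the
  generator's main infidelity to real data: real coagulopathy produces
  correlated derangements, so joint tail behaviour (and therefore any
  cohort-level DIC prevalence computed on synthetic data) will differ from a
  real cohort.  Tests on synthetic cohorts therefore assert marginal
  recovery and structural orderings (KSTH prevalence > ISTH; JAAM ≥ R-JAAM,
  which hold by rubric nesting), never published cohort-level prevalences or
  metric values.

Determinism: a seed is mandatory; identical (config, seed) yields an
identical cohort, and the whole simulate → score → evaluate pipeline is
byte-reproducible (no timestamps in outputs; logging goes to stderr).

## Problem sizes in the test suite

Factorial oracle grids use 3 000–10 000 points per rubric; randomized
invariant suites use 1 000 instances each; simulator-recovery checks use
n = 10 000 (10% relative tolerance on per-group medians, ±1.5 percentage
points on the mortality fraction — 3–4 Monte-Carlo standard errors at that
n); the permutation cross-check of the rank-sum route uses 2 000 resamples.
The full suite runs in well under a minute.

## Known limitations

* SOFA is a pass-through covariate; it is never derived from organ-level
  inputs.
* No ROC/AUC over raw score totals, no survival modelling beyond the binary
  in-hospital outcome, and no treatment/anticoagulation effects.
* The ICD-9 sepsis screen expands printed ranges over the tenths digit and
  treats "all sub codes" entries as prefix matches; codes outside the two
  supported definitions are ignored rather than validated against the full
  ICD-9-CM catalogue.
* The fibrinogen mg/dL heuristic (values > 30 are divided by 100) can in
  principle misclassify a true g/L value above 30, which is physiologically
  implausible; an explicit unit column always overrides it.
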