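# Methods

## Scope and model

`strokecourse` implements a two-cohort derive/validate protocol for
predicting acute cerebral ischaemia outcome from early clinical data:

1. **Screening.** A registry of screened admissions is filtered by an
   ordered, auditable exclusion cascade (no GP contact, haematoma,
   venous thrombosis, admission beyond 24 h, thrombolysis; then
   imprecise symptom course, insufficient GP data, diagnostic doubt;
   plus a prior-dependency criterion). First-match-wins attribution
   keeps every record counted exactly once, and the audit reconciles
   exactly: eligible + all exclusions = screened.
2. **Scoring.** Severity is measured on the standard 15-item NIHSS
   (total 0–42) and on an 11-item patient/family-reported Neurological
   Dysfunction Score, the NDS (each item ordinal 0 normal … 3 worst,
   total 0–33). Any item may be *unknown*; totals run over known items
   only. Unknown prehospital (GP) NIHSS items are completed from the
   admission examination when the NDS changed by < 2 points over the
   same interval, and disregarded otherwise.
3. **Course.** Between consecutive first-day examinations, a step is
   *worsening* when the NIHSS rises by ≥ 4 **and** the NDS by ≥ 2
   (conjunctive when both instruments cover the interval; one score
   decides alone when the other is missing), *regression* for the
   mirror decreases, *stable* otherwise. Courses with ≥ 2 alternations
   between worsening and regression are polyphasic/fluctuating; ≥ 2
   consecutive worsening steps without any regression are
   polyphasic/progressive; otherwise the course is monophasic — a
   regression step present makes it a total regression (final NIHSS 0)
   or partial regression (final NIHSS > 0), else stable. Per patient we
   extract NIHSS-max and NDS-max over the first-day series and the
   plateau (minutes at maximal deficit before regression), taking the
   patient/family anamnesis value when present and the series-derived
   value otherwise (capped at the 24 h window).
4. **Thresholds.** For a binary outcome with prevalence *p* (good:
   mRS 0–1; poor: mRS 4–5 or death, i.e. mRS > 3) and an error-overcost
   ratio Δ = (costFP − costRN)/(costFN − costRP), the operating point on
   the empirical ROC curve of a predictor (initial NIHSS or plateau
   duration) is the point where the tangent slope equals
   S = ((1 − p)/p)·Δ. Since an empirical ROC is a step function, the
   tangent condition is realised as maximisation of Se − S·(1 − Sp),
   which on the upper convex hull selects exactly the point where
   adjacent hull-segment slopes bracket S. Predictive values use the
   prevalence-weighted forms PPV = pSe/(pSe + (1−p)(1−Sp)) and
   NPV = (1−p)Sp/((1−p)Sp + p(1−Se)).
5. **Validation.** The cutoff and orientation frozen on the derivation
   cohort are applied unchanged to an independent cohort; Se and Sp are
   recomputed from the confusion counts.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| Δ (error overcost) | 2 | net cost of a false positive over a false negative; 2 weights the cutoff toward high PPV |
| prevalence *p* | cohort-empirical | rate of the positive outcome; user-suppliable (e.g. registry-based) |
| worsening/regression steps | ±4 NIHSS, ±2 NDS | minimum change that counts as a direction change |
| NDS stability window | \|ΔNDS\| < 2 | gates imputation of unknown GP items |
| plateau cap | 1440 min | the 24 h observation window |
| cutoff placement | midpoint between adjacent distinct scores | reproducible and orientation-symmetric |
| tie-break | higher specificity | among equal-objective ROC points |

## Synthetic cohorts

No patient-level data exist for this design, so the generator emulates
the published marginal structure of the original 154-patient cohort:

* discharge mRS from the published distribution (73/27/10/15/12/17 over
  mRS 0-1/2/3/4/5/death; the 0-1 bin is split evenly — immaterial, as
  every dichotomy groups 0 and 1);
* NDS-0, NIHSS-GP and plateau drawn per outcome group (mRS 0–3, 4-5,
  death) from truncated normals on the instrument ranges. The truncated
  *mean* is moment-matched exactly to the published group mean by a 1-D
  root solve; the spread targets the SD back-solved from the printed
  95% CI ((hi − lo)/2 · √n / 1.96) by bounded least squares. For the
  death group the back-solved SDs slightly exceed what any truncated
  normal with that mean can attain on the bounded range (the printed
  upper CI for NDS-0 even exceeds the instrument maximum), so the SD is
  best-effort there while the mean stays exact;
* course types from the published first-day mixture (stable 62, total
  regression 36, partial regression 36, fluctuating 10, progressive 10
  of 154), realised as serial NIHSS trajectories whose steps satisfy
  the ±4 rule. A label that requires a ≥ 4-point step is only
  realisable above a severity floor (e.g. total regression needs
  NIHSS-GP ≥ 4), so drawn labels are randomly assigned among patients
  whose drawn severity admits them — both marginals are preserved, at
  the price of a mild artificial severity–course coupling;
* per-item unknown rates for the GP score (dysarthria 21/154, neglect
  11/154, visual loss 9/154, ataxia 8/154), and an admission NDS
  generated as ≈ 0.79 × admission NIHSS plus noise (SD 2.5) so the two
  admission instruments cohere;
* outcome group, course type and ischaemia category are independent
  marginals: their joint distribution is not published.

What the generator does **not** emulate, hence what passing tests do
not show about real data: severity differences *within* the mRS 0–3
group (mRS 0-1 and 2-3 draw from the same distribution, so no predictor
can separate a good outcome from a moderate one — with Δ = 2 the
good-outcome objective Se − S(1−Sp) is non-positive at every non-trivial
ROC point on large default cohorts and the good-outcome cutoff can
degenerate to the "never call good" endpoint), plateau–course coupling
beyond the outcome group (no copula), imaging findings, aetiology and
risk-factor covariates, and anamnesis elicitation error (the anamnesis
is always present; disagreement with the series-derived plateau beyond
120 min only raises a consistency warning).

## Numerical choices and degenerate inputs

* Empirical ROC: one operating point per distinct score plus the two
  trivial endpoints; ties grouped at one cutoff; computed by cumulative
  counts over sorted distinct values (O(n log n)).
* An assessment with every item unknown has an undefined total and is
  excluded from the series rather than scored.
* PPV/NPV with a zero denominator (no predicted positives/negatives)
  are flagged as undefined (`None`), not raised.
* Pearson chi-square is computed without continuity correction;
  a zero margin is an error. Squared Pearson correlation is undefined
  (`None`) for constant series.
* Registry and cohort generation are reproducible field-for-field from
  the seed; infeasible draws (e.g. a course label with no admissible
  patient left) raise a generation error rather than silently skewing
  the mixtures.

## Open design points resolved here

* The NDS has no published numeric coding; items are scored 0–3, which
  makes the 0–33 range consistent with the published death-group mean
  of 31.5.
* "Disregarded" scores under an unstable NDS are read item-wise (the
  item stays unknown), not as discarding the whole GP assessment.
* A single isolated worsening step is classified monophasic/stable:
  it meets neither the ≥ 2-consecutive-worsening bar for progressive
  nor any regression criterion.
* The initial-severity predictor is the (imputed) prehospital NIHSS-GP
  total; the plateau predictor prefers the anamnesis value.

## Problem sizes

The test suite and the acceptance script work at the protocol's own
scale for pipeline quantities (361-registry, 154-patient derivation and
157-patient validation cohorts) and at n = 5000 for generator
calibration checks; the derive/validate replication study uses 100
independent cohort pairs of n = 1000, a size at which operating
characteristics are estimated to ~2 percentage points.

## Known limitations

Thresholds are reported without confidence intervals; ROC curves are
empirical (no binormal smoothing); vascular territory and deficit side
are carried only as labels; and the published headline cutoffs
(NIHSS < 5 / > 22, plateau 135 / 1230 min) depend on unpublished raw
patient data, so synthetic cohorts reproduce the *procedure* and the
published marginal structure, not those exact cutoff values.
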