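# strokecourse

Early clinical course analysis and cost-weighted outcome thresholds for
acute cerebral ischaemia (ischaemic stroke and TIA) cohorts.

The package is aimed at clinical epidemiologists and biostatisticians
studying the *natural course* of cerebral ischaemia in the first
24 hours: it turns serial bedside severity scores into course labels and
end points, and derives/validates decision thresholds for discharge
outcome. It implements, as a tested pipeline:

* **Cohort model** — itemized NIHSS (15 items, total 0–42) and NDS
  (11 patient/family-reported items, total 0–33) assessments with
  unknown-item support; modified Rankin Scale (mRS) outcome
  dichotomies; a wide-CSV interchange format.
* **Screening** — an ordered, auditable exclusion cascade over a
  screening registry with exact count reconciliation.
* **Course dynamics** — imputation of unknown prehospital (GP) NIHSS
  items from the admission examination under NDS stability; step-wise
  worsening/regression classification (±4 NIHSS and ±2 NDS points);
  monophasic/polyphasic course labels; NIHSS-max, NDS-max and plateau
  (duration at maximal deficit) extraction.
* **Threshold engine** — empirical ROC curves and the cost-weighted
  operating point where the tangent slope equals

  ```
  S = ((1 − p) / p) · Δ,     Δ = (costFP − costRN) / (costFN − costRP)
  ```

  realised on the discrete curve as the maximiser of `Se − S·(1 − Sp)`,
  with prevalence-aware predictive values
  `PPV = p·Se / (p·Se + (1−p)(1−Sp))` and
  `NPV = (1−p)·Sp / ((1−p)·Sp + p(1−Se))`.
* **Evaluation** — frozen-threshold validation on an independent
  cohort, score-coherence r², 2×2 chi-square association tests, and a
  `run-all` pipeline with a JSON manifest.
* **Synthetic cohorts** — a generator reproducing the published
  marginal structure (outcome mixture, outcome-group score and plateau
  distributions, first-day course mixture, GP item missingness) so the
  whole pipeline is testable without patient data.

## Worked example

```
$ strokecourse run-all --seed 1 --outdir demo
wrote demo/manifest.json
good_nihss_initial: cutoff=0.5 Se=0.10/Sp=0.96 -> validation Se=0.09/Sp=0.95
good_plateau_min: cutoff=82.5 Se=0.24/Sp=0.98 -> validation Se=0.17/Sp=0.92
poor_nihss_initial: cutoff=21.5 Se=0.38/Sp=0.98 -> validation Se=0.23/Sp=0.96
poor_plateau_min: cutoff=1240.0 Se=0.54/Sp=0.99 -> validation Se=0.43/Sp=0.96
```

This simulates a 154-patient derivation cohort and an independent
157-patient validation cohort, screens a 361-row registry (361 → 206
ischaemic admissions within 24 h → 154 eligible), classifies every
patient's first-day course, and derives Δ = 2 cost-weighted thresholds.
Read the lines as: *a prehospital NIHSS above 21.5 predicts a poor
outcome (mRS 4–5 or death) with 38% sensitivity and 98% specificity on
the derivation cohort, holding at 23%/96% on the independent cohort;
symptom persistence beyond ~1240 minutes behaves similarly.* Good- and
poor-outcome thresholds are oriented oppositely (a *low* score or
*short* plateau calls a good outcome). With Δ = 2 false positives cost
twice false negatives, pushing cutoffs toward high PPV; at this cohort
size the high-severity cutoffs sit in the low-20s NIHSS range and near
21 h of symptom persistence. The same steps are available piecewise
(`simulate`, `screen`, `classify`, `derive-thresholds`, `validate`) and
as library functions (`strokecourse.run_all`, `derive_thresholds`, …).

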