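# Methods

## The scoring model

A risk score is a sum of integer points over declarative items.  Each item
carries a list of conditions (`field op threshold` or a boolean flag) that
are OR-combined; an item with no conditions always fires, which is how the
Khorana cancer-site point (fixed at 1 for lymphoma) and the composite
"Hb < 100 g/L **or** ESA use" item are expressed.  Band classification uses
two integer breakpoints — the largest total still *low* and the largest
still *intermediate* — which expresses both the Khorana rule
(0 | 1–2 | ≥ 3) and the ThroLy rule (0–1 | 2–3 | > 3).

The shipped default item sets follow the original score publications:

* **Khorana**: lymphoma site (1), PLT ≥ 350×10⁹/L (1), Hb < 100 g/L or ESA
  use (1), WBC > 11×10⁹/L (1), BMI ≥ 35 kg/m² (1).
* **ThroLy**: prior VTE (2), reduced mobility (1), obesity BMI ≥ 30 (2),
  extranodal localization (1), mediastinal involvement (1), neutropenia
  NE < 1.0×10⁹/L (1), Hb < 100 g/L (1).

Both are JSON configuration (`src/lymphovte/data/`), overridable by users;
the engine never hard-codes weights.  **mThroLy** is produced by rewriting
the single hemoglobin item's threshold to 110 g/L.  Because Hb ≥ 110 g/L
acts as a protective factor, the predicate is strictly `hb < 110`: the
boundary value 110 earns no point.

**Missing values.**  Any optional field absent from a record is *unknown*.
A scoring condition on an unknown field evaluates false (the item
contributes 0 points) and a warning is logged — retrospective registries
are incomplete, and a silent zero with an audit trail is the least
surprising rule.  Binary *diagnostic tests* are stricter: a threshold or
composite test whose deciding field is missing raises an error naming the
field, because a risk cascade must not silently default on its own marker.

## Combined testing and the staged cascade

Simultaneous (parallel) combination is logical OR over children;
sequential (serial) combination is logical AND evaluated in declared order
with short-circuit, mirroring staged lab ordering (cheap screens gate
expensive assays).  For any tests A, B and any cohort,
positives(serial(A,B)) ⊆ positives(A) ⊆ positives(parallel(A,B)), hence
sensitivity is monotone up the chain and specificity monotone down — this
is property-tested on random cascades.

The staged cascade is
`serial( parallel(mThroLy high, D-dimer > 1345 µg/dL), 0.125·TM + 0.194·TAT > 3.26 )`.
Comparator conventions: the cascade's D-dimer test is strict `>` (its
operational definition), while the univariate risk-factor dichotomization
uses `≥ 1345`; both are explicit configuration.  The composite cutoff is
strict `>` as well, so a composite of exactly 3.26 is negative.  The
0.125/0.194 weights are logistic regression coefficients (B values) for TM
and TAT; they ship as constants and can be refit from any cohort with
`diagnostics.fit_logistic`.  Whether the original fit's intercept was
absorbed into the 3.26 cutoff is unknowable from the published summary;
the weights are treated as given.

On the D-dimer unit label: the source tables print µg/dL while the
surrounding discussion prints ng/mL for the same numeric value (1345).
The package treats the numeric scale as one and the same and provides a
`d_dimer_ng_ml` ingestion flag that accepts the alternative label without
rescaling; no other unit auto-conversion is attempted.

## Evaluation statistics

* Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
  NPV TN/(TN+FN); Youden J = se + sp − 1, stored in [−1, 1] and displayed
  ×100.  A zero denominator flags the metric *undefined* rather than
  propagating NaN.
* Odds ratios use the Woolf log-normal interval.  With a zero cell the OR
  is undefined under plain Woolf (an error); `woolf-haldane` adds 0.5 to
  every cell iff any cell is zero.  The per-table p-value is Fisher's
  exact when any expected cell is below 5, else Pearson chi-square (the
  sparse-table convention of mainstream clinical software).
* The 2×2 chi-square applies the Yates continuity correction by default
  when any expected count is below 5 (`correction="auto"`), matching the
  convention of the SPSS-style software this field reports with; both
  forced and disabled correction are available.  Yates can only raise the
  p-value, which is property-tested.
* The t-test is pooled-variance by default (as clinical tables assume),
  with Welch available by flag; the choice matters for heavily unbalanced
  groups (e.g. 304 vs 21).
* ROC/AUC: the AUC is the Mann–Whitney normalisation (ties count ½),
  verified against a brute-force concordant-pair oracle.  Thresholds are
  midpoints between consecutive distinct observed values plus ±∞
  sentinels; the Youden-optimal cutoff breaks ties toward the higher
  threshold (higher specificity — conservative for screening).
* Logistic regression is Newton/IRLS maximum likelihood (via statsmodels)
  with SEs from the observed information; Wald = (B/SE)², OR = exp(B).
  Perfect separation or non-convergence raises a diagnostic error.  For a
  single binary covariate the fitted OR equals the 2×2 cross-product ratio,
  which is used as a numerical cross-check.
* No multiple-testing adjustment is applied anywhere, deliberately
  mirroring standard practice in the source analyses; interpret the
  univariate p-values accordingly.

## Survival

Kaplan–Meier product-limit estimation with deaths processed before
censorings at tied times (the standard convention); fixed-horizon rates by
right-continuous step evaluation, carrying the last value forward (with a
warning) beyond follow-up; two-group log-rank with a χ²₁ p-value.  With no
censoring the estimator reduces to the empirical survivor function, which
is the oracle used in tests.

## The synthetic-cohort generator

The generator emulates the *marginal and group-conditional* structure of a
newly diagnosed NHL registry; it is the package's stand-in for
patient-level data that were never deposited.

* VTE outcomes: Bernoulli at prevalence 21/325 ≈ 6.46% (retrospective
  default) or 9.2% (validation preset, n = 98).
* Binary factors: Bernoulli conditional on VTE status at the published
  group prevalences (e.g. infection 13.8% | 33.3%, prior VTE 1.3% | 28.6%).
  Reduced mobility and extranodal localization are not tabulated in the
  source; they default to plausible registry rates (6%/15% and 30%/40%)
  and are flagged as such.  ECOG and Ann Arbor stage are refined from
  their dichotomized prevalences into full categories with fixed splits.
* Labs: drawn per group at the published means/SDs.  Well-behaved analytes
  use a zero-truncated normal whose *parent* parameters are solved so the
  truncated distribution has exactly the target moments (naïve truncation
  inflates the mean of any analyte whose SD approaches its mean — for WBC
  the bias would be ≈ +0.6×10⁹/L).  Heavy-tailed analytes (D-dimer, FDP,
  LDH; SD of the order of the mean) use a lognormal with matched arithmetic
  moments, since a truncated normal cannot even attain a CV above ~1; a
  `normal-truncated` switch exists for sensitivity analysis and knowingly
  accepts the distortion.  Labs are mutually independent (only marginals
  are published); BMI moments are back-solved from the dichotomized
  BMI ≥ 25 rates.
* Biomarkers: TM/TAT baselines (7±2, 4±2) with additive VTE shifts (+6,
  +8) sized so the composite cutoff 3.26 sits between the group means;
  **arbitrary units, not derived from any published axis**.  PIC and
  t-PAIC get no shift (they were not retained in the cascade).
* Survival: exponential death times, baseline hazard 0.014/month with a
  VTE hazard ratio of 2.9 (chosen to land near the published 1-/2-year
  rates of 61.9%/38.1% vs 87.4%/66.8%); administrative censoring uniform
  on [6, 47] months (median 26.5) plus a 24/325 early loss-to-follow-up
  fraction.  VTE onset times follow the published timing mix (28.6%
  pre-chemotherapy, 38.1% ≤ 3 months, 19.0% 3–6, 14.3% > 6).
* Reproducibility: one RNG substream per variable block, keyed by the root
  seed and the block name, so adding a field never perturbs existing
  draws; the same seed is bit-identical.

**What passing tests on synthetic data do and do not show.**  They show
the pipeline computes its statistics correctly under the stated generative
model, that the generator is calibrated to the published group-conditional
summaries, and that large-cohort OR estimates recover the published
univariate effects.  They do *not* validate patient-level quantities the
published summaries cannot determine — individual-level AUCs, multivariate
OR magnitudes (which depend on the unpublished covariate correlation
structure), or the exact survival curves.  Those are covered by
property-based substitutes (parameter recovery, pair-counting oracles,
algebraic identities) rather than by numeric reproduction.

## Problem sizes used in checks

Deterministic reproduction of the published metric sets runs on the
embedded counts (n = 325 and n = 98) in milliseconds.  Stochastic checks
use cohorts of 5 000 (OR coverage across 200 seeds, logistic recovery) and
50 000 (parameter recovery at ±0.01), sizes at which binomial and CLT error
bounds make the assertions sharp while the suite stays fast.

## Known limitations

* Scoring-table defaults encode the original Khorana/ThroLy publications;
  site-specific variants of either score must be supplied as JSON.
* The generator draws labs independently; real hematology panels are
  correlated, so joint statistics across labs (e.g. multivariate ORs)
  should not be read off synthetic cohorts.
* No Cox regression, no Firth small-sample logistic, no DeLong AUC
  comparison; AUCs are compared descriptively only.
* Lymphoma subtype is free text; no subtype-specific biology is simulated.
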