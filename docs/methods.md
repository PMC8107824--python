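# Methods

This note documents the models, designs and numerical conventions behind
`clinaudit`: what each component assumes, which knobs matter, and what the
synthetic validation does and does not demonstrate about real data.

## The synthetic cohort generator

The study the package emulates is described, not deposited, so the
generator is this package's own model of the described population.  It is
quota-exact where the description gives counts and distributional where it
gives mechanisms:

* **Composition quotas** (exact): 171 male / 132 female; disease subgroups
  AR 26, asthma 48, asthma+AR 54, COPD 36, COPD+AR 11, healthy 87, other
  41 (sum 303); smokers per gender at round-half-up of the configured
  rates (default 55% of males → 94, 0% of females); low-SES share of the
  cohort (default 0.5 → 152 of 303).
* **Smoking–SES reconciliation**: smoking is pinned to the gender quotas
  first; SES is then assigned so that smokers land in the low-SES group in
  proportion to the configured SES smoking rates (defaults 0.5 low / 0.1
  high).  The gender quota is authoritative because the source description
  gives it numerically while the SES rates are only qualitative
  ("predominantly non-smokers" / "roughly evenly divided").  The SES counts
  themselves are not documented at all; the 50/50 split is a default, not a
  fact.
* **Disease assignment**: the COPD-bearing categories are filled by
  weighted sampling without replacement (Gumbel top-k) with per-record
  log-odds increment `smoking_copd_weight × smoking`; all other categories
  partition the remaining records uniformly.  The default weight of 3.0
  makes COPD assignment smoking-dominated, reflecting the described
  population in which smoking is the dominant COPD risk factor and the
  fitted smoking coefficient is large.  Because category quotas are fixed,
  the weight changes *who* gets COPD, not how many.
* **Symptoms**: ten binary questionnaire items drawn per record from
  disease-conditional Bernoulli emissions (documented in
  `src/clinaudit/data/default_cohort.yaml`).  Obstructive symptoms load on
  asthma/COPD, upper-airway symptoms on AR, comorbid categories carry
  both, healthy controls have low background rates.  Values were chosen
  once so that baseline models are learnable but imperfect.
* **Peak flow**: a Gaussian fraction-of-predicted-normal per disease
  category, clipped at zero and discretized at the (0.8, 0.5) cuts into
  high/medium/low; the ordered level enters models as two dummies
  (medium, low) against the high reference.
* **Randomness**: one seed, split into labeled child streams (smoking,
  SES, disease, peak flow, one per symptom) via `SeedSequence.spawn`, so
  adding a feature never perturbs earlier draws and identical seeds give
  byte-identical cohorts.

`gender_exchangeable_config()` equalizes the smoking rates across genders
(0.31 each, preserving the total smoker count); since every other
mechanism conditions only on disease, gender becomes exchangeable — the
null condition for audit false-alarm checks.  `inject_group_noise` flips a
configurable fraction of one group's questionnaire bits, planting a known
systematic bias for power checks.  Note its scope: it corrupts the
questionnaire panel only, so it degrades models whose signal lives there
(asthma, AR) far more than the COPD model, which leans on the untouched
smoking and peak-flow columns.

**What passing tests show — and don't.**  The generator reproduces the
documented marginals and confounds, but its conditional independence
structure (symptoms independent given disease) is far simpler than real
clinical data, its feature panel is invented, and no attempt is made to
match the study's real-data AUC values (those data are unavailable;
matching them would be fabrication).  Notably, the synthetic COPD gender
gap comes out with the *female* groups scoring lower — female COPD cases
lack the dominant smoking marker — whereas the study reports higher
accuracy for women; the audits are validated on their ability to detect a
planted or structural gap, not on reproducing its direction or size.

## Disease models and training protocol

One-vs-rest L2-regularized logistic regression per disease (COPD, asthma,
AR), chosen for interpretability: the coefficient report ranks features by
|β| (name-sorted ties) and is part of every audit report.

* Positives: records whose label set is exactly the target disease
  (comorbid records excluded, so the positive label is unambiguous).
* Negatives: healthy controls by default; the `rest` policy (everyone
  lacking the disease, including "other" and comorbid-with-other records)
  is available and the active policy is echoed in every report.
* Split: stratified 80/20, jointly on label × gender where every cell has
  at least two members, label-only otherwise; seeded.
* Tuning: `C ∈ {10⁻³ … 10³}` (7 log-spaced points) by cross-validated
  AUC, then minority-class weight `∈ {1,2,3,5,8,13}` by cross-validated F1
  at threshold 0.5 (MCC selectable), both with stratified k=5 folds.  Ties
  break toward the smallest C and smallest weight — simpler models win.
  Grids, per-point scores, selections, seed and held-out AUC are recorded
  in `tuning_log`.
* Fits run scikit-learn's lbfgs solver to tight tolerance (1e-10 for final
  fits), making them deterministic and reproducible against an independent
  penalized-likelihood optimizer to ~1e-4 in predicted probability.

**Prevalence recalibration.**  For deployment prevalence π and training
prevalence π̂, the intercept becomes
`β₀* = β₀ + log(π/(1−π)) − log(π̂/(1−π̂))` with slopes untouched.  The
adjusted model stores the as-fitted intercept as an anchor, so chained
adjustments compose bit-exactly and adjusting back to π̂ is the exact
identity.  This prior-shift correction is exact when the class-conditional
feature distributions match between training and deployment; the test
suite verifies on a well-specified population (class-conditional
independent binary features) that the mean predicted probability tracks
the deployment prevalence to within 0.02 at n=20,000.

## Bias audits

Both audits run on the **whole cohort with membership labels** (a record
is positive for a disease if that disease appears in its label set;
comorbid records positive, "other" negative).  This is what makes the
documented partition sizes attainable — a balanced gender test set of
80+80 with a 104-record training draw from the 143-record remainder does
not fit inside any single-disease subset.  The one-vs-rest exact-label
policy remains the training-leg convention; the label policy is a
parameter of both audits.

Hyperparameters (C, class weight) are tuned once per audit — on the pool
for sampling audits, on the full cohort for systematic audits — and held
fixed across iterations: the audits study training-set *membership* at
constant model capacity, and re-running the two-stage grid search inside
every iteration would multiply cost ~65× without changing what the
resampling measures.

* **Systematic bias**: per iteration, one equal-size homogeneous test
  group per attribute level is drawn uniformly at random (default size
  `floor(0.5 × min group size)`; a draw missing a class is redrawn
  deterministically), the model is retrained on a random 80% of the
  remaining records — random training membership is the variance the IQR
  yardstick measures — and per-group AUC is recorded.  Summaries: median,
  quartiles, IQR per group, a pooled per-group ROC over all iterations,
  and an IQR-overlap flag.
* **Sampling bias**: the balanced test set (per-group quota, without
  replacement) is drawn once; for each training proportion × iteration a
  composition-exact training set (round-half-up on the first level's
  quota) is drawn from the disjoint pool, and AUC is scored on the whole
  test set and on each group separately.  Defaults mirror the documented
  designs: gender — train 104, test 80+80, proportion of males
  50/62.5/75/87.5%; SES — train 140, test 29+29, proportion of low-SES
  swept down 50/37.5/25/12.5% (the descending form is the one whose
  rounded quotas are feasible against the default SES split).  1000
  iterations by default.
* **Seeding**: iteration i of proportion-index p uses
  `SeedSequence([master, p, i])`, so any single cell reproduces
  independently.  Test/train disjointness is asserted inside the loops.

No hypothesis test is attached to the summaries: the audits report
medians, IQRs and overlap flags, deliberately nothing more inferential.

**Limitation — what the IQR yardstick can and cannot absorb.**  The IQR
captures resampling variance within one realized cohort.  A finite cohort
(n=303) also carries realization-level between-group AUC differences of
the same order (a few hundredths of AUC at ~50 positives per group), and
the audit — correctly, from its standpoint — flags those as performance
gaps even when the generating process is exchangeable.  Consequently the
overlap flag's false-alarm rate over *regenerated* exchangeable cohorts is
materially above zero at this cohort size, while its power against a
planted questionnaire corruption (flip rate 0.4) is essentially complete
for questionnaire-driven models.  Interpret a single non-overlap on a
small cohort as "this dataset shows a gap worth investigating", not as
proof of a biased data-generating process.

## Fairness

Three group criteria at an operating point: demographic parity
(independence, equal positive rates), equality of opportunity (separation
on positives, equal TPR), equality of odds (equal TPR and FPR — a common
point of the per-group ROC curves).  With unequal base rates and an
informative classifier the three cannot all hold: positive rate is the
prevalence-weighted mixture of TPR and FPR, so enforcing equalized odds
leaves a parity gap of |Δprevalence| × |TPR − FPR|.  The report therefore
always shows all three gaps at the chosen point.

* Default mode is a **shared threshold** (one deployed model, one
  threshold): the equalized-odds point minimizes max(TPR gap, FPR gap)
  over the union of observed thresholds, ties resolved toward higher TPR
  then lower FPR, with candidates where both groups sit at a trivial
  anchor ((0,0) or (1,1)) excluded — those zero every gap vacuously.
* **Per-group thresholds** are available: the geometric intersection of
  the piecewise-linear per-group ROC curves (anchors excluded; of several
  interior intersections the highest-TPR one is returned, all are
  reported; with no interior intersection the closest-approach point is
  returned with a warning flag).
* The satisfied flag uses an absolute gap tolerance, default 0.02 — the
  source material never quantifies acceptable residual unfairness, so the
  default is a reporting convention, not a norm.
* Fairness in the workflow is assessed on k-fold out-of-fold predicted
  probabilities over the training subset (more stable than the 20%
  held-out split alone); the fold structure is seeded and recorded.

## Numerical conventions

* Prediction rule: score ≥ λ is positive (boundary inclusive).
* ROC: empirical step curve over all distinct score thresholds, anchored
  at (0,0) and (1,1); ties collapse to one threshold.  Trapezoidal AUC
  equals the rank-pair statistic P(score⁺ > score⁻) with half credit for
  ties (verified exhaustively against a brute-force oracle).
* Quartiles: linear interpolation between order statistics (type 7);
  IQR = Q3 − Q1.  Chosen because it is the numpy default and the spread is
  only ever used comparatively.
* F1 = 2TP/(2TP+FP+FN), defined as 0 on a zero denominator; MCC returns 0
  when any confusion marginal is empty — audit loops never crash on
  degenerate resamples.
* Quota rounding is round-half-up on the first-listed level; the other
  level takes the remainder.  This is what makes the documented
  composition sweeps reproduce exactly.
* Reports are JSON with sorted keys plus a markdown rendering whose every
  number traces to a JSON field; a fixed configuration yields
  byte-identical reports.

## Validation problem sizes

The acceptance suite runs the audits at the sizes the documented designs
prescribe where that is cheap (composition and partition fixtures, exact
metric equivalences at 500 random instances, recalibration at n=20,000)
and at reduced iteration counts where the full 1000-iteration protocol
would add nothing but runtime to a distributional check: audit power and
false-alarm at B=200 over 20 regenerated cohorts, sweep flatness at
B=100, and the end-to-end workflow at B=50 with a byte-identity rerun.
These are the package's chosen validation scales; the library defaults
remain at the documented B=1000.
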