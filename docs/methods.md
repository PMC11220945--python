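# Methods

## The scoring model

The package operationalises a rule-based reading of early diffusion MRI
after cardiac arrest. Cytotoxic oedema from hypoxic-ischemic injury lowers
the apparent diffusion coefficient (ADC); an ROI is *restricted* when its
summary statistic is **strictly below 650 × 10⁻⁶ mm²/s** (a value of
exactly 650 is not restricted). Restriction is read in 17 fixed ROIs
spanning six region classes, and the MR lesion pattern (MLP) follows a
strict precedence over the restricted classes:

1. any thalamic, hippocampal or brainstem restriction → **MLP 4**
2. else any basal-ganglia restriction → **MLP 3**
3. else any cortical restriction (cerebral or cerebellar cortex) → **MLP 2**
4. else → **MLP 1**

The score therefore depends only on *which region classes* contain at
least one restricted ROI — never on how many ROIs are involved, nor on the
ADC magnitudes below threshold. This makes the rule monotone under set
inclusion of the restricted set, a property the test suite checks both by
brute-force enumeration of all 2¹⁷ ROI subsets against an independently
coded severity-rank evaluator and on random subset pairs.

Modelling choices where the scheme as described leaves room:

* **ROI summary statistic** — the source scheme says only that ADC values
  are "measured" in each ROI. The default is the ROI **mean**, the
  conventional read-out for small homogeneous ROIs; the median is
  available (`roi_statistic="median"`).
* **Cerebellar cortex** counts as cortical grey matter for MLP 2: it is a
  measured cortical region and not subcortical. Cerebellar-only
  restriction thus scores MLP 2.
* **One ROI suffices** to mark its class involved; no bilaterality or
  minimum lesion count is required (the rule text requires only
  "presence").
* **Chronic lesions / T2 shine-through** are not detected by the package;
  they enter as a caller-supplied per-ROI `excluded` flag which vetoes
  restriction regardless of ADC.

## Outcome model and cohort flow

Neurological outcome is the cerebral performance category (CPC, 1 good
recovery … 5 brain death) assessed at day 30 and day 180. The analysis
uses the **best** (numerically lowest) of the available assessments, so a
patient who recovers and later dies of an unrelated cause keeps the
recovered grade; one missing assessment is tolerated, both missing is an
error (silent dropping would hide data problems). CPC 1–2 is favourable
(FO), 3–5 unfavourable (UO).

The consort filter reduces an admission cohort in three ordered stages —
admission-stage exclusions with a recorded reason (regained consciousness
within 24 h, circulatory-failure death, brain death, no consent, advanced
directives), pre-MRI dropouts (regained consciousness before MRI, or
prognosticated without MRI), and other intracranial pathology found on
MRI. Each record is counted under exactly one reason, in that order, and
counts are conserved at every stage.

## Diagnostic evaluation

Severe MLP (3–4) is the positive test, UO the condition. From the 2×2
table: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV, accuracy
in percent, LR⁺ = sens/(1−spec), LR⁻ = (1−sens)/spec.

* **Proportion intervals** default to the Clopper–Pearson exact interval
  (beta-quantile inversion of the binomial tail tests, via statsmodels),
  with closed boundaries at 0 and 1; the Wilson score interval is
  available. The exact method is conservative: simulated coverage at
  n = 12, p = 0.83 runs well above the nominal 95 %.
* **Likelihood-ratio intervals** use the log-normal method
  exp(ln LR ± z·SE) with the standard (Simel) errors
  SE⁺ = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) and
  SE⁻ = √(1/FN − 1/(TP+FN) + 1/TN − 1/(FP+TN)). A zero cell in the SE
  makes the interval undefined (reported as NaN, never silently 0); a
  specificity of 1 makes LR⁺ infinite and is flagged as such.
* **Two rounding conventions for the LRs.** `raw` (default) forms the
  ratios from exact fractions; `as_published` first rounds sensitivity
  and specificity half-up to two decimals and then forms the ratios —
  the convention under which a 33/2/2/10 table yields LR⁺ 5.53 rather
  than the raw 5.66. Display rounding elsewhere is decimal half-up.
* **Two false-rate conventions** are computed and labelled explicitly:
  `fpr_paper` = FP/(TP+FP) = 1−PPV (the share of severe-pattern calls
  with a favourable outcome — the clinically feared misclassification)
  and `fpr_standard` = FP/(FP+TN) = 1−specificity; analogously for the
  false-negative rate.

## Synthetic data

The generators define the conditions under which the pipeline is
exercised; they are deliberately simple and their limits are stated here.

* **Toy atlas** — a 60×72×30 mm bounding volume (1 mm isotropic by
  default) in which each ROI is a single-slice rectangular patch of
  exactly the nominal in-plane area: 4 mm² → 2×2 voxels, 10 mm² → 2×5
  (no integer square exists for 10). Single-slice patches mirror how
  clinical ROIs are drawn on one slice; areas are given in mm², not
  volumes. Left/right pairs are mirrored exactly about the mid-sagittal
  plane; the seed jitters patch positions by ≤1 voxel (shared within a
  pair). Voxel geometries whose in-plane area does not divide both 4 and
  10 mm² are rejected rather than approximated.
* **ADC volumes** — Gaussian fields: normal grey matter
  N(800, 25²) × 10⁻⁶ mm²/s, lesions N(450, 25²). These are plausible
  normal-tissue and cytotoxic-oedema levels chosen to straddle the 650
  threshold by 8 SD on either side, not empirical claims; both are
  config-exposed. With ≥4 voxels per ROI the per-ROI misclassification
  probability is Φ(−(650−450)/(25/√4)) ≈ 10⁻⁵⁷, so the 400-subject
  recovery experiment must score every subject with its intended
  pattern; any miss indicates a bug, not noise. Not modelled: Rician
  noise, partial-volume effects, b-value dependence, registration error,
  reader variability — so passing recovery tests demonstrates the logic,
  not robustness on real scans.
* **Cohorts** — `exact_counts` mode emits a prescribed outcome × MLP
  joint table cell by cell (default: the 47-patient validation
  distribution); `multinomial` mode draws n patients from the normalised
  cell probabilities. CPC values are sampled uniformly within the
  outcome class, and the day-30/day-180 pair is constructed so its
  minimum equals the intended best CPC. The consort fixture prepends the
  85 admission-stage exclusions (44/19/11/7/4 by reason), 3 pre-MRI
  awakenings, 1 patient prognosticated without MRI and 1 other-pathology
  exclusion, giving the full 137-record flow.
* **Seeding** — one global integer seed; every stochastic operation
  draws from a named sub-stream (SeedSequence spawned from the seed and
  a CRC of the operation name), so runs are reproducible end to end and
  operations are order-independent.

## Numerical and interface choices

* Strict `<` at the restriction threshold; threshold monotonicity
  (raising the threshold never lowers an MLP) is property-tested.
* Undefined metrics (zero denominators) are NaN in memory and `null` in
  JSON, with the convention block recording which definitions were used.
* Atlas, volumes: NIfTI (nibabel) with a CSV ROI sidecar
  (`roi_id,region_class,hemisphere,label_value,area_mm2`); cohorts: RFC
  4180 CSV with a fixed header; reports: JSON with a provenance block
  (config echo, package version).
* The evaluation CLI is `simulate` / `score` / `evaluate`; `evaluate`
  subsumes report writing.

## Problem sizes

The bundled experiments use the study's own scale: the 137/52/48/47
consort flow, the 47-patient validation table, 400 simulated subjects
(100 per pattern) for recovery, 10 000 replicates for interval coverage,
and exhaustive enumeration for the 2¹⁷ pattern-rule check and the ≤6-cell
metric oracle. All run in seconds on one CPU.

## Known limitations

* The toy atlas is a geometric phantom; nothing about registration,
  segmentation or anatomical realism is tested.
* The printed proportion intervals of the source table are not
  reproducible by any single standard method (its PPV interval does not
  even bracket its point estimate), so only the likelihood-ratio
  intervals are treated as reproducible surfaces; proportion intervals
  default to Clopper–Pearson as the defensible exact choice.
* Multimodal prognostication (EEG, NSE, SSEP, clinical exam) is carried
  only as pass-through exclusion flags; no fusion logic is modelled.
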