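# mlpscore

Rule-based MRI lesion-pattern (MLP) scoring for neuroprognostication after
cardiac arrest, with a fully synthetic test bed.

After out-of-hospital cardiac arrest, diffusion-weighted MRI is read for
cytotoxic oedema: grey-matter regions whose apparent diffusion coefficient
(ADC) falls below **650 × 10⁻⁶ mm²/s** are called *restricted*. ADC is
measured in 17 pre-defined regions of interest — eight cerebral cortical
(frontal, parietal, temporal, occipital × left/right, 4 mm² each), two
cerebellar cortical (4 mm²), two hippocampal (4 mm²), two basal-ganglia
(10 mm²), two thalamic (10 mm²) and one midline brainstem ROI (10 mm²).
The topography of the restricted ROIs maps to a four-level score:

| MLP | Definition |
|-----|------------|
| 1 | no grey-matter lesion |
| 2 | purely cortical lesions (cerebral or cerebellar cortex) |
| 3 | basal-ganglia lesions without other deep grey matter (± cortex) |
| 4 | thalamic, hippocampal or brainstem lesions (± anything else) |

MLP 3–4 ("severe hypoxic brain injury") is evaluated as a binary predictor
of unfavourable outcome — best cerebral performance category (CPC) 3–5
over the day-30 and day-180 assessments — via a 2×2 table with
sensitivity, specificity, predictive values, likelihood ratios
(LR⁺ = sens/(1−spec), LR⁻ = (1−sens)/spec), accuracy, Clopper–Pearson
exact intervals for proportions and log-normal (Simel) intervals for the
likelihood ratios.

The package is aimed at people studying or re-implementing imaging-based
neuroprognostication pipelines: it contains the scoring and evaluation
logic as a library plus a CLI, and synthetic generators (a toy label
atlas, ADC volumes with known lesion topography, and cohorts with a
prescribed MLP × outcome joint distribution) so the whole pipeline runs
and is testable without any patient data.

## Worked example

```python
>>> import mlpscore as m
>>> atlas = m.build_toy_atlas(seed=0)                      # 60×72×30 voxels, 17 ROIs
>>> vol, truth = m.simulate_adc_volume(
...     atlas, m.LesionSpec(target_rois={"thalamus_L"}), seed=1)
>>> meas = m.call_restriction(m.extract_roi_values(vol, atlas))
>>> m.assign_mlp(meas, atlas.roi_table)
MlpScore(value=4, severe=True)                             # thalamic lesion → MLP 4

>>> cohort = m.consort_fixture(seed=3)                     # 137 admitted patients
>>> validation, flow = m.consort_filter(cohort)
>>> flow["admitted"], [s["remaining"] for s in flow["stages"]]
(137, [52, 48, 47])                                        # consort flow
>>> table, by_cell = m.crosstab(validation)
>>> table
ContingencyTable2x2(tp=33, fp=2, fn=2, tn=10)
>>> r = m.diagnostic_metrics(table, rounding_mode="as_published")
>>> print(f"sens {r.sensitivity:.2f}  spec {r.specificity:.2f}  "
...       f"acc {r.accuracy_pct:.2f}%  LR+ {r.lr_pos:.2f}  LR- {r.lr_neg:.2f}")
sens 0.94  spec 0.83  acc 91.49%  LR+ 5.53  LR- 0.07
>>> tuple(round(x, 2) for x in r.ci["lr_neg"])
(0.02, 0.27)
```

Reading: of 47 evaluable patients, 35 had a severe pattern, 33 of whom had
an unfavourable outcome; a severe pattern multiplies the odds of
unfavourable outcome by ~5.5, and its absence divides them by ~14
(LR⁻ 0.07), with an overall accuracy of 91.49 %.

The same pipeline runs from the shell:

```bash
mlpscore simulate --mode consort-fixture --seed 1 --out run/
mlpscore evaluate --cohort run/cohort.csv --as-published --out run/report/
mlpscore simulate --mode volumes --per-pattern 2 --seed 1 --out run/
mlpscore score --atlas run/atlas.nii.gz --volumes run/ --out run/scored/
```

`evaluate` writes `metrics.json` (point estimates, intervals, conventions
and a provenance block), `flow.json` (per-stage consort counts) and CSV
mirrors of the contingency tables.

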