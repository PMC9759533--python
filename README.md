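# relaxroi

ROI-based first-order analysis of quantitative MRI relaxometry maps
(T1/T2/PD) in treated gliomas.

Fast multiparametric sequences deliver voxel-wise quantitative T1 and T2
relaxation times (ms) and proton density (%) of the whole brain in minutes,
raising a clinically important question: can **pre-contrast** quantitative
values distinguish abnormal from normal tissue, and predict which lesions
will enhance after gadolinium injection — potentially sparing patients the
contrast agent? `relaxroi` implements the analysis pipeline for that
question, for imaging scientists working with coregistered quantitative maps
and lesion segmentations in NIfTI format.

## What it computes

Given per-patient maps and masks (T2-hyperintensity `T2h`, contrast
enhancement `T1e`, white matter `WM`), the pipeline:

1. **derives regions**: the combined abnormal tissue `ABN = T2h ∪ T1e`, a
   1-cm perilesional shell `PER` (Euclidean distance transform in world
   units, so anisotropic voxels are handled correctly) and normal-appearing
   white matter `nWM = WM ∖ (ABN ∪ PER)`;
2. **characterizes each region** by the first-order statistics of each map:
   mean, SD, Fisher skewness g₁ = m₃/m₂^{3/2} and Pearson kurtosis m₄/m₂²
   (normal → 3), with across-patient means and t-based 95% CIs;
3. **compares regions and patient groups** with the Wilcoxon signed-rank
   test — exact two-sided p-values from the full 2ⁿ sign-flip null for
   n ≤ 20, with average ranks for ties;
4. **classifies voxels** with composite metrics — T1, T2,
   normT1T2 = √(T1² + T2²) and normlog = √(ln²T1 + ln²T2), plus variants
   appending PD — via pooled ROC curves for three questions (ABN vs nWM,
   T1e vs the rest, T1e vs T2h), picking the operating threshold that
   maximizes the Youden index J = sensitivity + specificity − 1, and
   re-applying it to produce `ABN*`/`T1e*` masks scored by
   sensitivity/specificity/accuracy;
5. **predicts enhancement per patient** from the 16 pre-contrast features
   (4 metrics × 4 statistics inside ABN) with leave-pair-out
   cross-validation: every (enhancing, non-enhancing) pair is held out once,
   the training ROC's Youden threshold classifies the pair, and per-feature
   mean AUC, pooled rates and per-patient occurrence counts are reported.

Because such patient cohorts are rarely shareable, the package includes a
**synthetic cohort generator**: 7 + 7 patients with ellipsoidal white
matter, lesion and enhancing core, region values drawn from shifted
lognormals whose mean, SD and skewness match published per-region T1/T2
tables from a 14-patient treated-glioma cohort, with mild per-patient
heterogeneity. The whole pipeline is exercised end-to-end on it.

## Worked example

```python
from relaxroi import CohortConfig, generate_cohort, run_question, compute_roi_stats

cohort = generate_cohort(CohortConfig(seed=0))
print(f"patients: {len(cohort)}, enhancing: {sum(r.has_enhancement for r in cohort)}")

rec = cohort[0]
st = compute_roi_stats(rec.maps.t1, rec.rois.by_name("t2h"))
print(f"{rec.patient_id} lesion T1: mean={st.mean:.1f} ms, sd={st.sd:.1f} ms, "
      f"skewness={st.skewness:.2f}, kurtosis={st.kurtosis:.2f} ({st.n_voxels} voxels)")

roc = run_question(cohort, "abn_vs_nwm", "normlog")
print(f"lesion vs normal WM, normlog: AUC={roc.auc:.3f}, "
      f"Youden threshold={roc.youden_threshold:.2f} "
      f"(sens {100*roc.youden_sensitivity:.1f}%, spec {100*roc.youden_specificity:.1f}%)")
```

prints

```
patients: 14, enhancing: 7
patient-01 lesion T1: mean=1274.9 ms, sd=274.8 ms, skewness=1.24, kurtosis=6.15 (937 voxels)
lesion vs normal WM, normlog: AUC=0.918, Youden threshold=8.38 (sens 92.1%, spec 78.8%)
```

The lesion's T1 is elevated and right-skewed relative to normal white matter
(≈ 993 ms), and the log-domain composite metric separates pooled lesion from
normal white-matter voxels with AUC 0.92 at a threshold of 8.38 — on the same
scale as the ≈ 8.25 (normal WM) to ≈ 8.79 (lesion) normlog magnitudes implied
by the published per-region means.

## Command line

```bash
relaxroi simulate --out cohort/ --seed 0          # write NIfTI cohort + manifest
relaxroi analyze  --manifest cohort/manifest.yaml --out report/
relaxroi analyze  --out report/ --seed 0          # synthetic cohort in-memory
```

`analyze` emits per-patient and cohort statistics tables, region-comparison
p-values, ROC curves per question × metric, thresholded `ABN*`/`T1e*` masks
with agreement scores, the cross-validation grid and occurrence table, and a
machine-readable `summary.json`. Fixed published thresholds can be imposed
with `--abn-threshold 8.44 --t1e-threshold 1344`.

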