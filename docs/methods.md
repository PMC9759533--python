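# Methods

## Problem setting

Quantitative relaxometry assigns each brain voxel physical tissue parameters
— longitudinal relaxation time T1 (ms), transverse relaxation time T2 (ms)
and proton density PD (%) — instead of arbitrary scanner units. In treated
diffuse gliomas, edema, residual tumor and treatment effects all prolong T1
and T2, and tissue whose blood–brain barrier leaks (visible as post-contrast
T1w enhancement) tends to show the strongest prolongation already before
contrast. The pipeline quantifies how well pre-contrast values separate
(a) abnormal from normal tissue at the voxel level and (b) enhancing from
non-enhancing patients at the subject level.

## Regions of interest

Inputs per patient are three coregistered maps and three binary masks
(T2-hyperintensity `t2h`, enhancement `t1e`, white matter `wm`). Derived
regions:

* `abn = t2h ∪ t1e` — combined abnormal tissue;
* `per` — every voxel whose center lies within 10 mm (closed ball, world
  units) of an `abn` voxel center, minus `abn`. Implemented with a Euclidean
  distance transform sampled at the voxel edge lengths, so a 0.875 × 0.875 ×
  5 mm grid produces a geometrically correct 1-cm shell (±2 slices through
  the thick axis). The shell is deliberately kept as a separate region: it
  may harbor infiltrating tumor under a normal appearance, so it is excluded
  from both the normal and abnormal classes in ROC analysis.
* `nwm = wm ∖ (abn ∪ per)` — normal-appearing white matter.

Masks are binarized at > 0.5 (tolerant of interpolation residue); affines
must agree within 1e-4 per entry; maps are processed as float64. The shell
is not clipped to the brain by default; `derive_rois(..., brain_mask=...)`
can intersect it.

## First-order statistics

Within a region, values are summarized by the arithmetic mean, the sample SD
(n − 1), Fisher skewness g₁ = m₃/m₂^{3/2} and Pearson (non-excess) kurtosis
m₄/m₂², central moments with n denominators and no small-sample bias
correction. The kurtosis convention matters only as a constant offset of 3;
Pearson was fixed because reported lesion values (≈ 4–16) are discussed
against the normal-distribution reference of 3. Regions with fewer than 3
voxels or zero variance return NaN skewness/kurtosis and are flagged rather
than dropped. Across patients, each cell of the summary table carries the
mean and a Student-t 95% half-width t₀.₉₇₅,ₙ₋₁·s/√n — a t interval because
cohorts of 7–14 patients are too small for a normal interval to be honest.

## Hypothesis tests

Region-vs-region contrasts pair the per-patient statistic values and apply
the two-sided Wilcoxon signed-rank test: zero differences dropped, average
ranks for ties, and for n ≤ 20 an exact p-value from the distribution of the
positive-rank sum W over all 2ⁿ sign assignments (computed by dynamic
programming over the doubled ranks, which is exactly that enumeration).
Above n = 20 a tie-corrected normal approximation without continuity
correction is used. Note the signed-rank p is invariant under increasing
affine transforms of both pair members but not under general monotone maps,
since those reorder the absolute differences.

Enhancing vs non-enhancing patient groups are independent samples; the
design nevertheless calls for a signed-rank test, so with equal group sizes
patients are paired by index order within group, and a Mann-Whitney rank-sum
p-value is always computed alongside as the statistically conventional
cross-check (and as the fallback for unequal sizes).

## Voxel-wise classification

Composite metrics: T1, T2, normT1T2 = √(T1² + T2²), normlog =
√(ln²T1 + ln²T2) (natural logarithm — at white-matter magnitudes this puts
the metric near 8.2 and lesion tissue near 8.8, bracketing published
operating thresholds, whereas log₁₀ would sit near 4), and variants with PD
(or ln PD) appended. Units are mixed inside the norms by design; the metric
is a monotone score, not a physical quantity. Non-positive inputs to a
logarithm yield NaN voxels, which are counted, excluded from ROC pooling and
never classified positive.

ROC curves pool voxels across patients (one cohort-level curve per question;
per-patient weighting is a non-default option). Candidate thresholds are
midpoints between consecutive distinct pooled values plus ∓∞ sentinels, and
the decision rule is strictly `value > threshold`. Midpoints make the strict
rule unambiguous and ordering-independent. AUC is the trapezoidal area,
which for this construction equals the tie-corrected concordance
P(pos > neg) + ½P(pos = neg) (verified against brute force and an external
implementation in the tests). The operating point maximizes the Youden index
J; ties break toward the lower threshold. Three questions are built in:
`abn_vs_nwm`, `t1e_vs_rest` (negatives default to t2h + per + nwm and are
configurable, since either composition of "the rest" is defensible) and
`t1e_vs_t2h`. Learned (or fixed, user-supplied) thresholds are re-applied
per patient inside the union nwm ∪ per ∪ abn, and the resulting `ABN*`/`T1e*`
masks are scored in percent: sensitivity over the true region, specificity
and accuracy over the evaluation mask.

## Patient-level prediction

Each patient contributes 16 features: the four statistics of the four
non-PD metrics inside `abn`. Leave-pair-out cross-validation enumerates all
n₊ × n₋ (enhancing, non-enhancing) pairs — 49 folds for 7 + 7, each patient
held out exactly the opposite group's size times. Per fold, an ROC on the
remaining patients' feature values supplies a Youden threshold; the held-out
pair is classified by `feature > threshold → enhancing`. The direction is
fixed a priori (enhancing lesions have the higher pre-contrast statistics);
a per-fold flip for training AUC < 0.5 exists behind a flag, off by default,
because it leaks the sign decision into validation. Reported per feature:
mean and SD of fold AUCs, pooled sensitivity/specificity/accuracy over all
2·n₊·n₋ held-out classifications (pooling, rather than averaging per-fold
rates, matches the per-patient occurrence counts that are reported next to
it), and the occurrence table (times classified enhancing / times held out).
The best feature is the highest mean AUC, ties broken by pooled accuracy.

## Synthetic cohort generator

The generator exists so the full pipeline is testable without patient data.
Defaults emulate the reference study design: 14 patients (7 enhancing),
1 mm isotropic 48³ grids, a white-matter ellipsoid (semi-axes 0.44 of the
grid extent), one ellipsoidal lesion of 6–9 mm semi-axes near its center
and, in enhancing patients, an innermost core of 20–40% of the lesion volume
(selected by normalized ellipsoidal radius rank, so the fraction is exact to
the voxel). The lesion components are disjoint: `t2h` is the lesion minus
the core.

Voxel values are i.i.d. within a region — downstream analysis is entirely
first-order, so spatial texture would add cost without changing what any
test measures. Each (region, map) pair draws from a shifted lognormal.
With mean and SD targets only, moment inversion is exact:
σ² = ln(1 + cv²), μ = ln(m) − σ²/2 above the shift. When a skewness target
is given, σ is solved from the closed form g₁ = (w + 2)√(w − 1), w = e^{σ²}
(bisection), and the shift follows from the moments; the lognormal family
cannot reach g₁ ≤ 0, which is rejected. The default T1 and T2 targets are a
published cohort's per-region mean, SD *and* skewness (normal white matter
993.16/294.04 ms T1 with g₁ = 2.64, lesion 1353.78/294.68 with 1.23,
enhancing tissue 1713.30/448.03 with 1.00, shell 1056.78/315.16 with 2.27;
analogously for T2, where skewness reaches 10.72). Matching the printed
skewness concentrates the bulk of each distribution realistically — a
two-moment fit understates the published skewness several-fold and overstates
class overlap. Kurtosis is left free (a three-parameter family cannot match
four moments); the fitted lognormals are nevertheless strongly leptokurtic,
qualitatively matching the published kurtosis. PD targets are plausible
placeholders (white matter 68 ± 6%, wetter lesions above), intended to be
overridden when a real PD table is available.

Between-patient heterogeneity is modeled by multiplying each patient's
(region, map) mean and SD by a unit-mean lognormal factor with 5% CV —
published across-patient confidence intervals imply CVs of roughly 4–12%,
and 5% keeps the region ordering stable in every realization. Randomness is
one generator per cohort with per-patient substreams derived from
(seed, patient index), so cohorts are bit-reproducible and patients are
independent of cohort size.

What passing tests on this cohort do **not** show: performance on real
anatomy (no bias fields, no partial-volume rims at mask edges, no spatial
correlation, no acquisition noise model), nor realistic patient-level
prediction difficulty — with i.i.d. voxels and moderate jitter, several ABN
features separate the 7 + 7 synthetic groups perfectly, whereas real cohorts
overlap heavily (published cross-validated AUCs ≈ 0.68). The synthetic
cross-validation therefore exercises the bookkeeping and decision rule, not
the clinical effect size.

## Numerical and scale choices

* Exact signed-rank null: O(n · Σr) dynamic program, exact for n ≤ 20.
* ROC on pooled cohorts sorts ≈ 10⁵–10⁶ float64 values per question;
  thresholds are swept via binary search on the sorted class arrays.
* Default problem sizes (48³ grids, 14 patients, 10⁵-draw verification
  samples) keep a full pipeline run in seconds while leaving every region
  with thousands of voxels; they are a deliberate working scale for a
  simulation study, and all are configurable.
* Degenerate inputs have fixed conventions: empty regions raise; constant
  regions flag NaN shape statistics; NaN metric voxels never classify
  positive; thresholds are strict inequalities; Youden ties take the lower
  threshold.

## Known limitations

* The generator's geometry is ellipsoidal and single-lesion; multifocal
  disease, resection cavities and cortical involvement are out of scope.
* PD defaults are placeholders, so PD-augmented metrics run but their
  synthetic performance is not meaningful.
* The imposed index-pairing for the two-group signed-rank test is a
  convention, not a statistical recommendation; prefer the rank-sum
  cross-check when analyzing real data.
* Registration, segmentation and map estimation are upstream of this
  package and assumed correct.
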