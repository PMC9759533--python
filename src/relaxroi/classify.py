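"""Voxel-wise composite metrics, ROC curves, Youden thresholds and mask scoring.

Six voxel metrics are defined on the quantitative maps: raw T1, raw T2, the
Euclidean norm sqrt(T1^2 + T2^2) (``normT1T2``), the Euclidean norm of the
natural logarithms sqrt(ln(T1)^2 + ln(T2)^2) (``normlog``), and the two
variants that append PD (or ln PD) as a third component.  Units are mixed
inside the norms on purpose (ms with ms, or ms with percent): the metrics are
used as monotone classification scores, not as physical magnitudes.

ROC curves sweep candidate thresholds placed at midpoints between consecutive
distinct pooled values (with -inf/+inf sentinels); a voxel is called positive
when its metric is STRICTLY greater than the threshold.  The AUC is the
trapezoidal area, which for this construction equals the tie-corrected
pairwise concordance P(pos > neg) + P(pos = neg) / 2.  The operating point is
the threshold maximizing the Youden index J = sensitivity + specificity - 1,
ties broken toward the lower threshold.

Three cohort-level classification questions are supported, pooling voxels
across patients: abnormal-vs-normal white matter (the perilesional shell is
excluded as potentially tumor-infiltrated), enhancing-vs-all-non-enhancing,
and enhancing-vs-non-enhancing lesion tissue inside the lesion only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from relaxroi.io import PatientRecord, QuantitativeMapSet

logger = logging.getLogger(__name__)

METRICS = ("t1", "t2", "normT1T2", "normlog", "normT1T2PD", "normlogT1T2PD")

#: question id -> (positive ROI list, default negative ROI list)
QUESTIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "abn_vs_nwm": (("abn",), ("nwm",)),
    "t1e_vs_rest": (("t1e",), ("t2h", "per", "nwm")),
    "t1e_vs_t2h": (("t1e",), ("t2h",)),
}


@dataclass
class RocResult:
    """One ROC sweep: thresholds ascending, rule ``value > threshold``."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    youden_j: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class MaskAgreement:
    """Sensitivity/specificity/accuracy (percent) of a predicted mask."""

    sensitivity: float
    specificity: float
    accuracy: float
    n_evaluated: int


def compute_metric(maps: QuantitativeMapSet, metric: str) -> np.ndarray:
    """Evaluate one voxel metric over a whole map set.

    Logarithmic metrics are undefined where T1, T2 (or PD for the PD variant)
    are non-positive; such voxels come back NaN and their count is logged.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    t1, t2, pd_ = maps.t1, maps.t2, maps.pd
    if metric == "t1":
        return t1.copy()
    if metric == "t2":
        return t2.copy()
    if metric == "normT1T2":
        return np.sqrt(t1**2 + t2**2)
    if metric == "normT1T2PD":
        return np.sqrt(t1**2 + t2**2 + pd_**2)
    components = (t1, t2) if metric == "normlog" else (t1, t2, pd_)
    valid = np.ones(maps.shape, dtype=bool)
    for c in components:
        valid &= np.isfinite(c) & (c > 0)
    n_bad = int(valid.size - np.count_nonzero(valid))
    if n_bad:
        logger.warning(
            "%s: %d voxels with non-positive components masked out (NaN)",
            metric, n_bad,
        )
    out = np.full(maps.shape, np.nan, dtype=np.float64)
    out[valid] = np.sqrt(
        sum(np.log(c[valid]) ** 2 for c in components)
    )
    return out


def build_roc(positive_values, negative_values) -> RocResult:
    """ROC curve, AUC and Youden operating point from two pooled value sets."""
    pos = np.asarray(positive_values, dtype=np.float64).ravel()
    neg = np.asarray(negative_values, dtype=np.float64).ravel()
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must contain at least one finite value")

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    distinct = np.unique(np.concatenate([pos_sorted, neg_sorted]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    # voxels strictly above each threshold, via sorted-array bisection
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="right") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="right") / neg.size
    # endpoints: everything positive at -inf, nothing at +inf
    fpr = 1.0 - spec

    # thresholds ascend so fpr descends; integrate in ascending-fpr order
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = lowest threshold on ties
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thresholds[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
        youden_j=float(j[best]),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def pool_question_values(
    cohort: Iterable[PatientRecord],
    question: str,
    metric: str,
    negative_rois: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool positive and negative metric values across patients for a question."""
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}; expected one of {tuple(QUESTIONS)}")
    pos_rois, default_neg = QUESTIONS[question]
    neg_rois = tuple(negative_rois) if negative_rois is not None else default_neg
    pos_chunks, neg_chunks = [], []
    for rec in cohort:
        vol = compute_metric(rec.maps, metric)
        for roi in pos_rois:
            pos_chunks.append(vol[rec.rois.by_name(roi)])
        for roi in neg_rois:
            neg_chunks.append(vol[rec.rois.by_name(roi)])
    pos = np.concatenate(pos_chunks) if pos_chunks else np.empty(0)
    neg = np.concatenate(neg_chunks) if neg_chunks else np.empty(0)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0:
        raise ValueError(
            f"question {question!r}: no positive voxels in the cohort "
            "(no patient with an enhancing core?)"
        )
    return pos, neg


def run_question(
    cohort: Iterable[PatientRecord],
    question: str,
    metric: str,
    negative_rois: Sequence[str] | None = None,
) -> RocResult:
    """Build the cohort-level ROC for one classification question and metric."""
    cohort = list(cohort)
    pos, neg = pool_question_values(cohort, question, metric, negative_rois)
    return build_roc(pos, neg)


def apply_threshold(
    metric_volume: np.ndarray,
    threshold: float,
    evaluation_mask: np.ndarray,
) -> np.ndarray:
    """Binary mask of voxels strictly above the threshold, inside the mask.

    NaN metric values (log of non-positive inputs) never classify positive.
    """
    mask = np.asarray(evaluation_mask, dtype=bool)
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    vol = np.asarray(metric_volume, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        return (vol > threshold) & mask


def evaluate_masks(
    predicted: np.ndarray,
    truth: np.ndarray,
    evaluation_mask: np.ndarray,
) -> MaskAgreement:
    """Confusion-matrix agreement of a predicted mask, in percent.

    Sensitivity is computed over truth voxels inside the evaluation mask;
    specificity and accuracy over the whole evaluation mask.  An empty class
    makes the corresponding rate NaN.
    """
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    ev = np.asarray(evaluation_mask, dtype=bool)
    if not (pred.shape == tru.shape == ev.shape):
        raise ValueError("mask shapes differ")
    pred, tru = pred & ev, tru & ev
    tp = int(np.count_nonzero(pred & tru))
    fn = int(np.count_nonzero(~pred & tru))
    fp = int(np.count_nonzero(pred & ~tru & ev))
    tn = int(np.count_nonzero(~pred & ~tru & ev))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    n = tp + fn + fp + tn
    acc = 100.0 * (tp + tn) / n if n else float("nan")
    return MaskAgreement(sens, spec, acc, n)
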