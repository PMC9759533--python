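"""Patient-level prediction of contrast enhancement from pre-contrast features.

Each patient is summarized by the four first-order statistics (mean, SD,
skewness, kurtosis) of four voxel metrics (T1, T2, normT1T2, normlog)
evaluated inside the combined abnormal region — 16 candidate features, all
computable without contrast agent.  Validation is leave-pair-out: every
(enhancing, non-enhancing) patient pair is held out once, an ROC is fitted on
the remaining patients' feature values, its Youden threshold classifies the
held-out pair (strictly greater than threshold -> predicted enhancing), and
the fold's training AUC is recorded.  With 7 + 7 patients this gives 7 x 7 =
49 folds and each patient is held out exactly 7 times.

The direction high-feature -> enhancing is fixed (enhancing lesions have
higher pre-contrast T1/T2 statistics); an optional per-fold direction flip
for training AUC < 0.5 exists behind a flag but is off by default.
Sensitivity, specificity and accuracy are pooled over all held-out
classifications (per-fold averaging would weight the same patients
identically here, but pooling matches the per-patient occurrence counts
that are also reported).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from relaxroi.classify import build_roc, compute_metric
from relaxroi.io import PatientRecord
from relaxroi.stats import compute_roi_stats

FEATURE_METRICS = ("t1", "t2", "normT1T2", "normlog")
FEATURE_STATISTICS = ("mean", "sd", "skewness", "kurtosis")


@dataclass
class CvSummary:
    """Leave-pair-out cross-validation outcome for one feature."""

    feature: str
    fold_aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    sensitivity: float  # percent, pooled over held-out enhancing slots
    specificity: float  # percent, pooled over held-out non-enhancing slots
    accuracy: float  # percent, pooled over all held-out slots
    occurrences: dict[str, tuple[int, int]]  # patient -> (times positive, times held out)
    n_folds: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_folds = int(self.fold_aucs.size)


def build_feature_table(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """One row per patient: enhancement label plus the 16 lesion features.

    Columns are ``label`` (bool) and ``<metric>_<statistic>`` for the four
    metrics inside the combined abnormal region.  Degenerate statistics
    (constant regions) surface as NaN and are kept in the row.
    """
    rows = {}
    for rec in cohort:
        abn = rec.rois.by_name("abn")
        if not abn.any():
            raise ValueError(f"patient {rec.patient_id}: empty abnormal region")
        row: dict[str, float | bool] = {"label": rec.has_enhancement}
        for metric in FEATURE_METRICS:
            vol = compute_metric(rec.maps, metric)
            values = vol[abn]
            values = values[np.isfinite(values)]
            st = compute_roi_stats(values)
            for stat_name, value in st.as_dict().items():
                row[f"{metric}_{stat_name}"] = value
        rows[rec.patient_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table


def leave_pair_out_cv(
    table: pd.DataFrame, feature: str, allow_direction_flip: bool = False
) -> CvSummary:
    """Leave-pair-out cross-validation of one scalar feature.

    See the module docstring for the protocol.  ``allow_direction_flip``
    inverts the decision rule in folds whose training AUC is below 0.5.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    labels = table["label"].astype(bool)
    values = table[feature].astype(float)
    pos_ids = list(table.index[labels])
    neg_ids = list(table.index[~labels])
    if not pos_ids or not neg_ids:
        raise ValueError("both classes must be non-empty")

    fold_aucs = []
    occurrences = {pid: [0, 0] for pid in table.index}
    tp = fn = tn = fp = 0
    for pid_pos, pid_neg in itertools.product(pos_ids, neg_ids):
        train = table.index.difference([pid_pos, pid_neg])
        train_pos = values[train.intersection(pos_ids)].to_numpy()
        train_neg = values[train.intersection(neg_ids)].to_numpy()
        if train_pos.size == 0 or train_neg.size == 0:
            import warnings

            warnings.warn(
                f"fold ({pid_pos}, {pid_neg}) skipped: a training class is empty",
                stacklevel=2,
            )
            continue
        roc = build_roc(train_pos, train_neg)
        fold_aucs.append(roc.auc)
        flip = allow_direction_flip and roc.auc < 0.5
        for pid, truth in ((pid_pos, True), (pid_neg, False)):
            above = bool(values[pid] > roc.youden_threshold)
            predicted = (not above) if flip else above
            occurrences[pid][1] += 1
            if predicted:
                occurrences[pid][0] += 1
            if truth and predicted:
                tp += 1
            elif truth:
                fn += 1
            elif predicted:
                fp += 1
            else:
                tn += 1

    fold_aucs = np.asarray(fold_aucs, dtype=np.float64)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    total = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    return CvSummary(
        feature=feature,
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        sd_auc=float(fold_aucs.std(ddof=1)) if fold_aucs.size > 1 else 0.0,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        occurrences={pid: tuple(v) for pid, v in occurrences.items()},
    )


def summarize_prediction(
    cv_summaries: Mapping[str, CvSummary] | Iterable[CvSummary],
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Grid of CV results across features plus the per-patient occurrence table.

    Returns ``(grid, occurrences, best_feature)`` where the grid has one row
    per feature (mean/SD of fold AUCs and pooled percent rates) and the best
    feature maximizes mean AUC, ties broken by pooled accuracy.
    """
    if isinstance(cv_summaries, Mapping):
        summaries = list(cv_summaries.values())
    else:
        summaries = list(cv_summaries)
    if not summaries:
        raise ValueError("at least one feature must be analyzed")
    grid = pd.DataFrame(
        [
            {
                "feature": s.feature,
                "mean_auc": s.mean_auc,
                "sd_auc": s.sd_auc,
                "sensitivity_pct": s.sensitivity,
                "specificity_pct": s.specificity,
                "accuracy_pct": s.accuracy,
                "n_folds": s.n_folds,
            }
            for s in summaries
        ]
    ).set_index("feature")
    occ_rows = []
    for s in summaries:
        for pid, (n_pos, n_held) in s.occurrences.items():
            occ_rows.append(
                {
                    "feature": s.feature,
                    "patient_id": pid,
                    "times_classified_enhancing": n_pos,
                    "times_held_out": n_held,
                }
            )
    occurrences = pd.DataFrame(occ_rows)
    best = grid.sort_values(
        ["mean_auc", "accuracy_pct"], ascending=False, kind="stable"
    ).index[0]
    return grid, occurrences, str(best)
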