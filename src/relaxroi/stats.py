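"""First-order histogram statistics of map values inside a region.

Conventions (fixed once, used everywhere):

* mean — arithmetic mean;
* sd — sample standard deviation with the n-1 denominator;
* skewness — Fisher g1 = m3 / m2^(3/2) with n-denominator central moments;
* kurtosis — Pearson m4 / m2^2, i.e. NON-excess (a normal distribution
  scores 3), again with n-denominator moments and no small-sample bias
  correction.

Degenerate regions (constant values, or fewer than 3 voxels) get sd as
defined and NaN skewness/kurtosis.  Cohort summaries report, per (region,
map, statistic) cell, the across-patient mean and a t-based 95% confidence
half-width — appropriate for the small patient counts these studies have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from relaxroi.io import PatientRecord

STATISTIC_NAMES = ("mean", "sd", "skewness", "kurtosis")


class EmptyRoiError(ValueError):
    """Raised when statistics are requested over an empty region."""


@dataclass(frozen=True)
class RoiStatistics:
    """The four first-order statistics of one map inside one region."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
        }


def _extract(map_volume: np.ndarray, roi_mask: np.ndarray | None) -> np.ndarray:
    vol = np.asarray(map_volume, dtype=np.float64)
    if roi_mask is None:
        values = vol.ravel()
    else:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != vol.shape:
            raise ValueError("mask shape does not match volume shape")
        values = vol[mask]
    if values.size == 0:
        raise EmptyRoiError("region contains no voxels")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite map values inside the region")
    return values


def compute_roi_stats(
    map_volume: np.ndarray, roi_mask: np.ndarray | None = None
) -> RoiStatistics:
    """Compute mean, SD, skewness and kurtosis of the values inside a mask.

    ``roi_mask=None`` means "all voxels" (useful for 1-D value arrays).
    """
    values = _extract(map_volume, roi_mask)
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if n < 3 or sd == 0.0:
        skew = kurt = float("nan")
    else:
        skew = float(sps.skew(values, bias=True))
        kurt = float(sps.kurtosis(values, fisher=False, bias=True))
    return RoiStatistics(mean=mean, sd=sd, skewness=skew, kurtosis=kurt, n_voxels=int(n))


def compute_pdf(
    map_volume: np.ndarray,
    roi_mask: np.ndarray | None,
    bin_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of the values inside a mask.

    Returns ``(heights, bin_edges)`` with sum(height * width) = 1 over the
    bins that contain the data (numpy's density convention).
    """
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    values = _extract(map_volume, roi_mask)
    heights, edges = np.histogram(values, bins=bin_edges, density=True)
    return heights, edges


def cohort_statistics(
    cohort: Iterable[PatientRecord],
    rois: Sequence[str] = ("nwm", "t2h", "t1e", "per"),
    maps: Sequence[str] = ("t1", "t2", "pd"),
) -> pd.DataFrame:
    """Per-patient ROI statistics for a whole cohort, in tidy form.

    Returns a DataFrame with columns ``patient_id, roi, map, statistic,
    value, n_voxels``.  Patients whose region is empty (e.g. no enhancing
    core) simply contribute no rows for that region.
    """
    rows = []
    for rec in cohort:
        for roi in rois:
            mask = rec.rois.by_name(roi)
            if not mask.any():
                continue
            for map_name in maps:
                st = compute_roi_stats(rec.maps.by_name(map_name), mask)
                for stat_name, value in st.as_dict().items():
                    rows.append(
                        {
                            "patient_id": rec.patient_id,
                            "roi": roi,
                            "map": map_name,
                            "statistic": stat_name,
                            "value": value,
                            "n_voxels": st.n_voxels,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_cohort(per_patient_stats: pd.DataFrame) -> pd.DataFrame:
    """Across-patient summary of tidy per-patient statistics.

    For every (roi, map, statistic) cell: the mean over patients, the t-based
    95% CI half-width t_{0.975, n-1} * sd / sqrt(n), and the patient count.
    Cells with a single patient get an infinite half-width.
    """
    required = {"roi", "map", "statistic", "value"}
    if not required.issubset(per_patient_stats.columns):
        raise ValueError(f"input must have columns {sorted(required)}")

    def _cell(group: pd.DataFrame) -> pd.Series:
        vals = group["value"].to_numpy(dtype=np.float64)
        n = vals.size
        mean = float(np.mean(vals))
        if n >= 2:
            half = float(sps.t.ppf(0.975, n - 1) * np.std(vals, ddof=1) / np.sqrt(n))
        else:
            half = float("inf")
        return pd.Series({"mean": mean, "ci95_halfwidth": half, "n_patients": n})

    out = (
        per_patient_stats.groupby(["roi", "map", "statistic"], sort=False)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    out["n_patients"] = out["n_patients"].astype(int)
    return out
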