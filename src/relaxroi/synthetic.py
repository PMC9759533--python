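"""Synthetic glioma cohort generator.

Real quantitative-map cohorts of treated gliomas are small and rarely shared,
so the pipeline ships a generator that emulates the structure of such a study:
14 patients, half with a contrast-enhancing core, each with an ellipsoidal
white-matter compartment, an ellipsoidal T2-hyperintense lesion inside it and,
for enhancing patients, an inner enhancing core.  Voxel values inside each
region are drawn i.i.d. from a shifted lognormal whose first two moments match
the region's configured targets exactly by moment inversion — the per-region
default targets are the published cohort means and standard deviations of T1
and T2 in normal-appearing white matter, perilesional tissue, T2-hyperintense
and enhancing tissue.  A plain (zero-shift) lognormal is right-skewed and
heavy-tailed, matching the qualitative shape of per-region relaxometry
histograms; when a target skewness is given the shift is solved so the
analytic lognormal skewness matches it.

Voxel values carry no spatial texture: every downstream statistic in this
pipeline is first-order, so i.i.d. sampling within a region is sufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from relaxroi.io import (
    PatientRecord,
    QuantitativeMapSet,
    RoiSet,
    save_map,
    save_mask,
    write_manifest,
)
from relaxroi.roi import DEFAULT_SHELL_RADIUS_MM, derive_rois


class GeometryError(ValueError):
    """The requested lesion plus its shell does not fit inside the grid."""


@dataclass(frozen=True)
class RoiDistributionSpec:
    """Target first-order moments for one region of one map.

    Parameters
    ----------
    target_mean, target_sd : float
        Desired mean and SD of the sampled values, in map units (ms for T1/T2,
        percent for PD).
    target_skewness : float, optional
        Desired Fisher skewness.  When given, the lognormal shape parameter is
        solved from the closed-form skewness (w + 2) * sqrt(w - 1) with
        w = exp(sigma^2), and the shift follows from the first two moments.
        Must be positive (the lognormal family is right-skewed).
    shift : float
        Lower bound of the support when no skewness target is given.
    """

    target_mean: float
    target_sd: float
    target_skewness: float | None = None
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if self.target_mean <= self.shift:
            raise ValueError("target_mean must exceed shift")
        if self.target_skewness is not None and self.target_skewness <= 0:
            raise ValueError(
                "lognormal family cannot reach skewness <= 0; "
                f"got {self.target_skewness}"
            )

    def lognormal_params(self) -> tuple[float, float, float]:
        """Return (mu, sigma, shift) of the fitted shifted lognormal.

        With skewness unset: the lognormal above ``shift`` matches mean and SD
        by moment inversion.  With skewness set: sigma comes from inverting the
        analytic skewness by bisection, then the shift is implied by the
        coefficient of variation of the un-shifted part.
        """
        if self.target_skewness is None:
            shift = self.shift
            m = self.target_mean - shift
            cv2 = (self.target_sd / m) ** 2
            sigma2 = math.log1p(cv2)
        else:
            w = _solve_w_from_skewness(self.target_skewness)
            sigma2 = math.log(w)
            m = self.target_sd / math.sqrt(w - 1.0)
            shift = self.target_mean - m
        sigma = math.sqrt(sigma2)
        mu = math.log(m) - sigma2 / 2.0
        return mu, sigma, shift

    def analytic_skewness(self) -> float:
        """Skewness of the fitted lognormal: (w + 2) sqrt(w - 1), w = e^{sigma^2}."""
        _, sigma, _ = self.lognormal_params()
        w = math.exp(sigma**2)
        return (w + 2.0) * math.sqrt(w - 1.0)

    def analytic_kurtosis(self) -> float:
        """Pearson (non-excess) kurtosis of the fitted lognormal."""
        _, sigma, _ = self.lognormal_params()
        w = math.exp(sigma**2)
        return w**4 + 2.0 * w**3 + 3.0 * w**2 - 3.0


def _solve_w_from_skewness(g1: float) -> float:
    """Invert g1 = (w + 2) sqrt(w - 1) for w > 1 by bisection."""
    f = lambda w: (w + 2.0) * math.sqrt(w - 1.0) - g1
    lo, hi = 1.0 + 1e-12, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for finite g1
            raise ValueError("skewness target out of range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_roi_values(
    spec: RoiDistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. values from the spec's shifted lognormal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu, sigma, shift = spec.lognormal_params()
    return shift + rng.lognormal(mean=mu, sigma=sigma, size=n)


# default targets -----------------------------------------------------------

#: Cohort-mean (mean, SD, skewness) of T1 in ms per region, from a published
#: 14-patient treated-glioma relaxometry cohort.
DEFAULT_T1_TARGETS: Mapping[str, tuple[float, float, float]] = {
    "nwm": (993.16, 294.04, 2.64),
    "per": (1056.78, 315.16, 2.27),
    "t2h": (1353.78, 294.68, 1.23),
    "t1e": (1713.30, 448.03, 1.00),
}

#: Cohort-mean (mean, SD, skewness) of T2 in ms per region, same source as T1.
DEFAULT_T2_TARGETS: Mapping[str, tuple[float, float, float]] = {
    "nwm": (92.33, 48.90, 10.72),
    "per": (103.82, 63.56, 8.10),
    "t2h": (152.25, 64.63, 4.62),
    "t1e": (180.05, 130.81, 3.57),
}

#: Proton density (percent water) per region.  No published per-region table
#: is bundled; these are physiologically plausible placeholders (white matter
#: ~68%, edema and enhancing tissue wetter) and are meant to be overridden.
DEFAULT_PD_TARGETS: Mapping[str, tuple[float, float]] = {
    "nwm": (68.0, 6.0),
    "per": (72.0, 8.0),
    "t2h": (82.0, 9.0),
    "t1e": (85.0, 10.0),
}

ROI_NAMES = ("nwm", "per", "t2h", "t1e")
MAP_NAMES = ("t1", "t2", "pd")


def default_roi_specs() -> dict[tuple[str, str], RoiDistributionSpec]:
    """Default (roi, map) -> spec table built from the bundled targets."""
    specs: dict[tuple[str, str], RoiDistributionSpec] = {}
    for targets, map_name in (
        (DEFAULT_T1_TARGETS, "t1"),
        (DEFAULT_T2_TARGETS, "t2"),
        (DEFAULT_PD_TARGETS, "pd"),
    ):
        for roi, values in targets.items():
            specs[(roi, map_name)] = RoiDistributionSpec(*values)
    return specs


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    The defaults emulate the reference study design: 7 enhancing plus 7
    non-enhancing patients on a 1-mm isotropic grid, lesion radii of 6-9 mm
    with the enhancing core occupying 20-40% of the lesion volume, and mild
    (5%) per-patient lognormal jitter of each region's target mean to mimic
    between-patient heterogeneity.
    """

    n_enhancing: int = 7
    n_nonenhancing: int = 7
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_range: tuple[float, float] = (6.0, 9.0)
    core_fraction_range: tuple[float, float] = (0.2, 0.4)
    shell_radius_mm: float = DEFAULT_SHELL_RADIUS_MM
    mean_jitter: float = 0.05
    per_roi_specs: dict[tuple[str, str], RoiDistributionSpec] = field(
        default_factory=default_roi_specs
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enhancing < 0 or self.n_nonenhancing < 0:
            raise ValueError("patient counts must be >= 0")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion_radius_range must be positive and ordered")
        flo, fhi = self.core_fraction_range
        if not (0.0 < flo <= fhi < 1.0):
            raise ValueError("core_fraction_range must lie in (0, 1)")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_dims
        return aff


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    voxel_dims: np.ndarray,
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipsoid mask plus the normalized radial distance volume."""
    grids = np.meshgrid(
        *(np.arange(s) * d for s, d in zip(shape, voxel_dims)), indexing="ij"
    )
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return r2 <= 1.0, np.sqrt(r2)


def generate_patient(
    config: CohortConfig,
    enhancing: bool,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
) -> PatientRecord:
    """Generate one synthetic patient record with derived ROIs populated.

    Geometry: a large white-matter ellipsoid centered in the grid; a lesion
    ellipsoid (radii drawn from ``lesion_radius_range``, mild anisotropy and a
    small random center offset) placed near its center; for an enhancing
    patient the core is the innermost ``core_fraction`` of lesion voxels by
    normalized ellipsoidal radius, so the core voxel count matches the target
    fraction to the voxel.  The lesion component masks are disjoint: t2h is
    the lesion minus the core.
    """
    shape = tuple(config.grid_shape)
    voxel_dims = np.asarray(config.voxel_dims, dtype=np.float64)
    extent_mm = np.asarray(shape) * voxel_dims
    center_mm = extent_mm / 2.0

    lo, hi = config.lesion_radius_range
    radii = rng.uniform(lo, hi, size=3)
    offset = rng.uniform(-2.0, 2.0, size=3)
    lesion_center = center_mm + offset
    margin = radii + config.shell_radius_mm + voxel_dims
    if np.any(lesion_center - margin < 0) or np.any(lesion_center + margin > extent_mm):
        raise GeometryError(
            f"lesion (radii {radii} mm) plus {config.shell_radius_mm} mm shell "
            f"does not fit in grid of extent {extent_mm} mm"
        )

    wm_axes = 0.44 * extent_mm
    wm, _ = _ellipsoid_mask(shape, voxel_dims, center_mm, wm_axes)
    lesion, lesion_r = _ellipsoid_mask(shape, voxel_dims, lesion_center, radii)
    if not lesion.any():
        raise GeometryError("lesion ellipsoid contains no voxel centers")

    t1e = np.zeros(shape, dtype=bool)
    if enhancing:
        frac = rng.uniform(*config.core_fraction_range)
        n_core = max(1, int(round(frac * np.count_nonzero(lesion))))
        idx = np.flatnonzero(lesion)
        order = np.argsort(lesion_r.ravel()[idx], kind="stable")
        t1e.ravel()[idx[order[:n_core]]] = True
    t2h = lesion & ~t1e

    rois = RoiSet(t2h=t2h, t1e=t1e, wm=wm)
    derive_rois(rois, voxel_dims, config.shell_radius_mm)

    # Per-patient spec jitter: multiply the target mean by a unit-mean
    # lognormal factor; the SD scales along with the mean (constant CV).
    jitter = {}
    for key, spec in config.per_roi_specs.items():
        if config.mean_jitter > 0:
            factor = float(
                np.exp(rng.normal(0.0, config.mean_jitter) - config.mean_jitter**2 / 2)
            )
        else:
            factor = 1.0
        jitter[key] = replace(
            spec,
            target_mean=spec.target_mean * factor,
            target_sd=spec.target_sd * factor,
            shift=spec.shift * factor,
        )

    volumes = {}
    for map_name in MAP_NAMES:
        # Background (outside every region) uses normal-white-matter values so
        # the whole volume stays physically plausible and log-safe.
        vol = sample_roi_values(
            jitter[("nwm", map_name)], int(np.prod(shape)), rng
        ).reshape(shape)
        for roi in ("per", "t2h", "t1e"):
            mask = rois.by_name(roi)
            n = int(np.count_nonzero(mask))
            if n:
                vol[mask] = sample_roi_values(jitter[(roi, map_name)], n, rng)
        volumes[map_name] = vol

    maps = QuantitativeMapSet(
        patient_id, volumes["t1"], volumes["t2"], volumes["pd"], config.affine
    )
    return PatientRecord(maps=maps, rois=rois)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the full cohort, reproducibly from ``config.seed``.

    Patients alternate enhancing / non-enhancing until one group is exhausted
    (ids ``patient-01`` ...); each patient draws from an independent substream
    of the cohort seed, so the cohort is reproducible patient by patient.
    """
    n_pairs = min(config.n_enhancing, config.n_nonenhancing)
    flags = [f for _ in range(n_pairs) for f in (True, False)]
    flags += [True] * (config.n_enhancing - n_pairs)
    flags += [False] * (config.n_nonenhancing - n_pairs)
    records = []
    for i, enhancing in enumerate(flags):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        records.append(
            generate_patient(config, enhancing, rng, patient_id=f"patient-{i + 1:02d}")
        )
    return records


def write_cohort(records: list[PatientRecord], outdir: str | Path) -> Path:
    """Write a cohort as per-patient NIfTI files plus a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for rec in records:
        pdir = outdir / rec.patient_id
        pdir.mkdir(exist_ok=True)
        aff = rec.maps.affine
        for name in MAP_NAMES:
            save_map(rec.maps.by_name(name), aff, pdir / f"{name}.nii.gz")
        for name in ("t2h", "t1e", "wm"):
            save_mask(rec.rois.by_name(name), aff, pdir / f"{name}.nii.gz")
        entries[rec.patient_id] = {
            role: f"{rec.patient_id}/{role}.nii.gz"
            for role in ("t1", "t2", "pd", "t2h", "t1e", "wm")
        }
    manifest = outdir / "manifest.yaml"
    write_manifest(entries, manifest)
    return manifest
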