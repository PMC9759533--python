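"""Derivation of the analysis regions from raw lesion and white-matter masks.

Three regions are derived per patient:

* ``abn`` — the combined abnormal tissue, the voxel-wise union of the
  T2-hyperintense lesion (t2h) and the contrast-enhancing region (t1e);
* ``per`` — the perilesional shell: every voxel whose center lies within a
  physical radius (default 10 mm) of some abn voxel center, minus abn itself;
* ``nwm`` — normal-appearing white matter: the white-matter mask minus abn
  and per.

The shell is computed with a Euclidean distance transform in world units so
that anisotropic voxels (e.g. 0.875 x 0.875 x 5 mm) give a geometrically
correct 1-cm margin rather than a 1-voxel-per-axis dilation.  Ball membership
is closed (distance <= radius).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from relaxroi.io import PatientRecord, RoiSet

DEFAULT_SHELL_RADIUS_MM = 10.0


def derive_abn(t2h: np.ndarray, t1e: np.ndarray) -> np.ndarray:
    """Union of the two lesion components."""
    t2h = np.asarray(t2h, dtype=bool)
    t1e = np.asarray(t1e, dtype=bool)
    if t2h.shape != t1e.shape:
        raise ValueError(f"mask shapes differ: {t2h.shape} vs {t1e.shape}")
    return t2h | t1e


def derive_per(
    abn: np.ndarray,
    voxel_dims: np.ndarray | tuple[float, float, float],
    radius_mm: float = DEFAULT_SHELL_RADIUS_MM,
) -> np.ndarray:
    """Perilesional shell: voxels within ``radius_mm`` of abn, excluding abn.

    Distances are voxel-center to voxel-center in mm, each axis scaled by its
    voxel edge length.  An empty abn yields an empty shell.
    """
    abn = np.asarray(abn, dtype=bool)
    voxel_dims = np.asarray(voxel_dims, dtype=np.float64)
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if np.any(voxel_dims <= 0):
        raise ValueError("voxel_dims must be strictly positive")
    if not abn.any():
        return np.zeros_like(abn)
    dist = ndimage.distance_transform_edt(~abn, sampling=voxel_dims)
    return (dist <= radius_mm) & ~abn


def derive_nwm(wm: np.ndarray, abn: np.ndarray, per: np.ndarray) -> np.ndarray:
    """White matter minus abnormal tissue and perilesional shell."""
    wm = np.asarray(wm, dtype=bool)
    if wm.shape != np.shape(abn) or wm.shape != np.shape(per):
        raise ValueError("mask shapes differ")
    return wm & ~np.asarray(abn, dtype=bool) & ~np.asarray(per, dtype=bool)


def derive_rois(
    rois: RoiSet,
    voxel_dims: np.ndarray | tuple[float, float, float],
    radius_mm: float = DEFAULT_SHELL_RADIUS_MM,
    brain_mask: np.ndarray | None = None,
) -> RoiSet:
    """Populate abn, per and nwm in place and return the RoiSet.

    If ``brain_mask`` is given the shell is intersected with it (the shell is
    otherwise unconstrained and may extend past the brain).
    """
    rois.abn = derive_abn(rois.t2h, rois.t1e)
    per = derive_per(rois.abn, voxel_dims, radius_mm)
    if brain_mask is not None:
        per = per & np.asarray(brain_mask, dtype=bool)
    rois.per = per
    rois.nwm = derive_nwm(rois.wm, rois.abn, rois.per)
    rois.validate()
    return rois


def derive_patient_rois(record: PatientRecord, radius_mm: float = DEFAULT_SHELL_RADIUS_MM) -> PatientRecord:
    """Convenience wrapper deriving ROIs for a loaded patient record."""
    derive_rois(record.rois, record.maps.voxel_dims, radius_mm)
    return record
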