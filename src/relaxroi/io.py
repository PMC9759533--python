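"""NIfTI input/output for quantitative maps and masks, and the patient record.

All volumes of one patient must live on a single voxel grid (same shape, same
affine up to a small float tolerance); registration itself is out of scope.
Masks are binarized at > 0.5 so that masks that were resampled with
interpolation are handled gracefully.  Maps are promoted to float64 internally
regardless of the on-disk dtype because downstream composite metrics take
logarithms and Euclidean norms.

Voxel indexing is 0-based (i, j, k); world coordinates in mm are obtained
through the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

#: absolute tolerance on affine entries when checking coregistration
DEFAULT_AFFINE_TOL = 1e-4

#: threshold above which a mask voxel counts as set
MASK_BINARIZATION_THRESHOLD = 0.5


class CoregistrationError(ValueError):
    """Volumes of one patient do not share a grid (shape or affine mismatch)."""


class DataQualityError(ValueError):
    """Map values violate basic physical constraints inside the brain masks."""


@dataclass
class QuantitativeMapSet:
    """One patient's coregistered quantitative volumes.

    Attributes
    ----------
    patient_id : str
        Free-form identifier.
    t1, t2 : ndarray
        Longitudinal / transverse relaxation times in ms, 3-D float64.
    pd : ndarray
        Proton density in percent units, 3-D float64.
    affine : ndarray
        4x4 voxel-to-world (mm) transform shared by all three volumes.
    """

    patient_id: str
    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        self.t2 = np.asarray(self.t2, dtype=np.float64)
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not (self.t1.shape == self.t2.shape == self.pd.shape):
            raise CoregistrationError(
                f"patient {self.patient_id}: map shapes differ "
                f"(t1 {self.t1.shape}, t2 {self.t2.shape}, pd {self.pd.shape})"
            )
        if self.t1.ndim != 3:
            raise ValueError("maps must be 3-D volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine's linear part)."""
        dims = np.linalg.norm(self.affine[:3, :3], axis=0)
        if np.any(dims <= 0):
            raise ValueError("voxel dimensions must be strictly positive")
        return dims

    def by_name(self, name: str) -> np.ndarray:
        vol = {"t1": self.t1, "t2": self.t2, "pd": self.pd}.get(name)
        if vol is None:
            raise KeyError(f"unknown map {name!r}; expected t1, t2 or pd")
        return vol


@dataclass
class RoiSet:
    """Raw masks (t2h, t1e, wm) plus the three derived regions.

    ``abn`` (union of lesion components), ``per`` (1-cm perilesional shell) and
    ``nwm`` (white matter minus abn and per) are ``None`` until populated by
    :func:`relaxroi.roi.derive_rois`.
    """

    t2h: np.ndarray
    t1e: np.ndarray
    wm: np.ndarray
    abn: np.ndarray | None = None
    per: np.ndarray | None = None
    nwm: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("t2h", "t1e", "wm", "abn", "per", "nwm"):
            m = getattr(self, name)
            if m is not None:
                setattr(self, name, np.asarray(m, dtype=bool))
        if not (self.t2h.shape == self.t1e.shape == self.wm.shape):
            raise CoregistrationError("raw masks do not share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2h.shape

    def by_name(self, name: str) -> np.ndarray:
        m = getattr(self, name, None)
        if m is None:
            raise KeyError(f"ROI {name!r} is unknown or not derived yet")
        return m

    def validate(self) -> None:
        """Check the derived-ROI invariants; raise ValueError on violation."""
        if self.abn is None or self.per is None or self.nwm is None:
            raise ValueError("derived ROIs not populated; call derive_rois first")
        if not np.array_equal(self.abn, self.t2h | self.t1e):
            raise ValueError("abn must equal t2h | t1e exactly")
        if np.any(self.per & self.abn):
            raise ValueError("per overlaps abn")
        if np.any(self.nwm & (self.abn | self.per)):
            raise ValueError("nwm overlaps abn or per")
        if np.any(self.nwm & ~self.wm):
            raise ValueError("nwm extends outside wm")


@dataclass
class PatientRecord:
    """Maps plus ROIs of one patient; enhancement status derives from t1e."""

    maps: QuantitativeMapSet
    rois: RoiSet

    def __post_init__(self) -> None:
        if self.maps.shape != self.rois.shape:
            raise CoregistrationError(
                f"patient {self.patient_id}: mask shape {self.rois.shape} "
                f"differs from map shape {self.maps.shape}"
            )

    @property
    def patient_id(self) -> str:
        return self.maps.patient_id

    @property
    def has_enhancement(self) -> bool:
        return bool(np.count_nonzero(self.rois.t1e) > 0)


def _read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def load_patient(
    t1_path: str | Path,
    t2_path: str | Path,
    pd_path: str | Path,
    t2h_path: str | Path,
    t1e_path: str | Path,
    wm_path: str | Path,
    patient_id: str | None = None,
    affine_tol: float = DEFAULT_AFFINE_TOL,
) -> PatientRecord:
    """Load one patient's six NIfTI volumes into a :class:`PatientRecord`.

    The first file (t1) defines the reference grid; every other file must match
    its shape exactly and its affine entry-wise within ``affine_tol``.  Masks
    are binarized at > 0.5.  Derived ROIs (abn, per, nwm) are left unpopulated.

    Raises
    ------
    CoregistrationError
        If a volume's shape or affine disagrees with the reference, naming the
        offending file.
    DataQualityError
        If T1 or T2 contains non-finite or non-positive values inside any raw
        mask (those voxels would break the logarithmic metric).
    """
    paths = {
        "t1": t1_path, "t2": t2_path, "pd": pd_path,
        "t2h": t2h_path, "t1e": t1e_path, "wm": wm_path,
    }
    vols: dict[str, np.ndarray] = {}
    ref_affine: np.ndarray | None = None
    ref_shape: tuple | None = None
    for role, path in paths.items():
        vol, affine = _read_volume(path)
        if ref_affine is None:
            ref_affine, ref_shape = affine, vol.shape
        else:
            if vol.shape != ref_shape:
                raise CoregistrationError(
                    f"{path}: shape {vol.shape} differs from reference {ref_shape}"
                )
            if np.max(np.abs(affine - ref_affine)) > affine_tol:
                raise CoregistrationError(
                    f"{path}: affine differs from reference by more than {affine_tol}"
                )
        vols[role] = vol

    masks = {r: vols[r] > MASK_BINARIZATION_THRESHOLD for r in ("t2h", "t1e", "wm")}
    union = masks["t2h"] | masks["t1e"] | masks["wm"]
    for name in ("t1", "t2"):
        vals = vols[name][union]
        bad = int(np.count_nonzero(~np.isfinite(vals) | (vals <= 0)))
        if bad:
            raise DataQualityError(
                f"{paths[name]}: {bad} non-finite or non-positive {name.upper()} "
                "voxels inside the raw masks"
            )

    pid = patient_id if patient_id is not None else Path(t1_path).stem.split(".")[0]
    maps = QuantitativeMapSet(pid, vols["t1"], vols["t2"], vols["pd"], ref_affine)
    rois = RoiSet(t2h=masks["t2h"], t1e=masks["t1e"], wm=masks["wm"])
    return PatientRecord(maps=maps, rois=rois)


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an unsigned 8-bit NIfTI volume."""
    data = np.asarray(mask)
    if not np.isin(np.unique(data), (0, 1)).all():
        raise ValueError("mask must be binary (values 0/1)")
    img = nib.Nifti1Image(data.astype(np.uint8), np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))


def save_map(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a quantitative map as a 32-bit float NIfTI volume."""
    img = nib.Nifti1Image(
        np.asarray(volume, dtype=np.float32), np.asarray(affine, dtype=np.float64)
    )
    nib.save(img, str(path))


# manifest handling ---------------------------------------------------------

_MANIFEST_ROLES = ("t1", "t2", "pd", "t2h", "t1e", "wm")


def write_manifest(entries: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    """Write a cohort manifest: patient_id -> {role: NIfTI path}."""
    payload = {"patients": {pid: dict(roles) for pid, roles in sorted(entries.items())}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_manifest(path: str | Path, affine_tol: float = DEFAULT_AFFINE_TOL) -> list[PatientRecord]:
    """Load every patient listed in a YAML cohort manifest.

    The manifest maps each patient id to the six role paths (t1, t2, pd, t2h,
    t1e, wm); relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "patients" not in payload:
        raise ValueError(f"{path}: manifest must contain a 'patients' mapping")
    records = []
    for pid, roles in sorted(payload["patients"].items()):
        missing = [r for r in _MANIFEST_ROLES if r not in roles]
        if missing:
            raise ValueError(f"{path}: patient {pid} lacks roles {missing}")
        resolved = {r: path.parent / roles[r] for r in _MANIFEST_ROLES}
        records.append(
            load_patient(
                resolved["t1"], resolved["t2"], resolved["pd"],
                resolved["t2h"], resolved["t1e"], resolved["wm"],
                patient_id=str(pid), affine_tol=affine_tol,
            )
        )
    return records
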