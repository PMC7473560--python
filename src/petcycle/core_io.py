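"""Domain types and I/O for PET volumes.

A :class:`PETVolume` is a 3-D grid of activity concentration in kBq/ml with
an isotropic voxel size; :class:`ScanMeta` carries the scan quantities that
standardized-uptake-value (SUV) computation needs (decay-corrected injected
activity a' in kBq and patient weight w in grams).  Two on-disk dialects are
supported: NIfTI-1 (via nibabel) with a JSON sidecar for the metadata, and a
self-contained compressed-array archive (``.npz``) holding both the grid and
the metadata table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Defaults applied when a file carries no scan metadata: mean injected
#: activity 370.81 MBq and a mid-range 70 kg adult.
DEFAULT_INJECTED_ACTIVITY_KBQ = 370810.0
DEFAULT_PATIENT_WEIGHT_G = 70000.0

DEFAULT_VOXEL_SIZE_MM = 2.1

ROLES = ("low_dose", "full_dose", "truth", "recovered")


@dataclass
class PETVolume:
    """3-D activity-concentration grid (kBq/ml)."""

    values: np.ndarray
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    domain_role: str = "full_dose"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("PETVolume needs a 3-D grid with positive dimensions")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.domain_role not in ROLES:
            raise ValueError(f"unknown domain role {self.domain_role!r}")
        # invalid values are tolerated at construction so that validate_pair
        # can report them; writers and downstream modules reject them
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            log.warning("PETVolume carries non-finite or negative values")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def with_role(self, role: str) -> "PETVolume":
        return replace(self, domain_role=role)


@dataclass
class ScanMeta:
    """Scan-level quantities entering the SUV formula SUV = r / (a'/w)."""

    injected_activity_kbq: float = DEFAULT_INJECTED_ACTIVITY_KBQ
    patient_weight_g: float = DEFAULT_PATIENT_WEIGHT_G
    dose_fraction: float = 1.0

    def __post_init__(self):
        if self.injected_activity_kbq <= 0 or self.patient_weight_g <= 0:
            raise ValueError("injected activity and weight must be positive")
        if not 0 < self.dose_fraction <= 1:
            raise ValueError("dose_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "injected_activity_kbq": self.injected_activity_kbq,
            "patient_weight_g": self.patient_weight_g,
            "dose_fraction": self.dose_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMeta":
        return cls(
            injected_activity_kbq=float(
                d.get("injected_activity_kbq", DEFAULT_INJECTED_ACTIVITY_KBQ)
            ),
            patient_weight_g=float(d.get("patient_weight_g", DEFAULT_PATIENT_WEIGHT_G)),
            dose_fraction=float(d.get("dose_fraction", 1.0)),
        )


@dataclass
class VOIMask:
    """Boolean volume-of-interest mask aligned with a companion volume."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOIMask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_against(self, vol: PETVolume):
        if self.mask.shape != vol.shape:
            raise ValueError(
                f"mask {self.mask.shape} does not match volume {vol.shape}"
            )
        if self.n_voxels == 0:
            raise ValueError(f"VOI {self.label!r} selects no voxels")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: PETVolume, meta: ScanMeta, path, dialect: str = "archive"):
    """Write a volume (and metadata) in the named dialect; returns the path."""
    path = Path(path)
    if np.any(~np.isfinite(vol.values)):
        raise ValueError("refusing to write non-finite activity values")
    if dialect == "archive":
        np.savez_compressed(
            path,
            values=vol.values,
            voxel_size_mm=np.float64(vol.voxel_size_mm),
            domain_role=np.bytes_(vol.domain_role.encode()),
            **{k: np.float64(v) for k, v in meta.to_dict().items()},
        )
        # np.savez appends .npz if missing
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
    elif dialect == "nifti":
        import nibabel as nib

        affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(vol.values, affine), str(path))
        sidecar = dict(meta.to_dict(), domain_role=vol.domain_role)
        _sidecar_path(path).write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_volume(path, dialect: str = "archive") -> tuple[PETVolume, ScanMeta]:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "archive":
        with np.load(path) as z:
            values = z["values"]
            voxel = float(z["voxel_size_mm"]) if "voxel_size_mm" in z else (
                DEFAULT_VOXEL_SIZE_MM
            )
            role = (
                bytes(z["domain_role"]).decode() if "domain_role" in z else "full_dose"
            )
            meta = ScanMeta.from_dict(
                {k: float(z[k]) for k in ScanMeta().to_dict() if k in z}
            )
    elif dialect == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj, dtype=np.float64)
        voxel = float(img.header.get_zooms()[0])
        side = _sidecar_path(path)
        if side.exists():
            d = json.loads(side.read_text())
            role = d.get("domain_role", "full_dose")
            meta = ScanMeta.from_dict(d)
        else:
            log.info("no metadata sidecar for %s; applying defaults", path)
            role, meta = "full_dose", ScanMeta()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if voxel <= 0:
        raise ValueError(f"non-positive voxel size in {path}")
    return PETVolume(values, voxel_size_mm=voxel, domain_role=role), meta


def validate_pair(ld: PETVolume, fd: PETVolume) -> bool:
    """True iff the two volumes are geometrically and numerically compatible."""
    if ld.shape != fd.shape:
        log.warning("pair rejected: shapes %s vs %s", ld.shape, fd.shape)
        return False
    if not np.isclose(ld.voxel_size_mm, fd.voxel_size_mm):
        log.warning(
            "pair rejected: voxel sizes %.4g vs %.4g",
            ld.voxel_size_mm,
            fd.voxel_size_mm,
        )
        return False
    for name, v in (("low-dose", ld), ("full-dose", fd)):
        if not np.all(np.isfinite(v.values)) or np.any(v.values < 0):
            log.warning("pair rejected: %s volume has invalid values", name)
            return False
    return True
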