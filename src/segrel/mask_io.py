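"""Reading, writing and validating binary lesion masks and cohort manifests.

A segmentation study compares several delineations of the same CT scan, so
all masks belonging to one femur live on a single voxel grid: there is no
resampling or registration here, and overlap metrics downstream are exact
voxel-set operations.

Masks are exchanged as NIfTI-1 volumes (``.nii`` / ``.nii.gz``); voxel
spacing is taken from the header in millimetres.  A cohort is described by a
CSV manifest with one row per (femur, operator, session) mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OPERATORS = ("I", "II")
SESSIONS = (1, 2)
LESION_TYPES = ("osteolytic", "osteoblastic", "mixed")

MANIFEST_COLUMNS = ("femur_id", "operator", "session", "lesion_type", "mask_path")

#: Per-axis tolerance (mm) when deciding two masks share a grid.
SPACING_ATOL_MM = 1e-6


class MaskError(ValueError):
    """Invalid mask data or mask file."""


class GridMismatchError(ValueError):
    """Two masks do not share shape and spacing."""


class ManifestError(ValueError):
    """Structurally invalid cohort manifest."""


@dataclass(frozen=True)
class LabelMask:
    """One 3-D binary segmentation on a voxel grid with millimetre spacing.

    Parameters
    ----------
    voxels:
        Boolean occupancy array, ``True`` = lesion voxel.  Any array whose
        nonzero entries mark the lesion is accepted and binarized.
    spacing:
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all strictly positive.
        Anisotropic grids (e.g. 0.86 x 0.86 x 2.5 mm) are the norm for CT.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MaskError(f"voxels: expected 3-D volume, got {vox.ndim}-D")
        if vox.dtype != bool:
            vox = vox != 0
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise MaskError(f"spacing: expected 3 components, got {len(spacing)}")
        for axis, s in enumerate(spacing):
            if not np.isfinite(s) or s <= 0:
                raise MaskError(f"spacing: axis {axis} must be > 0, got {s}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        """Number of in-set (lesion) voxels."""
        return int(np.count_nonzero(self.voxels))

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass(frozen=True)
class SegmentationRecord:
    """One mask tagged with its place in the study design."""

    femur_id: str
    operator: str  # "I" | "II"
    session: int  # 1 | 2
    lesion_type: str  # osteolytic | osteoblastic | mixed
    mask: LabelMask

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ManifestError(
                f"operator: expected one of {OPERATORS}, got {self.operator!r}"
            )
        if self.session not in SESSIONS:
            raise ManifestError(
                f"session: expected one of {SESSIONS}, got {self.session!r}"
            )
        if self.lesion_type not in LESION_TYPES:
            raise ManifestError(
                f"lesion_type: expected one of {LESION_TYPES}, got {self.lesion_type!r}"
            )


def read_mask(path: str | Path) -> LabelMask:
    """Read a NIfTI volume as a binary :class:`LabelMask`.

    Any nonzero stored value maps to in-set; spacing is taken from the
    header ``pixdim`` in mm.  Raises :class:`MaskError` for non-3-D volumes
    or non-positive header spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise MaskError(f"{path}: expected 3-D volume, got {img.ndim}-D")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    for axis, s in enumerate(spacing):
        if not np.isfinite(s) or s <= 0:
            raise MaskError(f"{path}: header spacing axis {axis} must be > 0, got {s}")
    return LabelMask(voxels=data != 0, spacing=spacing)  # type: ignore[arg-type]


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as a NIfTI volume (uint8 0/1, spacing in the header).

    ``read_mask(write_mask(m))`` reproduces occupancy exactly and spacing to
    header (float32) precision.
    """
    path = Path(path)
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path


def validate_same_grid(a: LabelMask, b: LabelMask) -> None:
    """Check that two masks share shape and spacing (within 1e-6 mm per axis).

    Raises :class:`GridMismatchError` naming the offending axis.
    """
    if a.shape != b.shape:
        for axis, (da, db) in enumerate(zip(a.shape, b.shape)):
            if da != db:
                raise GridMismatchError(
                    f"shape mismatch on axis {axis}: {da} vs {db}"
                )
    for axis, (sa, sb) in enumerate(zip(a.spacing, b.spacing)):
        if abs(sa - sb) > SPACING_ATOL_MM:
            raise GridMismatchError(
                f"spacing mismatch on axis {axis}: {sa} mm vs {sb} mm"
            )


def _parse_session(value) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ManifestError(f"session: expected 1 or 2, got {value!r}") from None


def load_cohort(manifest: str | Path) -> list[SegmentationRecord]:
    """Load a cohort manifest CSV and its masks.

    The manifest must have columns ``femur_id, operator, session,
    lesion_type, mask_path`` (relative paths are resolved against the
    manifest's directory).  Validates that (femur_id, operator, session) is
    unique and that lesion_type is consistent within each femur.  Femurs
    missing any of the four (operator, session) combinations are kept in the
    returned list but reported with a warning; paired analyses exclude them.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, dtype={"femur_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")

    keys = list(zip(df["femur_id"], df["operator"], df["session"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ManifestError(f"duplicate (femur_id, operator, session) rows: {dupes}")

    for femur_id, group in df.groupby("femur_id"):
        types = set(group["lesion_type"])
        if len(types) > 1:
            raise ManifestError(
                f"femur {femur_id}: conflicting lesion_type values {sorted(types)}"
            )

    records = []
    for row in df.itertuples(index=False):
        mask_path = Path(row.mask_path)
        if not mask_path.is_absolute():
            mask_path = manifest.parent / mask_path
        records.append(
            SegmentationRecord(
                femur_id=str(row.femur_id),
                operator=str(row.operator),
                session=_parse_session(row.session),
                lesion_type=str(row.lesion_type),
                mask=read_mask(mask_path),
            )
        )

    for femur_id in incomplete_femurs(records):
        logger.warning(
            "femur %s: missing one or more of the 4 (operator, session) "
            "segmentations; excluded from paired analyses",
            femur_id,
        )
    return records


def complete_femurs(records: Iterable[SegmentationRecord]) -> list[str]:
    """Femur ids that have all four (operator, session) segmentations."""
    seen: dict[str, set[tuple[str, int]]] = {}
    order: list[str] = []
    for rec in records:
        if rec.femur_id not in seen:
            order.append(rec.femur_id)
        seen.setdefault(rec.femur_id, set()).add((rec.operator, rec.session))
    full = {(o, s) for o in OPERATORS for s in SESSIONS}
    return [fid for fid in order if seen[fid] == full]


def incomplete_femurs(records: Iterable[SegmentationRecord]) -> list[str]:
    """Femur ids missing at least one of the four segmentations."""
    records = list(records)
    complete = set(complete_femurs(records))
    order: list[str] = []
    for rec in records:
        if rec.femur_id not in complete and rec.femur_id not in order:
            order.append(rec.femur_id)
    return order
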