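"""Voxel-set overlap metrics between paired segmentations.

The agreement between two binary segmentations ``A`` and ``B`` on a shared
voxel grid is summarised by

* the 3-D Dice coefficient ``DC = 2|A n B| / (|A| + |B|)``, computed on
  voxel counts (voxel volume cancels in the ratio), and
* the non-overlapping segmentation volume ``|A| + |B| - 2|A n B|``, the
  volume of the symmetric difference, reported in cm^3.

Volumes are voxel counts times the (anisotropic) voxel volume; 1 cm^3 =
1000 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask_io import LabelMask, validate_same_grid


class EmptyPairError(ValueError):
    """Dice is undefined when both segmentations are empty."""


@dataclass(frozen=True)
class PairComparison:
    """All overlap quantities for one (A, B) segmentation pair.

    Invariants (exact, up to float rounding): ``dice = 2*volume_intersection
    / (volume_a + volume_b)``, ``non_overlap_volume = volume_a + volume_b -
    2*volume_intersection >= 0`` and ``mean_volume = (volume_a +
    volume_b)/2``; all volumes in cm^3.
    """

    dice: float
    volume_a: float
    volume_b: float
    volume_intersection: float
    non_overlap_volume: float
    mean_volume: float


def mask_volume(mask: LabelMask) -> float:
    """Physical volume of the in-set voxels, in cm^3."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def _counts(a: LabelMask, b: LabelMask) -> tuple[int, int, int]:
    validate_same_grid(a, b)
    na = a.n_voxels
    nb = b.n_voxels
    ni = int(np.count_nonzero(a.voxels & b.voxels))
    return na, nb, ni


def dice_coefficient(a: LabelMask, b: LabelMask) -> float:
    """3-D Dice coefficient ``2|A n B| / (|A| + |B|)`` in [0, 1].

    Symmetric in its arguments and independent of voxel spacing.  A pair
    with exactly one empty mask scores 0; a pair of two empty masks raises
    :class:`EmptyPairError` (the caller decides how to exclude it) — a
    silent 1.0 would inflate reliability summaries.
    """
    na, nb, ni = _counts(a, b)
    if na + nb == 0:
        raise EmptyPairError("Dice undefined for two empty segmentations")
    return 2.0 * ni / (na + nb)


def non_overlap_volume(a: LabelMask, b: LabelMask) -> float:
    """Volume of the symmetric difference ``|A| + |B| - 2|A n B|``, cm^3.

    Zero iff the masks are identical; defined for empty masks.
    """
    na, nb, ni = _counts(a, b)
    return (na + nb - 2 * ni) * a.voxel_volume_mm3 / 1000.0


def compare_pair(a: LabelMask, b: LabelMask) -> PairComparison:
    """Compute all :class:`PairComparison` fields for one mask pair."""
    na, nb, ni = _counts(a, b)
    if na + nb == 0:
        raise EmptyPairError("Dice undefined for two empty segmentations")
    vox_cm3 = a.voxel_volume_mm3 / 1000.0
    va = na * vox_cm3
    vb = nb * vox_cm3
    vi = ni * vox_cm3
    return PairComparison(
        dice=2.0 * ni / (na + nb),
        volume_a=va,
        volume_b=vb,
        volume_intersection=vi,
        non_overlap_volume=(na + nb - 2 * ni) * vox_cm3,
        mean_volume=(va + vb) / 2.0,
    )


#: 26-neighbourhood: all voxels sharing a face, edge or corner are connected.
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def count_components(mask: LabelMask) -> int:
    """Number of connected lesion components (26-connectivity).

    Used for lesion-count disagreement diagnostics only; the reliability
    analysis always merges all lesions of a femur before computing Dice, so
    the Dice values never depend on the connectivity convention.
    """
    _, n = ndimage.label(mask.voxels, structure=_STRUCTURE_26)
    return int(n)
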