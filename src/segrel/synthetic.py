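"""Synthetic segmentation-reliability cohorts with controlled agreement.

Real reliability studies of lesion segmentation rarely deposit their masks,
and no ground-truth lesion exists even in principle — only operators'
delineations.  This module generates a full synthetic study that mimics the
structure of such a cohort: femurs of three lesion types (osteolytic,
osteoblastic, mixed) with log-normal lesion volumes, segmented by two
operators in two sessions each, where the disagreement between paired masks
is *boundary* disagreement (spatially correlated displacement of the lesion
surface) calibrated so that each measured pair hits a prescribed Dice
target.

Generation model per femur
--------------------------
1. A hidden reference lesion — a randomly oriented, roughened ellipsoid of
   the sampled volume — is placed on the voxel grid.  It is a testing
   device recorded in the truth table and never consumed by the analysis.
2. Operator II's first-session mask is a mild perturbation of the
   reference (the anchor).
3. Operator II's second session is perturbed from the anchor to the
   intra-operator-II Dice target; both inter-operator masks are perturbed
   from the corresponding operator-II mask to the session's inter target.
   Each of those three measured pairs is therefore calibrated directly by
   bisecting the boundary-noise amplitude.
4. Operator I's two sessions share a common systematic deviation field
   (one operator's consistent interpretation of the lesion boundary), so
   the fourth measured pair — intra-operator I — emerges with an agreement
   between the inter level and the intra-II level.

Per-femur Dice targets are drawn around a global (or per-type) mean, with
an optional size effect: larger lesions get higher targets, reproducing the
common observation that big lesions are segmented more reproducibly.
Occasionally one mask of a femur is split in two by carving a thin gap,
emulating lesion-count disagreement between operators.

Everything is a pure function of :class:`SyntheticConfig`, including its
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .mask_io import (
    LESION_TYPES,
    LabelMask,
    SegmentationRecord,
    write_mask,
)
from .metrics import count_components, mask_volume, _STRUCTURE_26

logger = logging.getLogger(__name__)

_TYPE_ABBR = {"osteolytic": "lyt", "osteoblastic": "bla", "mixed": "mix"}

#: Margin (mm) around a lesion's bounding box in which perturbations live.
_PAD_MM = 18.0

#: Mask labels in generation order: (operator, session).
_MASK_KEYS = (("II", 1), ("II", 2), ("I", 1), ("I", 2))


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


class CalibrationError(RuntimeError):
    """Boundary-noise bisection could not reach the requested Dice."""

    def __init__(self, target: float, achieved: float):
        super().__init__(
            f"could not reach Dice target {target:.3f}; best achieved {achieved:.3f}"
        )
        self.target = target
        self.achieved = achieved


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a 54-femur cohort (19 osteolytic, 17 osteoblastic,
    18 mixed), 2 operators x 2 sessions, CT-like anisotropic voxels, and
    type-specific log-normal lesion-volume distributions.  Dice targets
    default to the moderate inter-operator agreement regime (~0.52) with an
    operator-II self-consistency advantage and a positive lesion-size
    effect.
    """

    n_per_type: tuple[int, int, int] = (19, 17, 18)
    grid_shape: tuple[int, int, int] = (96, 96, 160)
    spacing: tuple[float, float, float] = (0.98, 0.98, 3.0)
    #: per-type (mean, SD) of lesion volume in cm^3
    volume_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "osteolytic": (14.48, 13.83),
            "osteoblastic": (33.35, 32.42),
            "mixed": (41.2, 27.47),
        }
    )
    #: global or per-type mean inter-operator Dice target, in (0, 1]
    target_dice: float | Mapping[str, float] = 0.52
    #: SD of the femur-level Dice target around its mean
    dice_dispersion: float = 0.15
    #: SD of the per-pair jitter added on top of the femur-level target
    pair_jitter: float = 0.03
    #: operator II's intra-session Dice advantage over the inter level
    intra_boost: float = 0.19
    #: weight of operator I's shared (session-independent) deviation field
    operator_consistency: float = 0.85
    #: Dice of the anchor mask against the hidden reference
    anchor_dice: float = 0.93
    #: Dice-target shift per decade of lesion volume (0 disables size effect)
    size_dice_slope: float = 0.35
    #: volume (cm^3) at which the size effect is zero (the cohort's
    #: n-weighted geometric-mean volume, so the effect is centred)
    size_ref_volume_cm3: float = 20.0
    #: SD of the log-normal voxel-count jitter between paired masks
    volume_jitter: float = 0.10
    #: probability that one of a femur's four masks is split in two
    split_probability: float = 0.15
    #: correlation length (mm) of the boundary-noise fields
    smooth_mm: float = 5.0
    #: volume draws are redrawn above this cap so lesions fit the grid
    max_volume_cm3: float = 140.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_type) != 3 or any(n < 0 for n in self.n_per_type):
            raise ConfigError(f"n_per_type must be 3 counts >= 0, got {self.n_per_type}")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be positive, got {self.spacing}")
        if any(d < 8 for d in self.grid_shape):
            raise ConfigError(f"grid_shape too small: {self.grid_shape}")
        for lesion_type, (mean, sd) in self.volume_mean_sd.items():
            if mean <= 0:
                raise ConfigError(f"{lesion_type}: volume mean must be > 0, got {mean}")
            if sd < 0:
                raise ConfigError(f"{lesion_type}: volume SD must be >= 0, got {sd}")
        for lesion_type in LESION_TYPES:
            t = self.target_for(lesion_type)
            if not (0.0 < t <= 1.0):
                raise ConfigError(f"target_dice for {lesion_type} must be in (0, 1], got {t}")
        if not (0.0 <= self.operator_consistency <= 1.0):
            raise ConfigError("operator_consistency must be in [0, 1]")
        if not (0.0 <= self.split_probability <= 1.0):
            raise ConfigError("split_probability must be in [0, 1]")

    def target_for(self, lesion_type: str) -> float:
        if isinstance(self.target_dice, Mapping):
            return float(self.target_dice[lesion_type])
        return float(self.target_dice)


# ---------------------------------------------------------------------------
# volume sampling


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean and SD."""
    if mean <= 0:
        raise ConfigError(f"volume mean must be > 0, got {mean}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_lesion_volume(
    lesion_type: str, rng: np.random.Generator, config: SyntheticConfig
) -> float:
    """Draw one lesion volume (cm^3) from the type's log-normal distribution.

    A normal would produce negative volumes (the configured SDs are of the
    same order as the means); the log-normal is moment-matched so its mean
    and SD equal the configured ones.  Draws above ``max_volume_cm3`` are
    redrawn (then clipped) so the lesion fits the grid.
    """
    mean, sd = config.volume_mean_sd[lesion_type]
    mu, sigma = _lognormal_params(mean, sd)
    for _ in range(20):
        v = float(rng.lognormal(mu, sigma))
        if v <= config.max_volume_cm3:
            return v
    return config.max_volume_cm3


# ---------------------------------------------------------------------------
# geometry helpers


def _smooth_field(
    shape: tuple[int, ...],
    spacing: Sequence[float],
    rng: np.random.Generator,
    smooth_mm: float,
) -> np.ndarray:
    """Unit-variance Gaussian random field with ~smooth_mm correlation length."""
    noise = rng.standard_normal(shape).astype(np.float32)
    sigma_vox = [smooth_mm / s for s in spacing]
    fld = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = float(fld.std())
    if sd < 1e-12:
        return np.zeros(shape, dtype=np.float32)
    return (fld / sd).astype(np.float32)


def _signed_distance(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Signed Euclidean distance in mm, positive inside the mask."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return (inside - outside).astype(np.float32)


def _padded_bbox(
    mask: np.ndarray, pad_vox: Sequence[int]
) -> tuple[slice, slice, slice]:
    """Bounding box of the mask padded by pad_vox, clipped to the grid."""
    objs = ndimage.find_objects(mask.astype(np.uint8), max_label=1)
    if not objs or objs[0] is None:
        raise ValueError("empty mask has no bounding box")
    return tuple(
        slice(max(0, sl.start - p), min(dim, sl.stop + p))
        for sl, p, dim in zip(objs[0], pad_vox, mask.shape)
    )


def _dice_counts(a: np.ndarray, b: np.ndarray) -> float:
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        return 0.0
    ni = int(np.count_nonzero(a & b))
    return 2.0 * ni / (na + nb)


# ---------------------------------------------------------------------------
# reference lesion


def generate_reference_lesion(
    volume_cm3: float,
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    rng: np.random.Generator,
    roughness: float = 0.15,
    smooth_mm: float = 6.0,
    volume_tol: float = 0.05,
) -> LabelMask:
    """A connected, roughly ellipsoidal lesion of (almost) the requested volume.

    Axis ratios are drawn log-uniformly in [0.5, 2], orientation is a
    uniform random rotation, and the surface is roughened with smoothed
    noise.  The level-set threshold is bisected until the voxelised volume
    is within ``volume_tol`` (default 5%) of the request; the largest
    connected component is kept.

    Raises ``ValueError`` when the requested volume cannot fit in the grid.
    """
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be > 0, got {volume_cm3}")
    grid_shape = tuple(int(d) for d in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    voxvol = float(np.prod(spacing))

    r0 = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    q = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=3))
    q /= q.prod() ** (1.0 / 3.0)
    semi = r0 * q  # mm

    half_extent = np.array([d * s / 2.0 for d, s in zip(grid_shape, spacing)])
    margin = 4.0 + 2.0 * roughness * r0  # mm headroom for roughening
    limit = float(half_extent.min()) - margin
    if limit <= 0 or r0 >= limit:
        raise ValueError(
            f"volume {volume_cm3:.1f} cm^3 too large for grid "
            f"{grid_shape} at spacing {spacing}"
        )
    # squash overly long axes to the grid limit, preserving volume
    for _ in range(3):
        over = semi > limit
        if not over.any():
            break
        excess = semi[over].prod() / (limit ** over.sum())
        semi[over] = limit
        under = ~over
        if not under.any():
            raise ValueError(f"volume {volume_cm3:.1f} cm^3 too large for grid")
        semi[under] *= excess ** (1.0 / under.sum())

    # uniform random rotation via QR of a Gaussian matrix
    mat = rng.standard_normal((3, 3))
    rot, r_tri = np.linalg.qr(mat)
    rot *= np.sign(np.diag(r_tri))

    max_semi = float(semi.max())
    jitter = np.array(
        [
            rng.uniform(-1.0, 1.0) * max(0.0, h - max_semi - margin)
            for h in half_extent
        ]
    )
    center = half_extent + jitter  # mm from grid origin

    # local evaluation box
    extent = max_semi + margin
    lo = [max(0, int((c - extent) / s)) for c, s in zip(center, spacing)]
    hi = [min(d, int((c + extent) / s) + 2) for c, d, s in zip(center, grid_shape, spacing)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))

    axes_mm = [
        (np.arange(sl.start, sl.stop) + 0.5) * s - c
        for sl, s, c in zip(box, spacing, center)
    ]
    xg, yg, zg = np.meshgrid(*axes_mm, indexing="ij", copy=False)
    coords = np.stack([xg, yg, zg]).astype(np.float32)
    u = np.einsum("ij,jxyz->ixyz", rot.T.astype(np.float32), coords)
    level = np.sqrt(
        (u[0] / semi[0]) ** 2 + (u[1] / semi[1]) ** 2 + (u[2] / semi[2]) ** 2
    ) - 1.0

    target_n = volume_cm3 * 1000.0 / voxvol
    current_roughness = roughness
    for attempt in range(4):
        if current_roughness > 0:
            fld = _smooth_field(level.shape, spacing, rng, smooth_mm)
            rough_level = level + current_roughness * fld
        else:
            rough_level = level
        lo_c, hi_c = -0.95, 0.95
        for _ in range(45):
            mid = (lo_c + hi_c) / 2.0
            if np.count_nonzero(rough_level < mid) < target_n:
                lo_c = mid
            else:
                hi_c = mid
        sub = rough_level < ((lo_c + hi_c) / 2.0)
        labels, n = ndimage.label(sub, structure=_STRUCTURE_26)
        if n > 1:
            largest = np.argmax(ndimage.sum_labels(sub, labels, range(1, n + 1))) + 1
            sub = labels == largest
        achieved = np.count_nonzero(sub)
        if abs(achieved - target_n) <= volume_tol * target_n and achieved > 0:
            break
        current_roughness /= 2.0  # keep the blob connected and on-volume
    else:
        raise ValueError(
            f"could not realise volume {volume_cm3:.2f} cm^3 within "
            f"{volume_tol:.0%} on this grid"
        )

    voxels = np.zeros(grid_shape, dtype=bool)
    voxels[box] = sub
    return LabelMask(voxels=voxels, spacing=spacing)


# ---------------------------------------------------------------------------
# boundary perturbation


def _top_n_mask(values: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask selecting exactly the ``n`` largest entries of ``values``.

    Ties (frequent in discrete distance maps) are broken by flat index, so
    the result always has exactly ``n`` voxels.
    """
    n = int(np.clip(n, 1, values.size - 1))
    flat = values.ravel()
    idx = np.argpartition(flat, flat.size - n)[flat.size - n:]
    out = np.zeros(flat.size, dtype=bool)
    out[idx] = True
    return out.reshape(values.shape)


def _perturb_array(
    base: np.ndarray,
    spacing: Sequence[float],
    target: float,
    rng: np.random.Generator,
    field: np.ndarray | None = None,
    carve: np.ndarray | None = None,
    tol: float | None = None,
    smooth_mm: float = 5.0,
    max_amp_mm: float = 48.0,
    volume_jitter: float = 0.10,
) -> tuple[np.ndarray, float]:
    """Displace the lesion boundary until dice(base, out) hits target.

    Operates on a (sub)array that already contains the lesion with enough
    margin.  The candidate at noise amplitude ``a`` is the level set of
    ``signed_distance + a * field`` thresholded at the quantile that keeps
    the voxel count at the (jittered) base count: boundary disagreement
    decorrelates the surface without ballooning or shrinking the lesion,
    so cohort volume distributions survive chained perturbations.  The
    amplitude is bisected until ``dice(base, candidate)`` is within the
    tolerance of ``target``.

    ``field`` may be supplied to correlate perturbations across masks;
    ``carve`` is a voxel set removed from every candidate (a split gap),
    so the calibration accounts for it.
    """
    if not base.any():
        raise ValueError("cannot perturb an empty mask")
    if not (0.0 < target <= 1.0):
        raise ValueError(f"target Dice must be in (0, 1], got {target}")
    if tol is None:
        tol = 0.03 if target >= 0.3 else 0.05

    if target == 1.0 and carve is None:
        return base.copy(), 1.0

    dist = _signed_distance(base, spacing)
    if field is None:
        field = _smooth_field(base.shape, spacing, rng, smooth_mm)

    n_base = int(np.count_nonzero(base))
    # mean-one multiplicative volume noise between paired masks; a volume
    # ratio f caps the attainable Dice at 2f/(1+f), so clip the draw to the
    # range compatible with the target
    factor = float(np.exp(rng.normal(0.0, volume_jitter) - volume_jitter**2 / 2.0))
    bound = min(target + tol / 2.0, 0.999)
    bound = bound / (2.0 - bound)
    factor = float(np.clip(factor, bound, 1.0 / bound))
    n_target = max(1, int(round(n_base * factor)))

    best_err = np.inf
    best: tuple[np.ndarray, float] | None = None

    def measure(amp: float) -> float:
        nonlocal best_err, best
        if amp == 0.0:
            cand = _top_n_mask(dist, n_target)
        else:
            cand = _top_n_mask(dist + amp * field, n_target)
        if carve is not None:
            cand = cand & ~carve
        d = _dice_counts(base, cand)
        err = abs(d - target)
        if err < best_err:
            best_err = err
            best = (cand, d)
        return d

    if measure(0.0) <= target:
        # volume jitter / carve alone reaches (or undershoots) the target
        cand, d = best  # type: ignore[misc]
        if best_err <= tol:
            return cand, d
        raise CalibrationError(target, d)

    hi = float(min(spacing))
    while measure(hi) > target and hi < max_amp_mm:
        hi = min(hi * 2.0, max_amp_mm)
    lo = 0.0
    for _ in range(36):
        mid = (lo + hi) / 2.0
        d = measure(mid)
        if best_err <= tol / 2.0 or hi - lo < 1e-4:
            break
        if d > target:
            lo = mid
        else:
            hi = mid
    cand, d = best  # type: ignore[misc]
    if best_err > tol:
        raise CalibrationError(target, d)
    return cand, d


def perturb_to_target_dice(
    reference: LabelMask,
    target: float,
    rng: np.random.Generator,
    tol: float | None = None,
    smooth_mm: float = 5.0,
    max_amp_mm: float | None = None,
) -> LabelMask:
    """Perturb a mask's boundary so its Dice against the original hits ``target``.

    The boundary is displaced by a spatially correlated noise field (not
    i.i.d. voxel flips): operator disagreement on real scans is coherent
    boundary disagreement.  The noise amplitude is bisected until
    ``dice(reference, result)`` is within the tolerance (0.03, or 0.05 for
    targets below 0.3) of ``target``.  ``target=1`` returns an identical
    mask.  Raises :class:`CalibrationError` (carrying the best achieved
    value) for unattainable targets.
    """
    if reference.is_empty():
        raise ValueError("cannot perturb an empty reference mask")
    if target == 1.0:
        return LabelMask(voxels=reference.voxels.copy(), spacing=reference.spacing)
    if max_amp_mm is None:
        max_amp_mm = 48.0
    pad = [int(np.ceil(_PAD_MM / s)) + 2 for s in reference.spacing]
    box = _padded_bbox(reference.voxels, pad)
    sub = reference.voxels[box]
    out_sub, _ = _perturb_array(
        sub, reference.spacing, target, rng, tol=tol,
        smooth_mm=smooth_mm, max_amp_mm=max_amp_mm,
    )
    voxels = np.zeros(reference.shape, dtype=bool)
    voxels[box] = out_sub
    return LabelMask(voxels=voxels, spacing=reference.spacing)


# ---------------------------------------------------------------------------
# lesion splitting


def _gap_slab(
    mask: np.ndarray,
    spacing: Sequence[float],
    rng: np.random.Generator,
    offset_frac: float = 0.25,
) -> np.ndarray:
    """A thin, in-plane-normal slab through the mask's centroid region.

    The slab is just thick enough to break 26-connectivity across it for
    the given (anisotropic) spacing.
    """
    centroid = np.array(ndimage.center_of_mass(mask))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    normal = np.array([np.cos(phi), np.sin(phi), 0.0])  # in-plane: thin slab
    half_mm = 0.55 * sum(abs(n) * s for n, s in zip(normal, spacing))

    extents = [np.arange(d) - c for d, c in zip(mask.shape, centroid)]
    xg, yg, zg = np.meshgrid(*extents, indexing="ij", copy=False)
    proj = (
        normal[0] * xg * spacing[0]
        + normal[1] * yg * spacing[1]
        + normal[2] * zg * spacing[2]
    )
    # random offset from the centroid so the cut is not always central
    span = np.abs(proj[mask]).max() if mask.any() else 0.0
    proj = proj - rng.uniform(-offset_frac, offset_frac) * span
    return np.abs(proj) < half_mm


def split_lesion(
    mask: LabelMask,
    rng: np.random.Generator,
    min_voxels: int = 100,
    max_removed_frac: float = 0.10,
    max_tries: int = 20,
) -> LabelMask:
    """Carve a thin gap so the largest component splits into two.

    Emulates one operator seeing two lesions where the other sees one.  The
    gap removes less than ``max_removed_frac`` of the component's voxels and
    increases the connected-component count by exactly one.  Raises
    ``ValueError`` when the largest component is below ``min_voxels`` or no
    admissible cut is found.
    """
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTURE_26)
    if n == 0:
        raise ValueError("cannot split an empty mask")
    sizes = ndimage.sum_labels(mask.voxels, labels, range(1, n + 1))
    comp_label = int(np.argmax(sizes)) + 1
    comp = labels == comp_label
    comp_size = int(sizes[comp_label - 1])
    if comp_size < min_voxels:
        raise ValueError(
            f"largest component has {comp_size} voxels; need >= {min_voxels} to split"
        )

    for _ in range(max_tries):
        slab = _gap_slab(comp, mask.spacing, rng)
        removed = comp & slab
        n_removed = int(np.count_nonzero(removed))
        if n_removed == 0 or n_removed > max_removed_frac * comp_size:
            continue
        candidate = mask.voxels & ~removed
        new_mask = LabelMask(voxels=candidate, spacing=mask.spacing)
        if count_components(new_mask) == n + 1:
            return new_mask
    raise ValueError("no admissible split found (component too small or too thin)")


# ---------------------------------------------------------------------------
# cohort generation


def _clip_target(t: float, lo: float = 0.20, hi: float = 0.96) -> float:
    return float(np.clip(t, lo, hi))


def _generate_femur(
    femur_id: str,
    lesion_type: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, int], LabelMask], dict]:
    """Generate the four observed masks and the truth row for one femur."""
    volume = sample_lesion_volume(lesion_type, rng, config)
    reference = generate_reference_lesion(
        volume, config.grid_shape, config.spacing, rng
    )

    # femur-level inter-operator Dice target, with size effect
    size_term = config.size_dice_slope * np.log10(
        mask_volume(reference) / config.size_ref_volume_cm3
    )
    base = _clip_target(
        config.target_for(lesion_type)
        + size_term
        + rng.normal(0.0, config.dice_dispersion)
    )
    t_inter1 = _clip_target(base + rng.normal(0.0, config.pair_jitter))
    t_inter2 = _clip_target(base + rng.normal(0.0, config.pair_jitter))
    t_intra2 = _clip_target(
        base + config.intra_boost + rng.normal(0.0, config.pair_jitter), hi=0.97
    )

    # working region shared by every perturbation of this femur
    pad = [int(np.ceil(_PAD_MM / s)) + 2 for s in config.spacing]
    box = _padded_bbox(reference.voxels, pad)
    ref_sub = reference.voxels[box]
    sub_shape = ref_sub.shape
    spacing = config.spacing

    # optional lesion-count disagreement: one mask gets a carved gap
    victim: tuple[str, int] | None = None
    carve = None
    if rng.random() < config.split_probability:
        victim = _MASK_KEYS[rng.integers(0, len(_MASK_KEYS))]
        carve = _gap_slab(ref_sub, spacing, rng)

    def carve_for(key: tuple[str, int]):
        return carve if victim == key else None

    def perturb(base_sub, target, field=None, key=None):
        gap = carve_for(key)
        if gap is not None:
            # a carved candidate cannot reach very high Dice; the split is
            # itself disagreement, so cap that pair's target
            target = min(target, 0.90)
        return _perturb_array(
            base_sub, spacing, target, rng,
            field=field, carve=gap, smooth_mm=config.smooth_mm,
            volume_jitter=config.volume_jitter,
        )

    # operator II: anchor + self-consistent repeat (calibrated pair).
    # The anchor-vs-reference pair is never measured, so a split gap on the
    # anchor is carved after calibration.
    m_ii1, _ = _perturb_array(
        ref_sub, spacing, config.anchor_dice, rng,
        smooth_mm=config.smooth_mm, volume_jitter=config.volume_jitter,
    )
    if victim == ("II", 1):
        m_ii1 = m_ii1 & ~carve
    m_ii2, _ = perturb(m_ii1, t_intra2, key=("II", 2))

    # operator I: shared systematic deviation field across sessions
    alpha = config.operator_consistency
    beta = float(np.sqrt(max(0.0, 1.0 - alpha**2)))
    shared = _smooth_field(sub_shape, spacing, rng, config.smooth_mm)
    f1 = alpha * shared + beta * _smooth_field(sub_shape, spacing, rng, config.smooth_mm)
    f2 = alpha * shared + beta * _smooth_field(sub_shape, spacing, rng, config.smooth_mm)
    m_i1, _ = perturb(m_ii1, t_inter1, field=f1, key=("I", 1))
    m_i2, _ = perturb(m_ii2, t_inter2, field=f2, key=("I", 2))

    subs = {("II", 1): m_ii1, ("II", 2): m_ii2, ("I", 1): m_i1, ("I", 2): m_i2}
    masks = {}
    for key, sub in subs.items():
        voxels = np.zeros(config.grid_shape, dtype=bool)
        voxels[box] = sub
        masks[key] = LabelMask(voxels=voxels, spacing=spacing)

    truth = {
        "femur_id": femur_id,
        "lesion_type": lesion_type,
        "volume_request_cm3": volume,
        "volume_reference_cm3": mask_volume(reference),
        "target_inter1": t_inter1,
        "target_inter2": t_inter2,
        "target_intra_ii": t_intra2,
        "achieved_inter1": _dice_counts(m_i1, m_ii1),
        "achieved_inter2": _dice_counts(m_i2, m_ii2),
        "achieved_intra_i": _dice_counts(m_i1, m_i2),
        "achieved_intra_ii": _dice_counts(m_ii1, m_ii2),
        "split_mask": f"{victim[0]}@{victim[1]}" if victim else "",
    }
    return masks, truth


def generate_cohort_records(
    config: SyntheticConfig,
) -> tuple[list[SegmentationRecord], pd.DataFrame]:
    """Generate a full cohort in memory.

    Returns the segmentation records (4 per femur) and the truth table
    recording every generation parameter and the achieved pair Dice values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SegmentationRecord] = []
    truth_rows: list[dict] = []
    for lesion_type, count in zip(LESION_TYPES, config.n_per_type):
        abbr = _TYPE_ABBR[lesion_type]
        for i in range(count):
            femur_id = f"{abbr}{i + 1:02d}"
            masks, truth = _generate_femur(femur_id, lesion_type, config, rng)
            truth_rows.append(truth)
            for (operator, session), mask in masks.items():
                records.append(
                    SegmentationRecord(
                        femur_id=femur_id,
                        operator=operator,
                        session=session,
                        lesion_type=lesion_type,
                        mask=mask,
                    )
                )
    return records, pd.DataFrame(truth_rows)


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path]:
    """Generate a cohort and write it to disk.

    Writes one NIfTI mask per (femur, operator, session), a ``manifest.csv``
    in the cohort-manifest dialect, a ``truth.csv`` with the generation
    parameters, and a ``config.yaml`` echo.  Returns (manifest path, truth
    path).
    """
    out_dir = Path(out_dir)
    masks_dir = out_dir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)

    records, truth = generate_cohort_records(config)
    manifest_rows = []
    for rec in records:
        fname = f"{rec.femur_id}_op{rec.operator}_s{rec.session}.nii.gz"
        write_mask(rec.mask, masks_dir / fname)
        manifest_rows.append(
            {
                "femur_id": rec.femur_id,
                "operator": rec.operator,
                "session": rec.session,
                "lesion_type": rec.lesion_type,
                "mask_path": f"masks/{fname}",
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)

    cfg = asdict(config)
    cfg["volume_mean_sd"] = {k: list(v) for k, v in config.volume_mean_sd.items()}
    if isinstance(config.target_dice, Mapping):
        cfg["target_dice"] = dict(config.target_dice)
    for key in ("n_per_type", "grid_shape", "spacing"):
        cfg[key] = list(cfg[key])
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return manifest_path, truth_path
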