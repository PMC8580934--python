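"""Cohort-level reliability analysis of paired lesion segmentations.

A reliability study in which two operators each segment every femur twice
yields four comparison sets per femur:

* ``inter@1`` — operator I vs operator II, first session,
* ``inter@2`` — operator I vs operator II, second session,
* ``intra@I`` — operator I, session 1 vs session 2,
* ``intra@II`` — operator II, session 1 vs session 2.

All lesions of a femur are merged into one voxel set before comparison,
because operators need not agree on the number of lesions (one operator's
single large lesion may be another's two smaller ones); Dice on the merged
sets is insensitive to that split/merge disagreement.

The module builds a tidy per-femur table of :class:`~segrel.metrics.PairComparison`
rows, summarises Dice and segmentation volume by lesion type and by lesion
size (a 60 cm^3 threshold separates large from small lesions), computes the
fraction of femurs with good agreement (Dice strictly above 0.7), and tests
for Dice differences between lesion types with the Kruskal-Wallis rank test.

Summary statistics use the sample standard deviation (n-1 denominator).
Values exactly at a threshold fall on the lower / "not good" side, matching
the strict inequalities of the reliability conventions above.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mask_io import LabelMask, SegmentationRecord, complete_femurs, validate_same_grid
from .metrics import EmptyPairError, compare_pair

logger = logging.getLogger(__name__)

#: The four comparison sets; inter@s pairs (op I, session s) with
#: (op II, session s), intra@o pairs (op o, session 1) with (op o, session 2).
COMPARISON_LABELS = ("inter@1", "inter@2", "intra@I", "intra@II")

#: The two inter-operator sessions are the primary hypothesis tests
#: (Dice differences between lesion types).
PRIMARY_TEST_LABELS = ("inter@1", "inter@2")

DEFAULT_DC_THRESHOLD = 0.7
DEFAULT_SIZE_THRESHOLD_CM3 = 60.0

_TABLE_COLUMNS = [
    "femur_id",
    "lesion_type",
    "kind",
    "label",
    "dice",
    "volume_a",
    "volume_b",
    "volume_intersection",
    "non_overlap_volume",
    "mean_volume",
]


def merge_lesions_per_femur(masks: Sequence[LabelMask]) -> LabelMask:
    """Voxelwise union of all lesion masks of one (femur, operator, session).

    All masks must share one grid.
    """
    if not masks:
        raise ValueError("no masks to merge")
    first = masks[0]
    union = first.voxels.copy()
    for other in masks[1:]:
        validate_same_grid(first, other)
        union |= other.voxels
    return LabelMask(voxels=union, spacing=first.spacing)


def _pairings() -> list[tuple[str, str, tuple[tuple[str, int], tuple[str, int]]]]:
    return [
        ("inter", "inter@1", (("I", 1), ("II", 1))),
        ("inter", "inter@2", (("I", 2), ("II", 2))),
        ("intra", "intra@I", (("I", 1), ("I", 2))),
        ("intra", "intra@II", (("II", 1), ("II", 2))),
    ]


def assemble_study_table(records: Iterable[SegmentationRecord]) -> pd.DataFrame:
    """Build the per-femur comparison table (one row per femur x comparison set).

    Only femurs with all four (operator, session) segmentations contribute;
    pairs in which both masks are empty are excluded with a logged reason.
    """
    records = list(records)
    by_key = {(r.femur_id, r.operator, r.session): r for r in records}
    types = {r.femur_id: r.lesion_type for r in records}

    rows = []
    for femur_id in complete_femurs(records):
        for kind, label, ((op_a, ses_a), (op_b, ses_b)) in _pairings():
            rec_a = by_key[(femur_id, op_a, ses_a)]
            rec_b = by_key[(femur_id, op_b, ses_b)]
            try:
                pc = compare_pair(rec_a.mask, rec_b.mask)
            except EmptyPairError:
                logger.warning(
                    "femur %s, %s: both segmentations empty; pair excluded",
                    femur_id,
                    label,
                )
                continue
            rows.append(
                {
                    "femur_id": femur_id,
                    "lesion_type": types[femur_id],
                    "kind": kind,
                    "label": label,
                    "dice": pc.dice,
                    "volume_a": pc.volume_a,
                    "volume_b": pc.volume_b,
                    "volume_intersection": pc.volume_intersection,
                    "non_overlap_volume": pc.non_overlap_volume,
                    "mean_volume": pc.mean_volume,
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def mean_pair_volume(row: Mapping[str, float]) -> float:
    """Mean of the two paired segmentation volumes, cm^3.

    For inter-operator rows this averages the two operators' volumes within
    a session; for intra-operator rows, one operator's two sessions.  Which
    two masks are paired was fixed when the study table was assembled.
    """
    return (row["volume_a"] + row["volume_b"]) / 2.0


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else float("nan")
    return mean, sd


def summarize_by_type(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) Dice and mean (SD) pair volume per comparison set and lesion type."""
    if table.empty:
        raise ValueError("empty study table")
    rows = []
    for label in COMPARISON_LABELS:
        for lesion_type in sorted(table["lesion_type"].unique()):
            sub = table[(table["label"] == label) & (table["lesion_type"] == lesion_type)]
            if sub.empty:
                continue  # absent cell, not zero
            mean_dc, sd_dc = _mean_sd(sub["dice"].to_numpy())
            mean_vol, sd_vol = _mean_sd(sub["mean_volume"].to_numpy())
            rows.append(
                {
                    "label": label,
                    "lesion_type": lesion_type,
                    "mean_dc": mean_dc,
                    "sd_dc": sd_dc,
                    "mean_volume": mean_vol,
                    "sd_volume": sd_vol,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def overall_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Overall mean (SD) Dice and non-overlap volume per comparison set."""
    if table.empty:
        raise ValueError("empty study table")
    rows = []
    for label in COMPARISON_LABELS:
        sub = table[table["label"] == label]
        if sub.empty:
            continue
        mean_dc, sd_dc = _mean_sd(sub["dice"].to_numpy())
        mean_nov, sd_nov = _mean_sd(sub["non_overlap_volume"].to_numpy())
        rows.append(
            {
                "label": label,
                "mean_dc": mean_dc,
                "sd_dc": sd_dc,
                "mean_non_overlap_volume": mean_nov,
                "sd_non_overlap_volume": sd_nov,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """n-weighted mean of group means.

    Because lesion-type groups partition the cohort, the n-weighted mean of
    per-type mean Dice equals the overall mean Dice exactly.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or means.size == 0:
        raise ValueError("means and ns must be equal-length, non-empty")
    if np.any(ns < 0) or ns.sum() == 0:
        raise ValueError("group sizes must be >= 0 with positive total")
    return float(np.sum(means * ns) / ns.sum())


def good_dc_fraction(dcs: Sequence[float], threshold: float = DEFAULT_DC_THRESHOLD) -> float:
    """Fraction of Dice values strictly above ``threshold``.

    A value exactly at the threshold does not count as good agreement.
    """
    dcs = np.asarray(list(dcs), dtype=float)
    if dcs.size == 0:
        raise ValueError("good_dc_fraction of an empty list")
    return float(np.mean(dcs > threshold))


def split_by_size(
    table: pd.DataFrame,
    threshold: float = DEFAULT_SIZE_THRESHOLD_CM3,
    dc_threshold: float = DEFAULT_DC_THRESHOLD,
) -> pd.DataFrame:
    """Dice summaries for large vs small lesions, pooled inter and intra rows.

    Rows whose mean pair volume is strictly above ``threshold`` form the
    large stratum; all others (including exactly-at-threshold) the small
    stratum.  Inter-operator rows (both sessions) and intra-operator rows
    (both operators) are pooled separately.  Empty strata are absent from
    the result rather than reported as zero.
    """
    if table.empty:
        raise ValueError("empty study table")
    rows = []
    for kind in ("inter", "intra"):
        pool = table[table["kind"] == kind]
        large = pool[pool["mean_volume"] > threshold]
        small = pool[pool["mean_volume"] <= threshold]
        for stratum, sub in (("large", large), ("small", small)):
            if sub.empty:
                continue
            mean_dc, sd_dc = _mean_sd(sub["dice"].to_numpy())
            rows.append(
                {
                    "kind": kind,
                    "stratum": stratum,
                    "mean_dc": mean_dc,
                    "sd_dc": sd_dc,
                    "good_dc_fraction": good_dc_fraction(sub["dice"], dc_threshold),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value for >= 2 groups.

    The degenerate all-tied input, for which the tie correction divides by
    zero, is defined as no evidence of a difference: H = 0, p = 1 (logged).
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    if np.all(pooled == pooled[0]):
        logger.warning("Kruskal-Wallis: all values identical; H = 0, p = 1")
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def kruskal_by_type(
    table: pd.DataFrame, labels: Sequence[str] = COMPARISON_LABELS
) -> pd.DataFrame:
    """Kruskal-Wallis test of Dice across lesion types, per comparison set.

    The two inter-operator sessions are flagged ``primary``: they carry the
    study question of whether lesion type affects segmentation agreement.
    """
    rows = []
    for label in labels:
        sub = table[table["label"] == label]
        groups = [
            g["dice"].to_numpy()
            for _, g in sub.groupby("lesion_type")
            if len(g) > 0
        ]
        if len(groups) < 2:
            continue
        h, p = kruskal_wallis(groups)
        rows.append(
            {
                "label": label,
                "H": h,
                "p_value": p,
                "primary": label in PRIMARY_TEST_LABELS,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryReport:
    """All cohort-level summaries, ready for serialisation."""

    per_type: pd.DataFrame
    overall: pd.DataFrame
    per_size: pd.DataFrame
    kruskal: pd.DataFrame
    n_femurs: int
    dc_threshold: float = DEFAULT_DC_THRESHOLD
    size_threshold: float = DEFAULT_SIZE_THRESHOLD_CM3


def summarize(
    table: pd.DataFrame,
    dc_threshold: float = DEFAULT_DC_THRESHOLD,
    size_threshold: float = DEFAULT_SIZE_THRESHOLD_CM3,
) -> SummaryReport:
    """Compute all summaries for an assembled study table."""
    return SummaryReport(
        per_type=summarize_by_type(table),
        overall=overall_summary(table),
        per_size=split_by_size(table, threshold=size_threshold, dc_threshold=dc_threshold),
        kruskal=kruskal_by_type(table),
        n_femurs=table["femur_id"].nunique(),
        dc_threshold=dc_threshold,
        size_threshold=size_threshold,
    )


def _frame_records(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in rec.items()})
    return out


def _round_tree(obj, ndigits: int = 2):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_tree(v, ndigits) for v in obj]
    return obj


def report_to_dict(report: SummaryReport) -> dict:
    """Full-precision JSON-serialisable view of a :class:`SummaryReport`."""
    return {
        "n_femurs": report.n_femurs,
        "dc_threshold": report.dc_threshold,
        "size_threshold_cm3": report.size_threshold,
        "per_type": _frame_records(report.per_type),
        "overall": _frame_records(report.overall),
        "per_size": _frame_records(report.per_size),
        "kruskal": _frame_records(report.kruskal),
    }


def write_report(
    report: SummaryReport, out_dir: str | Path, table: pd.DataFrame | None = None
) -> dict[str, Path]:
    """Write summary CSVs and a JSON report to ``out_dir``.

    CSV cells for unavailable statistics are rendered ``NA``.  ``report.json``
    holds all numbers at full precision plus a 2-decimal presentation copy.
    If the study ``table`` is given it is written as ``per_femur.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, df in (
        ("per_type", report.per_type),
        ("per_size", report.per_size),
        ("overall", report.overall),
    ):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="NA")
        paths[name] = path
    if table is not None:
        path = out_dir / "per_femur.csv"
        table.to_csv(path, index=False, na_rep="NA")
        paths["per_femur"] = path

    payload = report_to_dict(report)
    doc = {"full_precision": payload, "rounded": _round_tree(payload)}
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(doc, indent=2))
    paths["report"] = json_path
    return paths
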