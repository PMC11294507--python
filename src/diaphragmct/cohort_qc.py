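"""Cohort-level QC of diaphragm-index values.

Mirrors the quality-control workflow used around the index at cohort
scale: per-group summary statistics (mean ± SD, range) and the
1.5 × IQR rule that selects segmentations for visual inspection.
Inspection itself is manual; the minor/major defect taxonomy is exposed
as a recordable label vocabulary so human-assigned labels can be
tabulated alongside the flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ParameterError


class DefectLabel(str, Enum):
    """Visual-inspection outcome for one segmentation.

    minor: absence of less than half of one or both hemidiaphragm domes,
    and/or a small spurious inclusion. major: absence of more than half
    of one or both domes, and/or a significant spurious inclusion.
    """

    none = "none"
    minor = "minor"
    major = "major"


@dataclass
class CohortRecord:
    subject_id: str
    group: str
    index_value: float

    def __post_init__(self):
        if not self.group:
            raise ParameterError("group label must be non-empty")
        if not self.index_value > 0:
            raise ParameterError("diaphragm index must be > 0")


@dataclass
class OutlierFlag:
    subject_id: str
    group: str
    index_value: float
    is_outlier: bool
    lower: float
    upper: float


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"subject_id", "group", "index_value"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [(r.subject_id, r.group, r.index_value) for r in records],
            columns=["subject_id", "group", "index_value"],
        )
    if df.empty:
        raise ParameterError("cohort is empty")
    return df


def flag_outliers(records, min_group_size: int = 4) -> list[OutlierFlag]:
    """Flag per-group 1.5 × IQR outliers.

    Within each group, Q1 and Q3 are computed by linear interpolation
    between order statistics; values outside
    ``[Q1 - 1.5 * IQR, Q3 + 1.5 * IQR]`` are flagged. Groups smaller
    than ``min_group_size`` are skipped with a warning (quartiles are
    meaningless there).
    """
    df = _as_frame(records)
    flags: list[OutlierFlag] = []
    for group, sub in df.groupby("group", sort=True):
        if len(sub) < min_group_size:
            warnings.warn(
                f"group {group!r} has only {len(sub)} records "
                f"(< {min_group_size}); skipped for outlier flagging",
                stacklevel=2,
            )
            continue
        values = sub["index_value"].to_numpy(dtype=float)
        q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for _, row in sub.iterrows():
            v = float(row["index_value"])
            flags.append(OutlierFlag(
                subject_id=str(row["subject_id"]), group=str(group),
                index_value=v, is_outlier=bool(v < lower or v > upper),
                lower=float(lower), upper=float(upper),
            ))
    return flags


def summarize_groups(records) -> pd.DataFrame:
    """Per-group n, mean, SD (n-1 denominator), min and max.

    Groups are ordered by label; SD is NaN for singleton groups.
    """
    df = _as_frame(records)
    out = (df.groupby("group", sort=True)["index_value"]
             .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1),
                  min="min", max="max")
             .reset_index())
    out["n"] = out["n"].astype(int)
    return out


def tabulate_defects(labels) -> pd.DataFrame:
    """Rates of human-assigned defect labels over inspected records.

    ``labels`` is an iterable of DefectLabel (or their string values);
    returns counts and percentages per category.
    """
    vals = [DefectLabel(v).value for v in labels]
    if not vals:
        raise ParameterError("no defect labels supplied")
    counts = pd.Series(vals).value_counts()
    rows = []
    for cat in DefectLabel:
        c = int(counts.get(cat.value, 0))
        rows.append({"label": cat.value, "count": c,
                     "percent": 100.0 * c / len(vals)})
    return pd.DataFrame(rows)


def flags_to_frame(flags: list[OutlierFlag]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in flags])
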