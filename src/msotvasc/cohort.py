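"""Group-comparison tables: median (IQR) descriptives and Mann-Whitney U.

Subjects belong to a healthy-control (HC) or patient (SSc) group; SSc
subjects may additionally carry an ischaemia-history subgroup label. The
HC-vs-SSc contrast is tested two-sided with the Mann-Whitney U test (exact
rank-permutation null for small tie-free samples, normal approximation with
tie and continuity correction otherwise). Subgroup rows report descriptives
only — no formal test, because the subgroups are too small.

Quantiles use linear interpolation between order statistics. No multiple-
testing correction is applied (documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import mean_over_fingers

__all__ = [
    "SubjectRecord",
    "GroupComparison",
    "median_iqr",
    "mann_whitney_u",
    "build_comparison_table",
    "comparisons_to_frame",
    "format_comparison_table",
]

logger = logging.getLogger(__name__)

GROUPS = ("HC", "SSc")
SUBGROUPS = ("none", "SSc_isch", "SSc_no_isch")

#: exact Mann-Whitney is used in "auto" mode up to this per-group size
EXACT_MODE_MAX_N = 8


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    ``mode`` is "exact" (full rank-permutation null; requires no ties),
    "asymptotic" (normal approximation with tie and continuity correction),
    or "auto" (exact when min(n) <= 8 and the pooled sample is tie-free).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = (
            "exact"
            if min(a.size, b.size) <= EXACT_MODE_MAX_N and not _has_ties(a, b)
            else "asymptotic"
        )
    if mode not in ("exact", "asymptotic"):
        raise ValueError("mode must be 'exact', 'asymptotic' or 'auto'")
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method=mode,
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class SubjectRecord:
    """One participant: group labels plus per-finger measurements.

    ``fingers`` maps a metric name to up to 8 per-finger values; missing
    fingers are NaN/None. ``occlusion`` optionally maps occlusion metric
    names (baseline/min/max sO2) to scalars.
    """

    subject_id: str
    group: str
    subgroup: str = "none"
    fingers: dict[str, list[float | None]] = field(default_factory=dict)
    occlusion: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"subgroup must be one of {SUBGROUPS}")
        if self.subgroup != "none" and self.group != "SSc":
            raise ValueError("only SSc subjects carry an ischaemia subgroup")

    def metric_names(self) -> list[str]:
        return sorted(set(self.fingers) | set(self.occlusion))

    def values_for(self, metric: str, level: str) -> list[float]:
        """Per-subject observations of one metric.

        ``level`` is "mean8" (mean over present fingers, one value per
        subject) or "finger" (all present finger values). Occlusion metrics
        are single-valued at either level.
        """
        if metric in self.occlusion:
            v = self.occlusion[metric]
            return [float(v)] if np.isfinite(v) else []
        if metric not in self.fingers:
            return []
        vals = self.fingers[metric]
        present = [
            float(v) for v in vals if v is not None and np.isfinite(v)
        ]
        if not present:
            return []
        if level == "mean8":
            return [mean_over_fingers(vals)]
        if level == "finger":
            return present
        raise ValueError("level must be 'mean8' or 'finger'")


@dataclass
class GroupComparison:
    """One table row: descriptives for two groups plus an optional test."""

    metric: str
    level: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    u_statistic: float | None = None
    p_value: float | None = None
    test_mode: str | None = None


def _collect(
    records: Sequence[SubjectRecord], metric: str, level: str, selector
) -> np.ndarray:
    out: list[float] = []
    for rec in records:
        if selector(rec):
            out.extend(rec.values_for(metric, level))
    return np.asarray(out, dtype=np.float64)


def build_comparison_table(
    records: Sequence[SubjectRecord],
    metric: str,
    level: str = "mean8",
    mode: str = "auto",
) -> list[GroupComparison]:
    """HC-vs-SSc row (with U test) plus a descriptive-only subgroup row.

    The subgroup row (SSc with vs without ischaemia history) carries
    medians and IQRs but null test fields.
    """
    available = sorted({m for r in records for m in r.metric_names()})
    if metric not in available:
        raise KeyError(
            f"unknown metric {metric!r}; available metrics: {available}"
        )

    hc = _collect(records, metric, level, lambda r: r.group == "HC")
    ssc = _collect(records, metric, level, lambda r: r.group == "SSc")
    if hc.size == 0 or ssc.size == 0:
        raise ValueError("need at least one HC and one SSc observation")
    u, p = mann_whitney_u(hc, ssc, mode=mode)
    med_hc, q1_hc, q3_hc = median_iqr(hc)
    med_ssc, q1_ssc, q3_ssc = median_iqr(ssc)
    rows = [
        GroupComparison(
            metric=metric,
            level=level,
            group_a="HC",
            group_b="SSc",
            n_a=int(hc.size),
            n_b=int(ssc.size),
            median_a=med_hc,
            q1_a=q1_hc,
            q3_a=q3_hc,
            median_b=med_ssc,
            q1_b=q1_ssc,
            q3_b=q3_ssc,
            u_statistic=u,
            p_value=p,
            test_mode=mode,
        )
    ]

    isch = _collect(
        records, metric, level, lambda r: r.subgroup == "SSc_isch"
    )
    no_isch = _collect(
        records, metric, level, lambda r: r.subgroup == "SSc_no_isch"
    )
    if isch.size and no_isch.size:
        med_i, q1_i, q3_i = median_iqr(isch)
        med_n, q1_n, q3_n = median_iqr(no_isch)
        rows.append(
            GroupComparison(
                metric=metric,
                level=level,
                group_a="SSc_isch",
                group_b="SSc_no_isch",
                n_a=int(isch.size),
                n_b=int(no_isch.size),
                median_a=med_i,
                q1_a=q1_i,
                q3_a=q3_i,
                median_b=med_n,
                q1_b=q1_n,
                q3_b=q3_n,
            )
        )
    return rows


def comparisons_to_frame(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy DataFrame of comparison rows (machine-precision values)."""
    return pd.DataFrame([vars(r) for r in rows])


def _fmt(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def format_comparison_table(
    rows: Sequence[GroupComparison], decimals: int = 3
) -> str:
    """Human-readable table: group_a median (IQR) | group_b median (IQR) | p.

    Volumes are conventionally printed with 1 decimal place and sO2 with 3;
    pass ``decimals`` accordingly. A p < 0.05 significance footnote is
    appended.
    """
    lines = []
    for r in rows:
        a = (
            f"{r.group_a} (n={r.n_a}): {_fmt(r.median_a, decimals)} "
            f"({_fmt(r.q1_a, decimals)}-{_fmt(r.q3_a, decimals)})"
        )
        b = (
            f"{r.group_b} (n={r.n_b}): {_fmt(r.median_b, decimals)} "
            f"({_fmt(r.q1_b, decimals)}-{_fmt(r.q3_b, decimals)})"
        )
        p = (
            f"p={r.p_value:.2f} [{r.test_mode}]"
            if r.p_value is not None
            else "descriptive only"
        )
        lines.append(f"{r.metric} [{r.level}] | {a} | {b} | {p}")
    lines.append("* p < 0.05 is significant; no multiplicity correction.")
    return "\n".join(lines)
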