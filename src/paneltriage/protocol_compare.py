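"""Paired region-by-region comparison of two library-prep protocols.

For each target region, mean read depth and percent coverage are measured
under a default and a modified hybridization protocol. The comparison
reports per-arm descriptive statistics, flag-count deltas (a region is
flagged when its mean depth is < 20 reads or it is < 100% covered), a
descriptive linear regression of the paired scatter, and a paired Wilcoxon
signed-rank test per metric.

The signed-rank test follows the classic convention: zero differences are
dropped, ties receive mid-ranks, V is the sum of the ranks of positive
differences; the two-sided p-value is exact (full sign-flip null
distribution, computed over doubled ranks so mid-ranks stay integral) for
n <= 25 and a normal approximation with tie correction and continuity
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .coverage_qc import FLAG_FULL_COVERAGE, FLAG_MIN_MEAN_DEPTH

EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedRegionData:
    """Per-region (default, optimized) mean depth and percent coverage."""

    region_ids: tuple[str, ...]
    depth_default: tuple[float, ...]
    depth_optimized: tuple[float, ...]
    pct_default: tuple[float, ...]
    pct_optimized: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        for name in ("depth_default", "depth_optimized", "pct_default", "pct_optimized"):
            if len(getattr(self, name)) != n:
                raise ValueError("paired design requires one value per region per arm")
        if n == 0:
            raise ValueError("at least one region pair is required")


@dataclass(frozen=True)
class WilcoxonResult:
    v: float
    p_value: float
    n: int  # nonzero differences used
    method: str  # "exact" or "normal"


class NotComputable(ValueError):
    """Raised when a statistic has no defined value (e.g. all-zero diffs)."""


def wilcoxon_signed_rank(diffs: Sequence[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on paired differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise NotComputable("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_p(ranks, v)
        method = "exact"
    else:
        p = _normal_p(ranks, v, n)
        method = "normal"
    return WilcoxonResult(v=v, p_value=min(1.0, p), n=int(n), method=method)


def _exact_p(ranks: np.ndarray, v: float) -> float:
    """Exact two-sided p by dynamic programming over doubled ranks.

    Doubling makes mid-ranks integral; the null assigns each rank to the
    positive side independently with probability 1/2.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w = int(round(2 * v))
    p_le = counts[: w + 1].sum()
    p_ge = counts[w:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_p(ranks: np.ndarray, v: float, n: int) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise NotComputable("zero variance under ties")
    # continuity correction toward the mean
    z = (v - mean - 0.5 * np.sign(v - mean)) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class ArmSummary:
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float


def _arm_summary(values: Sequence[float]) -> ArmSummary:
    arr = np.asarray(values, dtype=float)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return ArmSummary(float(med), float(q25), float(q75), float(arr.min()), float(arr.max()))


def _flag_count(depths: Sequence[float], pcts: Sequence[float]) -> int:
    return int(
        sum(
            d < FLAG_MIN_MEAN_DEPTH or p < FLAG_FULL_COVERAGE
            for d, p in zip(depths, pcts)
        )
    )


@dataclass(frozen=True)
class MetricSummary:
    default: ArmSummary
    optimized: ArmSummary
    delta_median: float
    delta_q25: float
    delta_q75: float
    delta_min: float
    delta_max: float


@dataclass(frozen=True)
class PairedSummary:
    n_regions: int
    depth: MetricSummary
    pct: MetricSummary
    flags_default: int
    flags_optimized: int
    flag_delta: int


def _metric_summary(default, optimized) -> MetricSummary:
    a, b = _arm_summary(default), _arm_summary(optimized)
    return MetricSummary(
        a, b,
        b.median - a.median, b.q25 - a.q25, b.q75 - a.q75,
        b.minimum - a.minimum, b.maximum - a.maximum,
    )


def paired_summary(data: PairedRegionData) -> PairedSummary:
    """Descriptive statistics per arm and metric, deltas, and flag counts."""
    return PairedSummary(
        n_regions=len(data.region_ids),
        depth=_metric_summary(data.depth_default, data.depth_optimized),
        pct=_metric_summary(data.pct_default, data.pct_optimized),
        flags_default=_flag_count(data.depth_default, data.pct_default),
        flags_optimized=_flag_count(data.depth_optimized, data.pct_optimized),
        flag_delta=_flag_count(data.depth_optimized, data.pct_optimized)
        - _flag_count(data.depth_default, data.pct_default),
    )


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class ProtocolComparison:
    summary: PairedSummary
    depth_test: Optional[WilcoxonResult]
    pct_test: Optional[WilcoxonResult]
    depth_regression: Optional[RegressionSummary]
    pct_regression: Optional[RegressionSummary]
    decreased_coverage_regions: list[str]


def _regression(x, y) -> Optional[RegressionSummary]:
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]) or x.size < 2:
        return None
    res = stats.linregress(x, y)
    return RegressionSummary(float(res.slope), float(res.intercept), float(res.rvalue**2))


def compare_protocols(data: PairedRegionData) -> ProtocolComparison:
    """Full paired protocol comparison: summaries, tests, regression, and the
    list of regions whose percent coverage decreased under the optimized arm."""
    summary = paired_summary(data)
    depth_diffs = np.subtract(data.depth_optimized, data.depth_default)
    pct_diffs = np.subtract(data.pct_optimized, data.pct_default)

    def safe_test(diffs) -> Optional[WilcoxonResult]:
        try:
            return wilcoxon_signed_rank(diffs)
        except NotComputable:
            return None

    decreased = [
        rid for rid, diff in zip(data.region_ids, pct_diffs) if diff < 0
    ]
    return ProtocolComparison(
        summary=summary,
        depth_test=safe_test(depth_diffs),
        pct_test=safe_test(pct_diffs),
        depth_regression=_regression(data.depth_default, data.depth_optimized),
        pct_regression=_regression(data.pct_default, data.pct_optimized),
        decreased_coverage_regions=decreased,
    )


def load_region_metrics(path) -> "pd.DataFrame":
    """Per-region metric TSV: columns region_id, mean_depth, pct_covered."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"region_id", "mean_depth", "pct_covered"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return df


def pair_metrics(default_df, optimized_df) -> PairedRegionData:
    """Join two per-region metric tables into a paired dataset.

    Raises when the two arms do not cover the same region set.
    """
    a = default_df.set_index("region_id").sort_index()
    b = optimized_df.set_index("region_id").sort_index()
    if list(a.index) != list(b.index):
        raise ValueError("mismatched region sets between protocol arms")
    return PairedRegionData(
        region_ids=tuple(a.index),
        depth_default=tuple(float(x) for x in a["mean_depth"]),
        depth_optimized=tuple(float(x) for x in b["mean_depth"]),
        pct_default=tuple(float(x) for x in a["pct_covered"]),
        pct_optimized=tuple(float(x) for x in b["pct_covered"]),
    )
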