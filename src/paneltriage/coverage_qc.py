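"""Region and gene coverage statistics, flagging rules, and the clinical
coverage report.

Two distinct rules coexist and are never conflated:

* flagged — mean depth < 20 reads OR the region is < 100% covered; these
  regions appear in the clinical report.
* unreliable — mean depth < 20 reads AND < 90% covered; these regions cannot
  be reliably sequenced at all.

All inequalities are strict, exactly as stated by the rules above.
"Percent covered" counts bases at or above ``covered_min_depth`` (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import DepthProfile, TargetRegion

FLAG_MIN_MEAN_DEPTH = 20.0
FLAG_FULL_COVERAGE = 100.0
UNRELIABLE_MAX_PCT = 90.0


@dataclass(frozen=True)
class RegionCoverageStat:
    region_id: str
    gene: str
    mean_depth: float
    pct_covered: float
    flagged: bool
    unreliable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_covered <= 100.0:
            raise ValueError("pct_covered must lie in [0, 100]")
        if self.unreliable and not self.flagged:
            raise ValueError("unreliable regions are always flagged")


def region_stats(
    profile: DepthProfile,
    covered_min_depth: int = 1,
    gene: str = "",
) -> RegionCoverageStat:
    """Mean depth, percent covered, and flag states for one region."""
    depths = np.asarray(profile.depths)
    if depths.size == 0:
        raise ValueError(f"region {profile.region_id}: empty depth profile")
    mean_depth = float(depths.mean())
    pct = 100.0 * float((depths >= covered_min_depth).sum()) / depths.size
    flagged = mean_depth < FLAG_MIN_MEAN_DEPTH or pct < FLAG_FULL_COVERAGE
    unreliable = mean_depth < FLAG_MIN_MEAN_DEPTH and pct < UNRELIABLE_MAX_PCT
    return RegionCoverageStat(profile.region_id, gene, mean_depth, pct, flagged, unreliable)


@dataclass(frozen=True)
class PanelSummary:
    n_regions: int
    n_flagged: int
    n_unreliable: int
    pct_unreliable: float  # rounded to 1 decimal


def panel_summary(stats: Sequence[RegionCoverageStat]) -> PanelSummary:
    if not stats:
        raise ValueError("no region statistics supplied")
    n = len(stats)
    n_flagged = sum(s.flagged for s in stats)
    n_unreliable = sum(s.unreliable for s in stats)
    pct = round(100.0 * n_unreliable / n, 1)
    return PanelSummary(n, n_flagged, n_unreliable, pct)


@dataclass(frozen=True)
class GeneCoverage:
    gene: str
    pct_covered: float
    expected_pct: Optional[float]
    suboptimal: bool
    n_regions: int


UNKNOWN_GENE = "<unknown>"


def gene_rollup(
    stats: Sequence[RegionCoverageStat],
    regions: Sequence[TargetRegion],
    expected: Optional[dict[str, float]] = None,
    weighting: str = "length",
    suboptimal_max_pct: float = 90.0,
    suboptimal_min_gap: float = 5.0,
) -> list[GeneCoverage]:
    """Per-gene coverage percent, length-weighted by default.

    A gene is "suboptimal" when its actual coverage is below
    ``suboptimal_max_pct`` AND more than ``suboptimal_min_gap`` points below
    the expectation supplied for it. ``weighting`` is ``"length"``
    (length-weighted mean of region percentages) or ``"uniform"``
    (plain mean over regions, matching per-sample averaged reporting).
    Regions without a gene label are collected under a sentinel gene.
    """
    if weighting not in ("length", "uniform"):
        raise ValueError("weighting must be 'length' or 'uniform'")
    lengths = {r.region_id: r.length for r in regions}
    by_gene: dict[str, list[tuple[float, float]]] = {}
    for s in stats:
        gene = s.gene or UNKNOWN_GENE
        w = lengths.get(s.region_id, 1) if weighting == "length" else 1.0
        by_gene.setdefault(gene, []).append((s.pct_covered, float(w)))
    out = []
    expected = expected or {}
    for gene in sorted(by_gene):
        pairs = by_gene[gene]
        total_w = sum(w for _, w in pairs)
        pct = sum(p * w for p, w in pairs) / total_w
        exp = expected.get(gene)
        sub = bool(
            exp is not None
            and pct < suboptimal_max_pct
            and exp - pct > suboptimal_min_gap
        )
        out.append(GeneCoverage(gene, pct, exp, sub, len(pairs)))
    return out


@dataclass(frozen=True)
class HotspotWarning:
    region_id: str
    gene: str
    hotspot_id: str
    chrom: str
    start: int
    end: int


@dataclass
class CoverageReport:
    """Clinical coverage report: every flagged/unreliable region plus
    prominent warnings where a failed region contains a known hotspot."""

    flagged: list[RegionCoverageStat]
    unreliable: list[RegionCoverageStat]
    hotspot_warnings: list[HotspotWarning]
    summary: PanelSummary

    def to_text(self) -> str:
        lines = ["# Clinical coverage report"]
        lines.append(
            f"regions={self.summary.n_regions} flagged={self.summary.n_flagged} "
            f"unreliable={self.summary.n_unreliable} "
            f"pct_unreliable={self.summary.pct_unreliable}"
        )
        if self.hotspot_warnings:
            lines.append("## WARNING: hotspots in failed regions")
            for w in self.hotspot_warnings:
                lines.append(
                    f"!! hotspot {w.hotspot_id} ({w.chrom}:{w.start}-{w.end}) lies in "
                    f"failed region {w.region_id} ({w.gene})"
                )
        lines.append("## Flagged regions")
        if not self.flagged:
            lines.append("none")
        for s in self.flagged:
            tag = "UNRELIABLE" if s.unreliable else "flagged"
            lines.append(
                f"{s.gene}\t{s.region_id}\tmean_depth={s.mean_depth:.1f}\t"
                f"pct_covered={s.pct_covered:.1f}\t{tag}"
            )
        return "\n".join(lines) + "\n"


def coverage_report(
    stats: Sequence[RegionCoverageStat],
    regions: Sequence[TargetRegion],
    hotspots: Iterable[TargetRegion] = (),
) -> CoverageReport:
    """Assemble the clinical report; stable-sorted by (gene, interval)."""
    by_id = {r.region_id: r for r in regions}

    def sort_key(s: RegionCoverageStat):
        r = by_id.get(s.region_id)
        return (s.gene, r.chrom if r else "", r.start if r else 0, s.region_id)

    flagged = sorted((s for s in stats if s.flagged), key=sort_key)
    unreliable = [s for s in flagged if s.unreliable]
    warnings = []
    for h in hotspots:
        for s in flagged:
            r = by_id.get(s.region_id)
            if r is None or r.chrom != h.chrom:
                continue
            if r.start < h.end and h.start < r.end:
                warnings.append(
                    HotspotWarning(r.region_id, r.gene, h.region_id, h.chrom, h.start, h.end)
                )
    warnings.sort(key=lambda w: (w.gene, w.chrom, w.start, w.hotspot_id))
    return CoverageReport(flagged, unreliable, warnings, panel_summary(list(stats)))
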