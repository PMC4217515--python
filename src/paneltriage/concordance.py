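"""Base-resolution concordance of NGS calls against Sanger truth.

The evaluation domain is the intersection of the Sanger-interrogated
intervals with the exons padded by a kept flank (default +/-5 bases);
intronic positions beyond the kept flank are excluded from all counts, since
capture designs with 10-base flanks do not reliably detect them.

Accounting convention: each evaluated reference position contributes one
count. A position carrying a normalized-key match in both call sets is a TP;
truth-only keys are FNs, NGS-only keys are FPs, and every remaining
evaluated base is a TN. Multi-base events (INDELs) match at variant level —
two events agree iff their normalized keys are identical — and occupy the
single anchor position in the accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .data_model import TargetRegion, VariantCall


@dataclass(frozen=True)
class ConcordanceSettings:
    exon_flank_keep: int = 5

    def __post_init__(self) -> None:
        if self.exon_flank_keep < 0:
            raise ValueError("exon_flank_keep must be >= 0")


@dataclass(frozen=True)
class ConcordanceTally:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def scope(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _domain_positions(
    truth_intervals: Sequence[TargetRegion],
    exons: Sequence[TargetRegion],
    settings: ConcordanceSettings,
) -> set[tuple[str, int]]:
    padded: dict[str, list[tuple[int, int]]] = {}
    for e in exons:
        padded.setdefault(e.chrom, []).append(
            (e.start - settings.exon_flank_keep, e.end + settings.exon_flank_keep)
        )
    domain = set()
    for iv in truth_intervals:
        for s, e in padded.get(iv.chrom, ()):
            lo, hi = max(iv.start, s), min(iv.end, e)
            for pos0 in range(lo, hi):
                domain.add((iv.chrom, pos0 + 1))  # store 1-based positions
    return domain


def tally(
    ngs_calls: Sequence[VariantCall],
    truth_variants: Sequence[VariantCall],
    truth_intervals: Sequence[TargetRegion],
    exons: Sequence[TargetRegion],
    settings: ConcordanceSettings = ConcordanceSettings(),
) -> ConcordanceTally:
    """Count TP/FN/TN/FP over the evaluation domain.

    ``truth_intervals`` are the Sanger-interrogated intervals; ``exons`` the
    exon coordinates in the same reference frame. Calls must be normalized.
    Contradictory truth records (two records at one position with different
    keys) raise.
    """
    domain = _domain_positions(truth_intervals, exons, settings)

    truth_by_pos: dict[tuple[str, int], set] = {}
    for t in truth_variants:
        truth_by_pos.setdefault((t.chrom, t.pos), set()).add(t.key)
    for pos, keys in truth_by_pos.items():
        if len(keys) > 1:
            raise ValueError(f"contradictory truth records at {pos[0]}:{pos[1]}")

    truth_keys = {t.key for t in truth_variants if (t.chrom, t.pos) in domain}
    ngs_keys = {v.key for v in ngs_calls if (v.chrom, v.pos) in domain}

    tp = len(truth_keys & ngs_keys)
    fn = len(truth_keys - ngs_keys)
    fp = len(ngs_keys - truth_keys)
    tn = len(domain) - tp - fn - fp
    if tn < 0:
        raise ValueError("more variant keys than evaluated positions")
    return ConcordanceTally(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class ConcordanceMetrics:
    """Percent metrics; None where the denominator is empty (not computable).

    ``rounded(decimals)`` gives the display form (3 decimals by default,
    1-decimal mode available).
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    fn_rate: Optional[float]
    fp_rate: Optional[float]

    def rounded(self, decimals: int = 3) -> dict[str, Optional[float]]:
        return {
            name: (None if value is None else round(value, decimals))
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("fn_rate", self.fn_rate),
                ("fp_rate", self.fp_rate),
            )
        }


def metrics(t: ConcordanceTally) -> ConcordanceMetrics:
    """Sensitivity, specificity, FN rate and FP rate in percent.

    sensitivity = 100*tp/(tp+fn); fn_rate = 100*fn/(tp+fn);
    specificity = 100*tn/(tn+fp); fp_rate = 100*fp/(tn+fp).
    """
    sens = fnr = spec = fpr = None
    if t.tp + t.fn > 0:
        sens = 100.0 * t.tp / (t.tp + t.fn)
        fnr = 100.0 * t.fn / (t.tp + t.fn)
    if t.tn + t.fp > 0:
        spec = 100.0 * t.tn / (t.tn + t.fp)
        fpr = 100.0 * t.fp / (t.tn + t.fp)
    return ConcordanceMetrics(sens, spec, fnr, fpr)
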