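"""Threshold-based germline pileup caller over columnar read stacks.

The caller applies the low-stringency semiconductor-sequencing settings used
for germline screening: per-type minimum coverage (6 reads for SNVs, 15 for
INDELs), per-type minimum alt coverage on each strand (0 / 5), a Phred-scaled
minimum variant score of 10, a minimum allele frequency of 0.1 (optionally
disabled, e.g. to recover low-fraction somatic reversions), and per-type
strand-bias ceilings (0.95 / 0.85).

The variant score is the Phred-scaled binomial tail probability of seeing at
least the observed alt-read count from sequencing error alone:

    score = -10 * log10( P[ Binomial(depth, error_rate) >= alt_count ] )

capped at ``SCORE_CAP``. When scoring an SNV candidate the caller uses the
per-allele substitution rate (one third of the per-base error rate, since a
substitution error lands on one of three alternate bases); indel candidates
are scored at the full per-base rate. The strand-bias statistic is the majority-strand
fraction of alt-supporting reads, max(fwd, rev) / (fwd + rev), in [0.5, 1].
All thresholds are inclusive: ``>=`` passes a minimum, ``<=`` passes a
ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .data_model import (
    ReadStack,
    ReferenceWindow,
    VariantCall,
    VariantType,
    normalize_variant,
)

SCORE_CAP = 4000.0
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class CallerSettings:
    """Stringency settings of the germline pileup caller."""

    min_cov_snp: int = 6
    min_cov_indel: int = 15
    min_cov_each_strand_snp: int = 0
    min_cov_each_strand_indel: int = 5
    min_variant_score: float = 10.0
    min_allele_freq: Optional[float] = 0.1  # None disables the cutoff
    strand_bias_max_snp: float = 0.95
    strand_bias_max_indel: float = 0.85
    per_base_error_rate: float = 0.01
    strand_bias_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "min_cov_snp",
            "min_cov_indel",
            "min_cov_each_strand_snp",
            "min_cov_each_strand_indel",
            "min_variant_score",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("strand_bias_max_snp", "strand_bias_max_indel"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_allele_freq is not None and not 0.0 <= self.min_allele_freq <= 1.0:
            raise ValueError("min_allele_freq must lie in [0, 1]")
        if not 0.0 < self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must lie in (0, 1)")


def variant_score(alt_count: int, depth: int, error_rate: float) -> float:
    """Phred-scaled binomial error-tail score of an alt-read count.

    Monotone non-decreasing in ``alt_count`` at fixed depth; 0 when
    ``alt_count`` is 0 (the tail probability is 1); capped at ``SCORE_CAP``.
    """
    if depth <= 0:
        raise ValueError("variant score undefined at zero depth")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count must lie in [0, depth]")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie in (0, 1)")
    if alt_count == 0:
        return 0.0
    log_sf = stats.binom.logsf(alt_count - 1, depth, error_rate)
    if not math.isfinite(log_sf):  # tail underflows below float range
        return SCORE_CAP
    return min(SCORE_CAP, -10.0 * log_sf / _LN10)


def strand_imbalance_significant(
    alt_fwd: int, alt_rev: int, alpha: float = 0.05
) -> bool:
    """Whether the strand split is inconsistent with fair (0.5) sampling.

    A raw ratio ceiling over-rejects sparse evidence: three alt reads land on
    one strand a quarter of the time under the null. The caller therefore
    discards a candidate for strand bias only when the ratio exceeds the
    ceiling AND this two-sided binomial test is significant at ``alpha``.
    """
    total = alt_fwd + alt_rev
    if total == 0:
        return False
    return stats.binomtest(min(alt_fwd, alt_rev), total, 0.5).pvalue < alpha


def strand_bias(alt_fwd: int, alt_rev: int) -> Optional[float]:
    """Majority-strand fraction of alt reads, or None when not evaluable."""
    if alt_fwd < 0 or alt_rev < 0:
        raise ValueError("strand counts must be >= 0")
    total = alt_fwd + alt_rev
    if total == 0:
        return None
    return max(alt_fwd, alt_rev) / total


@dataclass(frozen=True)
class _Candidate:
    """A candidate event in window coordinates before thresholding."""

    offset: int  # anchor offset for indels, variant offset for SNVs
    ref: str
    alt: str
    is_indel: bool
    alt_fwd: int
    alt_rev: int
    depth: int


def _column_matrix(stack: ReadStack) -> np.ndarray:
    """Byte matrix (n_reads x width) of per-position observation codes."""
    if not stack.reads:
        return np.empty((0, len(stack.reference)), dtype=np.uint8)
    joined = "".join(read.observations for read in stack.reads)
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(stack.reads), len(stack.reference))


def _collect_candidates(stack: ReadStack) -> list[_Candidate]:
    width = len(stack.reference)
    ref_u = stack.reference.upper()
    mat = _column_matrix(stack)
    strands = np.array([1 if r.strand == "+" else 0 for r in stack.reads], dtype=bool)
    covered = mat != ord(".")
    depth_per_col = covered.sum(axis=0)

    candidates: list[_Candidate] = []

    # SNV candidates column by column.
    for j in range(width):
        col = mat[:, j]
        for base in "ACGT":
            if base == ref_u[j]:
                continue
            hits = col == ord(base)
            n = int(hits.sum())
            if n == 0:
                continue
            fwd = int((hits & strands).sum())
            candidates.append(
                _Candidate(j, ref_u[j], base, False, fwd, n - fwd, int(depth_per_col[j]))
            )

    # Deletion candidates: maximal gap runs per read, keyed by (anchor, span).
    del_support: dict[tuple[int, int], list[int]] = {}
    gap = mat == ord("-")
    for i in range(mat.shape[0]):
        row = gap[i]
        j = 0
        while j < width:
            if row[j]:
                k = j
                while k < width and row[k]:
                    k += 1
                if j >= 1:  # needs an anchor base inside the window
                    del_support.setdefault((j, k - j), []).append(i)
                j = k
            else:
                j += 1
    for (j, span), readers in del_support.items():
        fwd = int(sum(strands[i] for i in readers))
        anchor = j - 1
        # A supporting read may not itself cover the anchor column.
        depth = max(int(depth_per_col[anchor]), len(readers))
        candidates.append(
            _Candidate(
                anchor,
                ref_u[anchor : j + span],
                ref_u[anchor],
                True,
                fwd,
                len(readers) - fwd,
                depth,
            )
        )

    # Insertion candidates keyed by (offset, inserted sequence).
    ins_support: dict[tuple[int, str], list[int]] = {}
    for i, read in enumerate(stack.reads):
        for off, seq in read.insertions.items():
            ins_support.setdefault((off, seq.upper()), []).append(i)
    for (off, seq), readers in ins_support.items():
        fwd = int(sum(strands[i] for i in readers))
        candidates.append(
            _Candidate(
                off,
                ref_u[off],
                ref_u[off] + seq,
                True,
                fwd,
                len(readers) - fwd,
                int(depth_per_col[off]),
            )
        )
    return candidates


def call_variants(
    stack: ReadStack,
    settings: CallerSettings = CallerSettings(),
    sample_id: str = "sample",
    run_id: str = "run",
) -> list[VariantCall]:
    """Call variants on a read stack; emitted calls are normalized.

    A candidate is emitted iff all of: per-type depth minimum, per-type
    each-strand alt-coverage minimum, variant score >= minimum, allele
    frequency >= minimum (skipped when disabled), and strand bias <= the
    per-type ceiling.
    """
    window = ReferenceWindow(stack.chrom, stack.start, stack.reference)
    calls: list[VariantCall] = []
    for c in _collect_candidates(stack):
        alt_count = c.alt_fwd + c.alt_rev
        if alt_count == 0 or c.depth == 0:
            continue
        if c.is_indel:
            min_cov = settings.min_cov_indel
            min_each = settings.min_cov_each_strand_indel
            bias_max = settings.strand_bias_max_indel
        else:
            min_cov = settings.min_cov_snp
            min_each = settings.min_cov_each_strand_snp
            bias_max = settings.strand_bias_max_snp
        if c.depth < min_cov:
            continue
        if c.alt_fwd < min_each or c.alt_rev < min_each:
            continue
        # A substitution error miscalls to one of three alternate bases, so a
        # specific SNV allele accumulates error support at one third of the
        # per-base rate; indel errors are not split.
        err = settings.per_base_error_rate / (1.0 if c.is_indel else 3.0)
        score = variant_score(alt_count, c.depth, err)
        if score < settings.min_variant_score:
            continue
        vaf = alt_count / c.depth
        if settings.min_allele_freq is not None and vaf < settings.min_allele_freq:
            continue
        bias = strand_bias(c.alt_fwd, c.alt_rev)
        if (
            bias is not None
            and bias > bias_max
            and strand_imbalance_significant(c.alt_fwd, c.alt_rev, settings.strand_bias_alpha)
        ):
            continue
        call = VariantCall(
            sample_id=sample_id,
            run_id=run_id,
            chrom=stack.chrom,
            pos=stack.start + c.offset + 1,
            ref=c.ref,
            alt=c.alt,
            quality=score,
            depth=c.depth,
            alt_fwd=c.alt_fwd,
            alt_rev=c.alt_rev,
        )
        calls.append(normalize_variant(call, window))
    calls.sort(key=lambda v: (v.pos, v.ref, v.alt))
    return calls
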