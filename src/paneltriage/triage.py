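"""Rule-based triage of surviving variant calls.

Each variant is classified HIGH_CONFIDENCE (Sanger confirmation not
warranted) or NEEDS_CONFIRMATION by eight criteria: Phred q >= 30, total
depth >= 20, VAF >= 25%, absence from wild-type controls, absence from other
samples in the same run, no co-occurring variants on the alt-carrying reads,
no homopolymer/repeat context, and the variant being an SNV (every INDEL
needs orthogonal confirmation). Any criterion that fails — or cannot be
evaluated from the available data — blocks HIGH_CONFIDENCE; missing evidence
never silently passes.

A variant whose VAF sits below the germline threshold but with at least a
few alt reads is additionally flagged as a possible somatic event whose
alignments deserve manual inspection; coverage at germline thresholds is too
low to call such variants reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .data_model import ReadStack, ReferenceWindow, VariantCall, VariantType

CRITERIA = (
    "quality",
    "depth",
    "vaf",
    "not_in_controls",
    "not_in_runmates",
    "no_read_covariants",
    "context",
    "is_snv",
)


class Outcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUABLE = "not_evaluable"


class TriageClass(str, Enum):
    HIGH_CONFIDENCE = "HIGH_CONFIDENCE"
    NEEDS_CONFIRMATION = "NEEDS_CONFIRMATION"


@dataclass(frozen=True)
class TriageThresholds:
    """Numeric triage thresholds; all minima are inclusive."""

    min_q: float = 30.0
    min_depth: int = 20
    min_vaf: float = 0.25
    homopolymer_min_run: int = 4
    repeat_max_unit: int = 3
    repeat_min_span: int = 8
    adjacency: int = 1  # "immediately adjacent" distance in bases
    covariant_min_reads: int = 2
    covariant_min_fraction: float = 0.2
    somatic_min_alt_reads: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in (0, 1]")
        for name in ("min_q", "min_depth", "homopolymer_min_run", "repeat_min_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TriageVerdict:
    """Per-criterion outcomes and the final class for one variant."""

    key: str
    criteria: dict[str, Outcome]
    final: TriageClass
    reasons: list[str]
    somatic_suspect: bool = False

    def __post_init__(self) -> None:
        all_pass = all(o is Outcome.PASS for o in self.criteria.values())
        if (self.final is TriageClass.HIGH_CONFIDENCE) != all_pass:
            raise ValueError("final class inconsistent with criterion outcomes")


# ---------------------------------------------------------------------------
# Sequence-context check
# ---------------------------------------------------------------------------


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def _repeat_spans(seq: str, max_unit: int, min_span: int) -> list[tuple[int, int]]:
    """Maximal tandem-repeat spans with unit length <= max_unit."""
    spans = []
    n = len(seq)
    for unit in range(1, max_unit + 1):
        i = 0
        while i + unit < n:
            if seq[i] == seq[i + unit]:
                j = i
                while j + unit < n and seq[j] == seq[j + unit]:
                    j += 1
                span = (j + unit) - i  # total bases covered by the repeat
                if span >= min_span:
                    spans.append((i, j + unit))
                i = j + 1
            else:
                i += 1
    return spans


def check_context(
    v: VariantCall,
    window: ReferenceWindow,
    thresholds: TriageThresholds = TriageThresholds(),
) -> Outcome:
    """Fail when a homopolymer run or short tandem repeat overlaps or abuts
    the variant footprint (distance <= ``adjacency``); not evaluable when the
    window does not span the scan radius on both sides.
    """
    radius = max(thresholds.homopolymer_min_run, thresholds.repeat_min_span)
    foot_start = v.pos - 1 - window.start
    foot_end = foot_start + len(v.ref)  # half-open, window coordinates
    if foot_start < 0 or foot_end > len(window.seq):
        return Outcome.NOT_EVALUABLE
    if foot_start < radius or len(window.seq) - foot_end < radius:
        return Outcome.NOT_EVALUABLE
    seq = window.seq.upper()
    intervals = _homopolymer_runs(seq, thresholds.homopolymer_min_run)
    intervals += _repeat_spans(seq, thresholds.repeat_max_unit, thresholds.repeat_min_span)
    lo = foot_start - thresholds.adjacency
    hi = foot_end + thresholds.adjacency
    for s, e in intervals:
        if s < hi and e > lo:
            return Outcome.FAIL
    return Outcome.PASS


# ---------------------------------------------------------------------------
# Same-read co-variant check
# ---------------------------------------------------------------------------


def _read_supports(read, offset: int, v: VariantCall, ref: str) -> bool:
    if v.variant_type is VariantType.SNV:
        return read.observations[offset] == v.alt
    if v.variant_type is VariantType.INS:
        seq = v.alt[len(v.ref):]
        return read.insertions.get(offset, "").upper() == seq.upper()
    if v.variant_type is VariantType.DEL:
        span = len(v.ref) - len(v.alt)
        gap = read.observations[offset + 1 : offset + 1 + span]
        return gap == "-" * span and (
            offset + 1 + span >= len(read.observations)
            or read.observations[offset + 1 + span] != "-"
        )
    return False


def check_read_covariants(
    v: VariantCall,
    stack: Optional[ReadStack],
    thresholds: TriageThresholds = TriageThresholds(),
) -> Outcome:
    """Fail when the alt-carrying reads share another non-reference signal.

    Scattered sequencing errors are tolerated: a secondary mismatch counts
    only when at least ``covariant_min_reads`` alt reads and at least
    ``covariant_min_fraction`` of them share the same observation. Setting
    the fraction to 0 reduces the tolerance to "ignore mismatches unique to
    one read".
    """
    if stack is None:
        return Outcome.NOT_EVALUABLE
    offset = v.pos - 1 - stack.start
    if not 0 <= offset < len(stack.reference):
        return Outcome.NOT_EVALUABLE
    ref = stack.reference.upper()
    alt_reads = [r for r in stack.reads if _read_supports(r, offset, v, ref)]
    if not alt_reads:
        return Outcome.NOT_EVALUABLE
    n_alt = len(alt_reads)
    threshold = max(thresholds.covariant_min_reads, 2)
    if thresholds.covariant_min_fraction > 0:
        threshold = max(threshold, thresholds.covariant_min_fraction * n_alt)

    foot = set(range(offset, offset + len(v.ref)))
    shared: dict[tuple[int, str], int] = {}
    for read in alt_reads:
        obs = read.observations
        for j, code in enumerate(obs):
            if j in foot or code == "." or code == ref[j]:
                continue
            shared[(j, code)] = shared.get((j, code), 0) + 1
        for j, seq in read.insertions.items():
            if j in foot and v.variant_type is VariantType.INS:
                continue
            shared[(j, "+" + seq)] = shared.get((j, "+" + seq), 0) + 1
    if any(count >= threshold for count in shared.values()):
        return Outcome.FAIL
    return Outcome.PASS


# ---------------------------------------------------------------------------
# Cohort checks
# ---------------------------------------------------------------------------


def _key_in_callsets(v: VariantCall, callsets: Sequence[Sequence[VariantCall]]) -> bool:
    key = v.key
    return any(c.key == key for cs in callsets for c in cs)


def check_cohort(
    v: VariantCall,
    controls: Sequence[Sequence[VariantCall]],
    runmates: Sequence[Sequence[VariantCall]],
) -> Outcome:
    """Fail when the key occurs in any wild-type control or any run-mate."""
    if _key_in_callsets(v, controls) or _key_in_callsets(v, runmates):
        return Outcome.FAIL
    return Outcome.PASS


# ---------------------------------------------------------------------------
# Full classification
# ---------------------------------------------------------------------------


@dataclass
class TriageInputs:
    """Context evidence needed to evaluate the non-numeric criteria."""

    window: Optional[ReferenceWindow] = None
    stack: Optional[ReadStack] = None
    controls: Optional[Sequence[Sequence[VariantCall]]] = None
    runmates: Optional[Sequence[Sequence[VariantCall]]] = None


def _threshold_outcome(value, minimum) -> Outcome:
    if value is None:
        return Outcome.NOT_EVALUABLE
    return Outcome.PASS if value >= minimum else Outcome.FAIL


def classify(
    v: VariantCall,
    thresholds: TriageThresholds = TriageThresholds(),
    inputs: TriageInputs = TriageInputs(),
) -> TriageVerdict:
    """Evaluate all eight criteria; HIGH_CONFIDENCE iff every one passes."""
    out: dict[str, Outcome] = {}
    out["quality"] = _threshold_outcome(v.quality, thresholds.min_q)
    out["depth"] = _threshold_outcome(v.depth, thresholds.min_depth)
    out["vaf"] = _threshold_outcome(v.vaf, thresholds.min_vaf)
    out["not_in_controls"] = (
        Outcome.NOT_EVALUABLE
        if inputs.controls is None
        else (Outcome.FAIL if _key_in_callsets(v, inputs.controls) else Outcome.PASS)
    )
    out["not_in_runmates"] = (
        Outcome.NOT_EVALUABLE
        if inputs.runmates is None
        else (Outcome.FAIL if _key_in_callsets(v, inputs.runmates) else Outcome.PASS)
    )
    out["no_read_covariants"] = check_read_covariants(v, inputs.stack, thresholds)
    out["context"] = (
        Outcome.NOT_EVALUABLE
        if inputs.window is None
        else check_context(v, inputs.window, thresholds)
    )
    out["is_snv"] = (
        Outcome.PASS if v.variant_type is VariantType.SNV else Outcome.FAIL
    )

    reasons = [name for name, o in out.items() if o is not Outcome.PASS]
    final = (
        TriageClass.HIGH_CONFIDENCE if not reasons else TriageClass.NEEDS_CONFIRMATION
    )
    somatic = bool(
        v.vaf is not None
        and v.vaf < thresholds.min_vaf
        and (v.alt_count or 0) >= thresholds.somatic_min_alt_reads
    )
    return TriageVerdict(
        key=str(v.key), criteria=out, final=final, reasons=reasons,
        somatic_suspect=somatic,
    )


def verdicts_table(verdicts: Sequence[TriageVerdict]) -> "pd.DataFrame":
    """Tabulate verdicts, one row per variant with all criterion outcomes."""
    import pandas as pd

    rows = []
    for v in verdicts:
        row = {"key": v.key, "class": v.final.value,
               "somatic_suspect": v.somatic_suspect}
        for name in CRITERIA:
            row[name] = v.criteria[name].value
        row["reasons"] = ",".join(v.reasons)
        rows.append(row)
    return pd.DataFrame(rows)
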