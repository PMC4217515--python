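"""Platform-specific false-positive blacklist built from healthy controls.

Low-stringency germline calling keeps false negatives down at the price of
recurrent platform artifacts. Variants annotated as predicted-deleterious
that appear in more than one healthy control are taken to be such artifacts
and are subtracted from patient call sets by exact normalized-key match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .data_model import VariantCall, VariantKey


@dataclass
class Blacklist:
    """Recurrent-artifact keys with per-entry control carrier counts."""

    provenance: dict[VariantKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, n in self.provenance.items() if n < 2]
        if bad:
            raise ValueError(
                f"blacklist entries must be carried by >= 2 controls: {bad[0]}"
            )

    @property
    def entries(self) -> set[VariantKey]:
        return set(self.provenance)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.provenance

    def __len__(self) -> int:
        return len(self.provenance)


def build_blacklist(control_callsets: Sequence[Sequence[VariantCall]]) -> Blacklist:
    """Collect keys that are predicted deleterious and occur in > 1 control.

    "Present in" means present as a called variant regardless of the VAF or
    quality in the control. Raises on duplicate control sample ids, which
    would double-count carriers.
    """
    sample_ids = [cs[0].sample_id for cs in control_callsets if cs]
    if len(sample_ids) != len(set(sample_ids)):
        raise ValueError("duplicate sample_id among control call sets")
    carriers: dict[VariantKey, set[str]] = {}
    deleterious: set[VariantKey] = set()
    for callset in control_callsets:
        for v in callset:
            carriers.setdefault(v.key, set()).add(v.sample_id)
            if v.predicted_deleterious:
                deleterious.add(v.key)
    provenance = {
        key: len(samples)
        for key, samples in carriers.items()
        if key in deleterious and len(samples) > 1
    }
    return Blacklist(provenance)


def apply_blacklist(
    patient_calls: Sequence[VariantCall], bl: Blacklist
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition patient calls into (kept, removed) by exact key match.

    Order is preserved within each part; idempotent.
    """
    kept, removed = [], []
    for v in patient_calls:
        (removed if v.key in bl else kept).append(v)
    return kept, removed


def write_blacklist(bl: Blacklist, path: str | Path) -> None:
    """Serialize as 4+-column BED; the normalized key lives in column 4.

    The interval spans the REF footprint (0-based half-open); column 5 holds
    the control carrier count.
    """
    with open(path, "w") as fh:
        for key in sorted(bl.provenance):
            start = key.pos - 1
            fh.write(
                f"{key.chrom}\t{start}\t{start + len(key.ref)}\t{key}\t"
                f"{bl.provenance[key]}\n"
            )


def read_blacklist(path: str | Path) -> Blacklist:
    provenance: dict[VariantKey, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            key = VariantKey.parse(cols[3])
            provenance[key] = int(cols[4]) if len(cols) > 4 else 2
    return Blacklist(provenance)


def filter_report(
    patient_calls: Sequence[VariantCall], bl: Blacklist
) -> list[dict]:
    """Per-variant action report (key, control count, kept/removed)."""
    rows = []
    for v in patient_calls:
        removed = v.key in bl
        rows.append(
            {
                "key": str(v.key),
                "sample_id": v.sample_id,
                "control_count": bl.provenance.get(v.key, 0),
                "action": "removed" if removed else "kept",
            }
        )
    return rows
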