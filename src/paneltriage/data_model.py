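"""Core domain types, standard-format I/O, and variant normalization.

Coordinate conventions follow the underlying standards: VCF positions are
1-based, BED intervals are 0-based half-open, and all internal region
arithmetic is 0-based half-open.

Strand counts travel in a small, documented VCF INFO dialect (``SAF``/``SAR``
for alt-supporting forward/reverse reads, ``PDEL`` for a deleteriousness
annotation flag); VCFs lacking those tags parse fine with the strand counts
marked unknown, and downstream strand-dependent checks report "not evaluable"
for such variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam


class VariantType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


def infer_variant_type(ref: str, alt: str) -> VariantType:
    """Classify an allele pair by the length relationship of REF and ALT."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(ref) < len(alt):
        return VariantType.INS
    if len(ref) > len(alt):
        return VariantType.DEL
    return VariantType.MNV


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity used for blacklist and cohort matching."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, allele = text.split(":")
        ref, alt = allele.split(">")
        return cls(chrom, int(pos), ref, alt)


_BASES = frozenset("ACGTN")


@dataclass
class VariantCall:
    """One called variant with sample/run provenance and evidence fields.

    ``alt_fwd``/``alt_rev`` are the alt-supporting read counts per strand;
    both are ``None`` when the source file carried no strand information.
    ``vaf`` is derived from the counts when not supplied explicitly.
    """

    sample_id: str
    run_id: str
    chrom: str
    pos: int  # 1-based, leftmost reference base of the event
    ref: str
    alt: str
    quality: float = 0.0
    depth: int = 0
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    vaf: Optional[float] = None
    predicted_deleterious: bool = False
    variant_type: VariantType = field(init=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty base strings")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if set(allele.upper()) - _BASES:
                raise ValueError(f"non-base characters in allele {allele!r}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.quality < 0:
            raise ValueError("quality must be a Phred-scaled score >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        self.variant_type = infer_variant_type(self.ref, self.alt)
        if self.strand_known:
            if self.alt_fwd < 0 or self.alt_rev < 0:
                raise ValueError("strand counts must be >= 0")
            if self.alt_count > self.depth:
                raise ValueError(
                    f"alt_fwd + alt_rev = {self.alt_count} exceeds depth {self.depth}"
                )
            if self.vaf is None and self.depth > 0:
                self.vaf = self.alt_count / self.depth
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must lie in [0, 1]")

    @property
    def strand_known(self) -> bool:
        return self.alt_fwd is not None and self.alt_rev is not None

    @property
    def alt_count(self) -> Optional[int]:
        if not self.strand_known:
            return None
        return self.alt_fwd + self.alt_rev

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TargetRegion:
    """Panel interval, 0-based half-open, with its exon-flank design width."""

    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    flank: int = 10

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthProfile:
    """Per-base read depths for one target region."""

    region_id: str
    depths: Sequence[int]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be non-negative")


@dataclass
class StackRead:
    """One read's columnar observations over a region window.

    ``observations`` is a string of per-position codes aligned to the window:
    ``.`` not covered, ``-`` deleted base, otherwise the observed base.
    ``insertions`` maps a window offset to the base string inserted
    immediately after that position.
    """

    read_id: str
    strand: str  # "+" or "-"
    observations: str
    insertions: dict[int, str] = field(default_factory=dict)


@dataclass
class ReadStack:
    """Per-read allele observations over a region window.

    The substrate for pileup calling and same-read co-variant checks.
    """

    chrom: str
    start: int  # 0-based
    reference: str
    reads: list[StackRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        width = len(self.reference)
        for read in self.reads:
            if len(read.observations) != width:
                raise ValueError(
                    f"read {read.read_id}: observation width "
                    f"{len(read.observations)} != window width {width}"
                )
            if any(not 0 <= off < width for off in read.insertions):
                raise ValueError(f"read {read.read_id}: insertion outside window")

    @property
    def end(self) -> int:
        return self.start + len(self.reference)


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence with genomic coordinates (0-based start)."""

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def base_at(self, pos: int) -> str:
        """Reference base at 1-based position ``pos``."""
        off = pos - 1 - self.start
        if not 0 <= off < len(self.seq):
            raise ValueError(
                f"position {pos} outside window {self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[off]


class ReferenceMismatchError(ValueError):
    pass


def normalize_variant(v: VariantCall, window: ReferenceWindow) -> VariantCall:
    """Left-align and trim a variant to its minimal leftmost representation.

    SNVs are returned unchanged (after a reference check). INDELs are shifted
    to the leftmost equivalent position within the reference window and
    common prefix/suffix bases are trimmed. Idempotent.
    """
    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    off = pos - 1 - window.start
    if off < 0 or off + len(ref) > len(window.seq):
        raise ValueError(
            f"window {window.chrom}:{window.start}-{window.end} does not cover "
            f"event at pos {pos} (ref length {len(ref)})"
        )
    expected = window.seq[off : off + len(ref)].upper()
    if expected != ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {v.chrom}:{pos}: expected {expected!r}, "
            f"variant says {ref!r}"
        )
    if len(ref) == 1 and len(alt) == 1:
        return v

    # Right-trim shared suffix bases; when one allele would empty, extend left
    # with the preceding reference base instead (standard left alignment).
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            prev_off = pos - 2 - window.start
            if prev_off < 0:
                break
            prev = window.seq[prev_off].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            ref = ref[:-1]
            alt = alt[:-1]
    # Left-trim shared prefix bases, keeping the anchor base of an INDEL.
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1

    if pos == v.pos and ref == v.ref and alt == v.alt:
        return v
    return VariantCall(
        sample_id=v.sample_id,
        run_id=v.run_id,
        chrom=v.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        quality=v.quality,
        depth=v.depth,
        alt_fwd=v.alt_fwd,
        alt_rev=v.alt_rev,
        vaf=v.vaf,
        predicted_deleterious=v.predicted_deleterious,
    )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_VCF_INFO_LINES = [
    ('DP', '1', 'Integer', 'Total read depth at the locus'),
    ('AF', 'A', 'Float', 'Variant allele frequency'),
    ('SAF', 'A', 'Integer', 'Alt-supporting reads on the forward strand'),
    ('SAR', 'A', 'Integer', 'Alt-supporting reads on the reverse strand'),
    ('PDEL', '0', 'Flag', 'Variant annotated as predicted deleterious'),
]


def read_variants(
    path: str | Path,
    sample_id: Optional[str] = None,
    run_id: Optional[str] = None,
) -> list[VariantCall]:
    """Read a VCF into VariantCall records, one per ALT allele.

    Multi-allelic records are split. Sample and run identifiers come from
    ``##sample_id=`` / ``##run_id=`` header lines unless overridden by the
    arguments. Records without strand tags get unknown strand counts and a
    record-level warning.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        header_meta = {}
        for rec in vcf.header.records:
            if rec.type == "GENERIC" and rec.key in ("sample_id", "run_id"):
                header_meta[rec.key] = rec.value
        sid = sample_id or header_meta.get("sample_id") or "unknown"
        rid = run_id or header_meta.get("run_id") or "unknown"
        calls: list[VariantCall] = []
        for rec in vcf:
            if rec.alts is None:
                continue
            depth = int(_info_get(rec, "DP", 0) or 0)
            safs = _info_get(rec, "SAF")
            sars = _info_get(rec, "SAR")
            afs = _info_get(rec, "AF")
            pdel = bool(_info_get(rec, "PDEL", False))
            n_alts = len(rec.alts)
            for i, alt in enumerate(rec.alts):
                fwd = rev = None
                if safs is not None and sars is not None:
                    fwd = int(_nth(safs, i, n_alts))
                    rev = int(_nth(sars, i, n_alts))
                else:
                    warnings.warn(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks SAF/SAR "
                        "strand tags; strand counts marked unknown",
                        stacklevel=2,
                    )
                vaf = float(_nth(afs, i, n_alts)) if afs is not None else None
                calls.append(
                    VariantCall(
                        sample_id=sid,
                        run_id=rid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        depth=depth,
                        alt_fwd=fwd,
                        alt_rev=rev,
                        vaf=vaf,
                        predicted_deleterious=pdel,
                    )
                )
    return calls


def _info_get(rec, key, default=None):
    # pysam raises on INFO tags absent from the header; treat those as missing
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _nth(value, i, n_alts):
    if isinstance(value, (tuple, list)):
        return value[i]
    if n_alts == 1:
        return value
    raise ValueError("per-ALT INFO field is scalar on a multi-allelic record")


def write_variants(
    calls: Iterable[VariantCall],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
    sample_id: Optional[str] = None,
    run_id: Optional[str] = None,
) -> None:
    """Write VariantCall records as a VCF v4.2 file (one record per call)."""
    calls = list(calls)
    header = pysam.VariantHeader()
    for tag, number, typ, desc in _VCF_INFO_LINES:
        header.info.add(tag, number, typ, desc)
    contigs = contig_lengths or {}
    for c in sorted({v.chrom for v in calls} | set(contigs)):
        header.contigs.add(c, length=contigs.get(c, 2**29))
    sid = sample_id or (calls[0].sample_id if calls else "unknown")
    rid = run_id or (calls[0].run_id if calls else "unknown")
    header.add_meta("sample_id", sid)
    header.add_meta("run_id", rid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                qual=v.quality,
            )
            rec.info["DP"] = v.depth
            if v.vaf is not None:
                rec.info["AF"] = (v.vaf,)
            if v.strand_known:
                rec.info["SAF"] = (v.alt_fwd,)
                rec.info["SAR"] = (v.alt_rev,)
            if v.predicted_deleterious:
                rec.info["PDEL"] = True
            out.write(rec)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_regions(path: str | Path, flank: int = 10) -> list[TargetRegion]:
    """Read a 3+/4-column BED into TargetRegion records, sorted by locus.

    Column 4, when present, carries the region name as ``gene|region_id``
    (or a bare region id); otherwise an id is synthesized from coordinates.
    Overlapping regions are preserved, never merged.
    """
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    regions = []
    for row in df.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}: rejected record {chrom}:{start}-{end} (start >= end)")
        name = str(row[3]) if df.shape[1] >= 4 and not pd.isna(row[3]) else ""
        if "|" in name:
            gene, region_id = name.split("|", 1)
        elif name:
            gene, region_id = "", name
        else:
            gene, region_id = "", f"{chrom}:{start}-{end}"
        regions.append(TargetRegion(region_id, gene, chrom, start, end, flank=flank))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_regions(regions: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            name = f"{r.gene}|{r.region_id}" if r.gene else r.region_id
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Read-stack fixture format (TSV)
# ---------------------------------------------------------------------------


def write_read_stack(stack: ReadStack, path: str | Path) -> None:
    """Write a read stack in the package's columnar TSV fixture format."""
    with open(path, "w") as fh:
        fh.write(f"#window\t{stack.chrom}\t{stack.start}\t{stack.reference}\n")
        for read in stack.reads:
            ins = ";".join(f"{off}:{seq}" for off, seq in sorted(read.insertions.items()))
            fh.write(f"{read.read_id}\t{read.strand}\t{read.observations}\t{ins}\n")


def read_read_stack(path: str | Path) -> ReadStack:
    with open(path) as fh:
        head = fh.readline().rstrip("\n").split("\t")
        if len(head) != 4 or head[0] != "#window":
            raise ValueError(f"{path}: missing #window header line")
        chrom, start, reference = head[1], int(head[2]), head[3]
        reads = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            read_id, strand, obs = parts[0], parts[1], parts[2]
            insertions = {}
            if len(parts) > 3 and parts[3]:
                for token in parts[3].split(";"):
                    off, seq = token.split(":")
                    insertions[int(off)] = seq
            reads.append(StackRead(read_id, strand, obs, insertions))
    return ReadStack(chrom, start, reference, reads)
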