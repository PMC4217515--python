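"""Seeded generators for panels, references, depth profiles, read stacks and
multi-sample runs with the statistical structure of targeted capture panels.

The generator emulates the features the downstream stages are built to
handle: heavy-tailed (log-normal) capture non-uniformity across regions, a
fraction of systematically failing regions (mean depth < 20 with zero-depth
stretches), germline heterozygous/homozygous variants, a low-fraction
somatic variant at deep coverage, recurrent control-cohort artifacts,
run-wide artifacts shared between samples, and homopolymer-adjacent
artifacts. Every bundle carries a truth manifest enumerating each planted
event and its intended triage outcome, so tests never re-derive intent from
data.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.default_rng`` substreams; a fixed seed yields byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    DepthProfile,
    ReadStack,
    ReferenceWindow,
    StackRead,
    TargetRegion,
    VariantCall,
    VariantKey,
    write_read_stack,
    write_regions,
    write_variants,
)
from . import triage as _triage


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedVariant:
    """A variant to plant into a read stack (VCF-style anchored alleles)."""

    region_id: str
    offset: int  # 0-based offset of the leftmost reference base within the region
    ref: str
    alt: str
    vaf: float
    strand_fraction: float = 0.5  # fraction of alt reads on the forward strand

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ConfigError("planted VAF must lie in [0, 1]")
        if not 0.0 <= self.strand_fraction <= 1.0:
            raise ConfigError("strand_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HomopolymerSpec:
    region_id: str
    offset: int
    base: str
    run_length: int


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic run bundle.

    Defaults mirror a semiconductor-sequencing capture panel: median region
    depth ~305 reads with a heavy right tail (log-normal), 1.8% of regions
    systematically failing, a 1% per-base substitution error rate, and 11
    healthy controls for background filtering.
    """

    seed: int = 0
    n_regions: int = 75
    region_length_range: tuple[int, int] = (100, 160)
    depth_lognormal_mu: float = 5.72  # ln(305)
    depth_lognormal_sigma: float = 0.7
    fraction_failing_regions: float = 0.018
    per_base_error_rate: float = 0.01
    planted_variants: tuple[PlantedVariant, ...] = ()
    homopolymer_spec: tuple[HomopolymerSpec, ...] = ()
    n_controls: int = 11
    control_artifact_sharing: tuple[int, ...] = (2, 3, 2)
    # run-composition knobs
    n_patients: int = 4
    n_homopolymer_artifacts: int = 3
    n_runwide_artifacts: int = 3
    n_singleton_control_artifacts: int = 2
    include_low_vaf_somatic: bool = True
    somatic_depth: int = 257
    somatic_vaf: float = 0.03
    clean_region_min_depth: float = 60.0
    regions_per_gene: int = 5
    region_gap: int = 30
    run_id: str = "run1"

    def __post_init__(self) -> None:
        for name in ("fraction_failing_regions", "per_base_error_rate", "somatic_vaf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.depth_lognormal_sigma < 0:
            raise ConfigError("depth_lognormal_sigma must be >= 0")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be >= 0")
        if any(n < 1 for n in self.control_artifact_sharing):
            raise ConfigError("control sharing counts must be >= 1")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


_BASES = "ACGT"


def _no_run_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random DNA avoiding homopolymer runs of length 3 or more."""
    seq: list[str] = []
    for _ in range(length):
        if len(seq) >= 2 and seq[-1] == seq[-2]:
            choices = [b for b in _BASES if b != seq[-1]]
        else:
            choices = list(_BASES)
        seq.append(choices[int(rng.integers(len(choices)))])
    return seq


def simulate_panel(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TargetRegion]]:
    """Reference sequence and target regions for a synthetic panel.

    All regions lie on one contig, separated by ``region_gap`` bases; the
    background sequence avoids homopolymer runs >= 3 so that runs exist only
    where ``homopolymer_spec`` embeds them. Returns a contig->sequence
    mapping and the region list (ids unique, genes assigned in blocks).
    """
    rng = _rng(config, 1)
    lo, hi = config.region_length_range
    if lo < 1 or hi < lo:
        raise ConfigError("invalid region_length_range")
    lengths = rng.integers(lo, hi + 1, size=config.n_regions)
    chrom = "chr1"
    regions: list[TargetRegion] = []
    cursor = config.region_gap
    for i, length in enumerate(lengths):
        gene = f"GENE{i // config.regions_per_gene + 1:03d}"
        regions.append(
            TargetRegion(f"R{i + 1:04d}", gene, chrom, cursor, cursor + int(length))
        )
        cursor += int(length) + config.region_gap
    seq = _no_run_sequence(rng, cursor)
    by_id = {r.region_id: r for r in regions}
    for spec in config.homopolymer_spec:
        region = by_id.get(spec.region_id)
        if region is None:
            raise ConfigError(f"homopolymer spec names unknown region {spec.region_id}")
        if spec.offset < 0 or spec.offset + spec.run_length > region.length:
            raise ConfigError(
                f"homopolymer run exceeds bounds of region {spec.region_id}"
            )
        start = region.start + spec.offset
        seq[start : start + spec.run_length] = spec.base * spec.run_length
        # keep the run exactly run_length long: break any accidental extension
        for edge in (start - 1, start + spec.run_length):
            if 0 <= edge < len(seq) and seq[edge] == spec.base:
                seq[edge] = next(b for b in _BASES if b != spec.base)
    return {chrom: "".join(seq)}, regions


def simulate_depth_profiles(
    config: SimulationConfig, regions: Sequence[TargetRegion]
) -> list[DepthProfile]:
    """Per-region depth profiles: log-normal region means with Poisson
    per-base jitter; ``round(fraction_failing_regions * n)`` regions are
    forced to mean depth < 20 with a zero-coverage stretch.
    """
    if not regions:
        raise ConfigError("regions must be nonempty")
    rng = _rng(config, 2)
    n = len(regions)
    means = rng.lognormal(config.depth_lognormal_mu, config.depth_lognormal_sigma, n)
    n_fail = int(round(config.fraction_failing_regions * n))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist()) if n_fail else set()
    profiles = []
    for i, region in enumerate(regions):
        length = region.length
        if i in fail_idx:
            mean = rng.uniform(2.0, 15.0)
            depths = rng.poisson(mean, length)
            frac = rng.uniform(0.12, 0.5)
            stretch = max(1, int(round(frac * length)))
            start = int(rng.integers(0, length - stretch + 1))
            depths[start : start + stretch] = 0
        else:
            depths = rng.poisson(means[i], length)
        profiles.append(DepthProfile(region.region_id, depths.astype(int).tolist()))
    return profiles


def simulate_read_stack(
    region: TargetRegion,
    window: ReferenceWindow,
    profile: DepthProfile,
    planted: Sequence[PlantedVariant] = (),
    error_rate: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> ReadStack:
    """Columnar read stack over a region window.

    Every read spans the full window. The number of reads is the rounded
    mean of the depth profile. At each planted event the alt-read count is
    Binomial(n_reads, vaf); all other positions carry substitution errors at
    ``error_rate``. Read strands are Bernoulli(0.5) unless a planted
    variant's ``strand_fraction`` overrides the strands of its alt reads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    refseq = window.seq[region.start - window.start : region.end - window.start].upper()
    length = region.length
    n = int(round(float(np.mean(profile.depths))))
    base_bytes = np.frombuffer(refseq.encode("ascii"), dtype=np.uint8)
    if n == 0:
        return ReadStack(region.chrom, region.start, refseq, [])
    mat = np.tile(base_bytes, (n, 1))

    if error_rate > 0:
        err = rng.random((n, length)) < error_rate
        if err.any():
            order = np.frombuffer(b"ACGT", dtype=np.uint8)
            idx_of = np.zeros(256, dtype=np.int64)
            for k, b in enumerate(order):
                idx_of[b] = k
            rows, cols = np.nonzero(err)
            shift = rng.integers(1, 4, size=rows.size)
            mat[rows, cols] = order[(idx_of[mat[rows, cols]] + shift) % 4]

    strands = rng.random(n) < 0.5
    insertions: dict[int, dict[int, str]] = {}
    for pv in planted:
        if pv.region_id != region.region_id:
            raise ConfigError(
                f"planted variant targets region {pv.region_id}, stack is "
                f"{region.region_id}"
            )
        if pv.offset < 0 or pv.offset + len(pv.ref) > length:
            raise ConfigError(
                f"planted position outside region {region.region_id}"
            )
        k = int(rng.binomial(n, pv.vaf))
        if k == 0:
            continue
        carriers = rng.choice(n, size=k, replace=False)
        if len(pv.ref) == 1 and len(pv.alt) == 1:
            mat[carriers, pv.offset] = ord(pv.alt)
        elif len(pv.ref) > len(pv.alt):  # deletion: gap the removed bases
            # restore the anchor base on carriers (errors there would make
            # the event a different haplotype)
            mat[carriers, pv.offset] = base_bytes[pv.offset]
            span = len(pv.ref) - len(pv.alt)
            mat[carriers[:, None], np.arange(pv.offset + 1, pv.offset + 1 + span)] = ord("-")
        else:  # insertion after the anchor base
            mat[carriers, pv.offset] = base_bytes[pv.offset]
            seq = pv.alt[len(pv.ref):]
            for c in carriers:
                insertions.setdefault(int(c), {})[pv.offset] = seq
        if pv.strand_fraction != 0.5:
            strands[carriers] = rng.random(k) < pv.strand_fraction

    reads = []
    for i in range(n):
        reads.append(
            StackRead(
                read_id=f"{region.region_id}_r{i + 1}",
                strand="+" if strands[i] else "-",
                observations=mat[i].tobytes().decode("ascii"),
                insertions=insertions.get(i, {}),
            )
        )
    return ReadStack(region.chrom, region.start, refseq, reads)


# ---------------------------------------------------------------------------
# Full run bundles
# ---------------------------------------------------------------------------

EXPECT_HIGH_CONFIDENCE = "HIGH_CONFIDENCE"
EXPECT_NEEDS_CONFIRMATION = "NEEDS_CONFIRMATION"
EXPECT_BLACKLISTED = "BLACKLISTED"
EXPECT_NOT_CALLED_DEFAULT = "NOT_CALLED_DEFAULT"


@dataclass(frozen=True)
class PlantedTruth:
    kind: str
    sample_id: str
    region_id: str
    key: VariantKey
    vaf: float
    expected: str
    blacklist_expected: bool = False


@dataclass
class RunBundle:
    config: SimulationConfig
    reference: dict[str, str]
    regions: list[TargetRegion]
    profiles: list[DepthProfile]
    patient_ids: list[str]
    control_ids: list[str]
    patient_stacks: dict[tuple[str, str], ReadStack]  # (sample_id, region_id)
    control_callsets: list[list[VariantCall]]
    truth: list[PlantedTruth]

    @property
    def run_id(self) -> str:
        return self.config.run_id

    def window(self, region: TargetRegion) -> ReferenceWindow:
        seq = self.reference[region.chrom]
        return ReferenceWindow(region.chrom, 0, seq)


def _clean_offsets(
    window: ReferenceWindow,
    region: TargetRegion,
    thresholds: _triage.TriageThresholds,
    needed: int,
) -> list[int]:
    """Offsets within the region where an SNV passes the context check."""
    radius = max(thresholds.homopolymer_min_run, thresholds.repeat_min_span)
    out = []
    refseq = window.seq
    for off in range(radius + 1, region.length - radius - 1):
        pos = region.start + off + 1
        probe = VariantCall(
            sample_id="probe", run_id="probe", chrom=region.chrom, pos=pos,
            ref=refseq[region.start + off], alt="N",
        )
        if _triage.check_context(probe, window, thresholds) is _triage.Outcome.PASS:
            out.append(off)
            if len(out) >= needed:
                break
    return out


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[int(rng.integers(len(choices)))]


def simulate_run(config: SimulationConfig = SimulationConfig()) -> RunBundle:
    """A full multi-sample run with planted truth.

    Plants one clean heterozygous SNV per patient in every adequately
    covered region, plus homopolymer-adjacent artifacts, run-wide artifacts
    (shared by two patients in the run), control-cohort artifacts shared by
    ``control_artifact_sharing`` controls each (blacklist-expected when
    shared by >= 2), singleton-control artifacts, and one low-fraction
    somatic variant at deep, fixed coverage. The truth manifest enumerates
    every planted event with its intended outcome.
    """
    thresholds = _triage.TriageThresholds()
    reference, regions = _auto_panel(config)
    profiles = simulate_depth_profiles(config, regions)
    prof_by_id = {p.region_id: p for p in profiles}
    mean_depth = {p.region_id: float(np.mean(p.depths)) for p in profiles}
    rng = _rng(config, 3)

    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    control_ids = [f"C{i + 1:02d}" for i in range(config.n_controls)]
    chrom = regions[0].chrom
    window = ReferenceWindow(chrom, 0, reference[chrom])

    hp_regions = {spec.region_id for spec in _auto_homopolymer_specs(config, regions)}
    eligible = [
        r for r in regions
        if mean_depth[r.region_id] >= config.clean_region_min_depth
        and r.region_id not in hp_regions
    ]
    if len(eligible) < 2 + config.n_runwide_artifacts + len(
        config.control_artifact_sharing
    ) + config.n_singleton_control_artifacts:
        raise ConfigError("panel too small for the requested run composition")

    offsets_by_region = {
        r.region_id: _clean_offsets(window, r, thresholds, config.n_patients + 2)
        for r in regions
    }

    planted: dict[tuple[str, str], list[PlantedVariant]] = {}
    truth: list[PlantedTruth] = []
    controls: dict[str, list[VariantCall]] = {c: [] for c in control_ids}

    def plant(sample: str, region: TargetRegion, pv: PlantedVariant) -> None:
        planted.setdefault((sample, region.region_id), []).append(pv)

    def mkkey(region: TargetRegion, off: int, ref: str, alt: str) -> VariantKey:
        return VariantKey(region.chrom, region.start + off + 1, ref, alt)

    def control_call(cid: str, key: VariantKey) -> VariantCall:
        return VariantCall(
            sample_id=cid, run_id=config.run_id, chrom=key.chrom, pos=key.pos,
            ref=key.ref, alt=key.alt, quality=45.0, depth=80,
            alt_fwd=18, alt_rev=18, predicted_deleterious=True,
        )

    cursor = 0  # walks the eligible-region list so artifact loci never collide

    # Somatic low-VAF variant at fixed deep coverage.
    if config.include_low_vaf_somatic:
        region = eligible[cursor]; cursor += 1
        prof_by_id[region.region_id] = DepthProfile(
            region.region_id, [config.somatic_depth] * region.length
        )
        mean_depth[region.region_id] = float(config.somatic_depth)
        off = offsets_by_region[region.region_id][-1]
        ref = window.seq[region.start + off]
        alt = _other_base(rng, ref)
        plant(patient_ids[0], region,
              PlantedVariant(region.region_id, off, ref, alt, config.somatic_vaf))
        truth.append(PlantedTruth(
            "low_vaf_somatic", patient_ids[0], region.region_id,
            mkkey(region, off, ref, alt), config.somatic_vaf,
            EXPECT_NOT_CALLED_DEFAULT,
        ))

    # Run-wide artifacts: same key planted in two patients of the run.
    for _ in range(config.n_runwide_artifacts):
        region = eligible[cursor]; cursor += 1
        off = offsets_by_region[region.region_id][-1]
        ref = window.seq[region.start + off]
        alt = _other_base(rng, ref)
        pair = rng.choice(config.n_patients, size=2, replace=False)
        for pi in pair:
            plant(patient_ids[pi], region,
                  PlantedVariant(region.region_id, off, ref, alt, 0.45))
            truth.append(PlantedTruth(
                "runwide_artifact", patient_ids[pi], region.region_id,
                mkkey(region, off, ref, alt), 0.45, EXPECT_NEEDS_CONFIRMATION,
            ))

    # Control-cohort artifacts, each shared by a configured number of controls.
    for i, n_sharing in enumerate(config.control_artifact_sharing):
        region = eligible[cursor]; cursor += 1
        off = offsets_by_region[region.region_id][-1]
        ref = window.seq[region.start + off]
        alt = _other_base(rng, ref)
        key = mkkey(region, off, ref, alt)
        n_sharing = min(n_sharing, config.n_controls)
        for cid in control_ids[:n_sharing]:
            controls[cid].append(control_call(cid, key))
        patient = patient_ids[i % config.n_patients]
        plant(patient, region, PlantedVariant(region.region_id, off, ref, alt, 0.45))
        blacklisted = n_sharing > 1
        truth.append(PlantedTruth(
            "control_artifact" if blacklisted else "singleton_control_artifact",
            patient, region.region_id, key, 0.45,
            EXPECT_BLACKLISTED if blacklisted else EXPECT_NEEDS_CONFIRMATION,
            blacklist_expected=blacklisted,
        ))

    # Artifacts carried by exactly one control: never blacklisted, but the
    # wild-type-control criterion must still exclude them.
    for i in range(config.n_singleton_control_artifacts):
        if not control_ids:
            break
        region = eligible[cursor]; cursor += 1
        off = offsets_by_region[region.region_id][-1]
        ref = window.seq[region.start + off]
        alt = _other_base(rng, ref)
        key = mkkey(region, off, ref, alt)
        cid = control_ids[(i + len(config.control_artifact_sharing)) % len(control_ids)]
        controls[cid].append(control_call(cid, key))
        patient = patient_ids[(i + 1) % config.n_patients]
        plant(patient, region, PlantedVariant(region.region_id, off, ref, alt, 0.45))
        truth.append(PlantedTruth(
            "singleton_control_artifact", patient, region.region_id, key, 0.45,
            EXPECT_NEEDS_CONFIRMATION,
        ))

    # Homopolymer-adjacent artifacts.
    for spec in _auto_homopolymer_specs(config, regions):
        region = next(r for r in regions if r.region_id == spec.region_id)
        if mean_depth[region.region_id] < 20:
            continue
        off = spec.offset + spec.run_length  # abuts the 3' end of the run
        if off + 1 >= region.length:
            continue
        ref = window.seq[region.start + off]
        alt = _other_base(rng, ref)
        patient = patient_ids[int(rng.integers(config.n_patients))]
        plant(patient, region, PlantedVariant(region.region_id, off, ref, alt, 0.45))
        truth.append(PlantedTruth(
            "homopolymer_artifact", patient, region.region_id,
            mkkey(region, off, ref, alt), 0.45, EXPECT_NEEDS_CONFIRMATION,
        ))

    artifact_regions = {region_id for (_, region_id) in planted}

    # Clean heterozygous germline SNVs: one per patient per adequately
    # covered artifact-free region, each with a distinct key.
    for region in eligible[cursor:]:
        if region.region_id in artifact_regions:
            continue
        offs = offsets_by_region[region.region_id]
        if len(offs) < config.n_patients:
            continue
        for pi, patient in enumerate(patient_ids):
            off = offs[pi]
            ref = window.seq[region.start + off]
            alt = _other_base(rng, ref)
            plant(patient, region, PlantedVariant(region.region_id, off, ref, alt, 0.5))
            truth.append(PlantedTruth(
                "clean_snv", patient, region.region_id,
                mkkey(region, off, ref, alt), 0.5, EXPECT_HIGH_CONFIDENCE,
            ))

    # Simulate every patient stack with a per-(sample, region) substream.
    stacks: dict[tuple[str, str], ReadStack] = {}
    for si, patient in enumerate(patient_ids):
        for ri, region in enumerate(regions):
            sub = np.random.default_rng([config.seed, 100 + si, ri])
            stacks[(patient, region.region_id)] = simulate_read_stack(
                region, window, prof_by_id[region.region_id],
                planted.get((patient, region.region_id), ()),
                config.per_base_error_rate, sub,
            )

    profiles = [prof_by_id[r.region_id] for r in regions]
    return RunBundle(
        config=config,
        reference=reference,
        regions=regions,
        profiles=profiles,
        patient_ids=patient_ids,
        control_ids=control_ids,
        patient_stacks=stacks,
        control_callsets=[controls[c] for c in control_ids],
        truth=truth,
    )


def _auto_homopolymer_specs(
    config: SimulationConfig, regions: Sequence[TargetRegion]
) -> tuple[HomopolymerSpec, ...]:
    """Deterministic homopolymer placements when none are configured."""
    if config.homopolymer_spec:
        return config.homopolymer_spec
    specs = []
    step = max(1, len(regions) // max(1, config.n_homopolymer_artifacts))
    for k in range(config.n_homopolymer_artifacts):
        idx = (k * step + step // 2) % len(regions)
        region = regions[idx]
        offset = region.length // 2
        run_length = 6
        if offset + run_length + 10 > region.length:
            offset = max(1, region.length - run_length - 11)
        specs.append(HomopolymerSpec(region.region_id, offset, "ACGT"[k % 4], run_length))
    return tuple(specs)


def _auto_panel(config: SimulationConfig):
    """Panel with the auto-generated homopolymer specs embedded."""
    specs = _auto_homopolymer_specs(
        config, simulate_panel(replace(config, homopolymer_spec=()))[1]
    )
    return simulate_panel(replace(config, homopolymer_spec=specs))


# ---------------------------------------------------------------------------
# On-disk bundle layout
# ---------------------------------------------------------------------------


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_depth_profiles(profiles: Sequence[DepthProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tdepths\n")
        for p in profiles:
            fh.write(f"{p.region_id}\t{','.join(str(d) for d in p.depths)}\n")


def read_depth_profiles(path: str | Path) -> list[DepthProfile]:
    profiles = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("region_id"):
            raise ValueError(f"{path}: missing depth-profile header")
        for line in fh:
            region_id, depths = line.rstrip("\n").split("\t")
            profiles.append(
                DepthProfile(region_id, [int(d) for d in depths.split(",")])
            )
    return profiles


def write_truth_manifest(truth: Sequence[PlantedTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "kind\tsample_id\tregion_id\tchrom\tpos\tref\talt\tvaf\texpected\t"
            "blacklist_expected\n"
        )
        for t in truth:
            fh.write(
                f"{t.kind}\t{t.sample_id}\t{t.region_id}\t{t.key.chrom}\t"
                f"{t.key.pos}\t{t.key.ref}\t{t.key.alt}\t{t.vaf}\t{t.expected}\t"
                f"{int(t.blacklist_expected)}\n"
            )


def read_truth_manifest(path: str | Path) -> list[PlantedTruth]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (kind, sample_id, region_id, chrom, pos, ref, alt, vaf, expected,
             bl) = line.rstrip("\n").split("\t")
            out.append(PlantedTruth(
                kind, sample_id, region_id, VariantKey(chrom, int(pos), ref, alt),
                float(vaf), expected, bool(int(bl)),
            ))
    return out


def write_bundle(bundle: RunBundle, outdir: str | Path) -> None:
    """Write a run bundle (FASTA, BED, depth TSV, stacks, control VCFs,
    truth manifest) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.reference, outdir / "reference.fa")
    write_regions(bundle.regions, outdir / "regions.bed")
    write_depth_profiles(bundle.profiles, outdir / "profiles.tsv")
    write_truth_manifest(bundle.truth, outdir / "truth_manifest.tsv")
    stacks_dir = outdir / "stacks"
    stacks_dir.mkdir(exist_ok=True)
    for (sample, region_id), stack in sorted(bundle.patient_stacks.items()):
        write_read_stack(stack, stacks_dir / f"{sample}_{region_id}.tsv")
    controls_dir = outdir / "controls"
    controls_dir.mkdir(exist_ok=True)
    contigs = {c: len(s) for c, s in bundle.reference.items()}
    for cid, calls in zip(bundle.control_ids, bundle.control_callsets):
        write_variants(
            calls, controls_dir / f"{cid}.vcf", contig_lengths=contigs,
            sample_id=cid, run_id=bundle.run_id,
        )
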