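"""End-to-end orchestration: call -> background-filter -> triage -> coverage.

Works either on an in-memory :class:`~paneltriage.synthetic_data.RunBundle`
(`analyze_bundle`) or on an on-disk bundle directory described by a
:class:`PipelineConfig` (`run_pipeline`). Outputs are deterministic given the
inputs and carry a config hash in their headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import background_filter as bgf
from . import coverage_qc as cov
from . import triage as tri
from .data_model import (
    ReferenceWindow,
    TargetRegion,
    VariantCall,
    read_read_stack,
    read_regions,
    read_variants,
    write_variants,
)
from .pileup_caller import CallerSettings, call_variants
from .synthetic_data import RunBundle, read_depth_profiles

logger = logging.getLogger("paneltriage")


@dataclass
class PipelineResult:
    blacklist: bgf.Blacklist
    raw_calls: dict[str, list[VariantCall]]
    kept: dict[str, list[VariantCall]]
    removed: dict[str, list[VariantCall]]
    verdicts: dict[str, list[tri.TriageVerdict]]
    coverage: cov.CoverageReport

    def verdict_for(self, sample_id: str, key) -> Optional[tri.TriageVerdict]:
        for v in self.verdicts.get(sample_id, []):
            if v.key == str(key):
                return v
        return None


def analyze_bundle(
    bundle: RunBundle,
    settings: CallerSettings = CallerSettings(),
    thresholds: tri.TriageThresholds = tri.TriageThresholds(),
) -> PipelineResult:
    """Run calling, blacklist filtering, triage, and coverage QC on a bundle."""
    region_by_id = {r.region_id: r for r in bundle.regions}

    raw: dict[str, list[VariantCall]] = {p: [] for p in bundle.patient_ids}
    call_region: dict[tuple[str, str], str] = {}
    for (sample, region_id), stack in sorted(bundle.patient_stacks.items()):
        calls = call_variants(stack, settings, sample_id=sample, run_id=bundle.run_id)
        raw[sample].extend(calls)
        for c in calls:
            call_region[(sample, str(c.key))] = region_id
    logger.info("called %d variants across %d samples",
                sum(len(v) for v in raw.values()), len(raw))

    blacklist = bgf.build_blacklist(bundle.control_callsets)
    kept: dict[str, list[VariantCall]] = {}
    removed: dict[str, list[VariantCall]] = {}
    for sample, calls in raw.items():
        kept[sample], removed[sample] = bgf.apply_blacklist(calls, blacklist)
    logger.info("blacklist of %d keys removed %d calls", len(blacklist),
                sum(len(v) for v in removed.values()))

    verdicts: dict[str, list[tri.TriageVerdict]] = {}
    for sample in bundle.patient_ids:
        runmates = [kept[other] for other in bundle.patient_ids if other != sample]
        verdicts[sample] = []
        for call in kept[sample]:
            region_id = call_region.get((sample, str(call.key)))
            region = region_by_id.get(region_id) if region_id else None
            inputs = tri.TriageInputs(
                window=bundle.window(region) if region else None,
                stack=bundle.patient_stacks.get((sample, region_id)) if region_id else None,
                controls=bundle.control_callsets,
                runmates=runmates,
            )
            verdicts[sample].append(tri.classify(call, thresholds, inputs))

    stats = [
        cov.region_stats(p, gene=region_by_id[p.region_id].gene)
        for p in bundle.profiles
    ]
    report = cov.coverage_report(stats, bundle.regions)
    return PipelineResult(blacklist, raw, kept, removed, verdicts, report)


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and settings for a file-based pipeline run."""

    bundle_dir: Path
    out_dir: Path
    seed: int = 0
    caller: CallerSettings = field(default_factory=CallerSettings)
    thresholds: tri.TriageThresholds = field(default_factory=tri.TriageThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            bundle_dir=Path(raw["bundle_dir"]),
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            caller=CallerSettings(**raw.get("caller", {})),
            thresholds=tri.TriageThresholds(**raw.get("thresholds", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        required = ["reference.fa", "regions.bed", "profiles.tsv", "stacks", "controls"]
        missing = [n for n in required if not (self.bundle_dir / n).exists()]
        if missing:
            raise FileNotFoundError(
                f"bundle at {self.bundle_dir} is missing: {', '.join(missing)}"
            )

    def config_hash(self) -> str:
        payload = {
            "bundle_dir": str(self.bundle_dir),
            "seed": self.seed,
            "caller": vars(self.caller) if hasattr(self.caller, "__dict__") else str(self.caller),
            "thresholds": str(self.thresholds),
        }
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_bundle_dir(bundle_dir: str | Path) -> RunBundle:
    """Reconstruct a RunBundle from the on-disk layout of ``write_bundle``."""
    from pyfaidx import Fasta

    from .synthetic_data import SimulationConfig, read_truth_manifest

    bundle_dir = Path(bundle_dir)
    ref_path = bundle_dir / "reference.fa"
    if not ref_path.exists():
        raise FileNotFoundError(f"missing reference FASTA: {ref_path}")
    fasta = Fasta(str(ref_path))
    reference = {name: str(fasta[name][:]) for name in fasta.keys()}
    regions = read_regions(bundle_dir / "regions.bed")
    profiles = read_depth_profiles(bundle_dir / "profiles.tsv")
    stacks = {}
    samples = set()
    for path in sorted((bundle_dir / "stacks").glob("*.tsv")):
        sample, region_id = path.stem.split("_", 1)
        stacks[(sample, region_id)] = read_read_stack(path)
        samples.add(sample)
    control_callsets = []
    control_ids = []
    for path in sorted((bundle_dir / "controls").glob("*.vcf")):
        calls = read_variants(path)
        control_callsets.append(calls)
        control_ids.append(calls[0].sample_id if calls else path.stem)
    truth_path = bundle_dir / "truth_manifest.tsv"
    truth = read_truth_manifest(truth_path) if truth_path.exists() else []
    return RunBundle(
        config=SimulationConfig(),
        reference=reference,
        regions=regions,
        profiles=profiles,
        patient_ids=sorted(samples),
        control_ids=control_ids,
        patient_stacks=stacks,
        control_callsets=control_callsets,
        truth=truth,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline: load bundle, analyze, write the artifact set.

    Outputs under ``config.out_dir``: per-sample filtered VCFs, a triage TSV,
    the clinical coverage report, a blacklist BED, and a JSON summary. Every
    text output carries a header with the config hash and seed.
    """
    config.validate()
    bundle = load_bundle_dir(config.bundle_dir)
    result = analyze_bundle(bundle, config.caller, config.thresholds)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    contigs = {c: len(s) for c, s in bundle.reference.items()}

    for sample in bundle.patient_ids:
        write_variants(
            result.kept[sample], out / f"{sample}.filtered.vcf",
            contig_lengths=contigs, sample_id=sample, run_id=bundle.run_id,
        )
    bgf.write_blacklist(result.blacklist, out / "blacklist.bed")

    rows = []
    for sample in bundle.patient_ids:
        df = tri.verdicts_table(result.verdicts[sample])
        df.insert(0, "sample_id", sample)
        rows.append(df)
    import pandas as pd

    triage_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["sample_id", "key", "class"])
    )
    with open(out / "triage.tsv", "w") as fh:
        fh.write(stamp)
        triage_df.to_csv(fh, sep="\t", index=False)

    with open(out / "coverage_report.txt", "w") as fh:
        fh.write(stamp)
        fh.write(result.coverage.to_text())

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(bundle.patient_ids),
        "n_raw_calls": sum(len(v) for v in result.raw_calls.values()),
        "n_blacklist": len(result.blacklist),
        "n_removed": sum(len(v) for v in result.removed.values()),
        "n_high_confidence": sum(
            sum(v.final is tri.TriageClass.HIGH_CONFIDENCE for v in vs)
            for vs in result.verdicts.values()
        ),
        "coverage": {
            "n_regions": result.coverage.summary.n_regions,
            "n_flagged": result.coverage.summary.n_flagged,
            "n_unreliable": result.coverage.summary.n_unreliable,
            "pct_unreliable": result.coverage.summary.pct_unreliable,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
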