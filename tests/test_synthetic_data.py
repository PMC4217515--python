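import numpy as np
import pytest

from paneltriage.data_model import DepthProfile, ReferenceWindow, TargetRegion
from paneltriage.pileup_caller import call_variants
from paneltriage.synthetic_data import (
    ConfigError,
    HomopolymerSpec,
    PlantedVariant,
    SimulationConfig,
    simulate_depth_profiles,
    simulate_panel,
    simulate_read_stack,
    simulate_run,
    write_bundle,
)


class TestSimulatePanel:
    def test_homopolymer_embedded_verbatim(self):
        cfg = SimulationConfig(
            seed=4, n_regions=2,
            homopolymer_spec=(HomopolymerSpec("R0001", 10, "A", 6),),
        )
        reference, regions = simulate_panel(cfg)
        region = regions[0]
        seq = reference[region.chrom][region.start : region.end]
        assert seq[10:16] == "AAAAAA"
        # the run is exactly six bases
        assert seq[9] != "A" and seq[16] != "A"

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=11, n_regions=5)
        assert simulate_panel(cfg) == simulate_panel(cfg)

    def test_hundred_regions_unique_ids(self):
        cfg = SimulationConfig(seed=1, n_regions=100)
        _, regions = simulate_panel(cfg)
        assert len(regions) == 100
        assert len({r.region_id for r in regions}) == 100

    def test_background_avoids_homopolymer_runs(self):
        reference, _ = simulate_panel(SimulationConfig(seed=2, n_regions=10))
        seq = reference["chr1"]
        assert all(base * 3 not in seq for base in "ACGT")

    def test_out_of_bounds_homopolymer_rejected(self):
        cfg = SimulationConfig(
            seed=4, n_regions=1, region_length_range=(50, 50),
            homopolymer_spec=(HomopolymerSpec("R0001", 48, "A", 6),),
        )
        with pytest.raises(ConfigError, match="bounds"):
            simulate_panel(cfg)


class TestDepthProfiles:
    def test_no_failing_regions_at_zero_fraction_and_zero_sigma(self):
        cfg = SimulationConfig(
            seed=3, n_regions=50, fraction_failing_regions=0.0,
            depth_lognormal_mu=float(np.log(300)), depth_lognormal_sigma=0.0,
        )
        _, regions = simulate_panel(cfg)
        profiles = simulate_depth_profiles(cfg, regions)
        assert sum(float(np.mean(p.depths)) < 20 for p in profiles) == 0

    def test_failing_fraction_matches_panel_scale(self):
        cfg = SimulationConfig(seed=5, n_regions=2455, fraction_failing_regions=0.018)
        _, regions = simulate_panel(cfg)
        profiles = simulate_depth_profiles(cfg, regions)
        n_fail = sum(float(np.mean(p.depths)) < 20 for p in profiles)
        assert n_fail == pytest.approx(44, abs=6)  # round(0.018 * 2455) forced

    def test_profiles_reproducible(self):
        cfg = SimulationConfig(seed=6, n_regions=20)
        _, regions = simulate_panel(cfg)
        a = simulate_depth_profiles(cfg, regions)
        b = simulate_depth_profiles(cfg, regions)
        assert all(x.depths == y.depths for x, y in zip(a, b))

    def test_profile_length_matches_region(self):
        cfg = SimulationConfig(seed=6, n_regions=10)
        _, regions = simulate_panel(cfg)
        for region, profile in zip(regions, simulate_depth_profiles(cfg, regions)):
            assert len(profile.depths) == region.length

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, depth_lognormal_sigma=-0.5)


def _toy_region(length=40, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    region = TargetRegion("R1", "G", "chr1", 0, length)
    return region, ReferenceWindow("chr1", 0, seq)


class TestReadStack:
    def test_vaf_one_no_errors_every_read_carries_alt(self):
        region, window = _toy_region()
        profile = DepthProfile("R1", [30] * region.length)
        alt = "A" if window.seq[20] != "A" else "C"
        pv = PlantedVariant("R1", 20, window.seq[20], alt, 1.0)
        stack = simulate_read_stack(region, window, profile, [pv], 0.0, 1)
        assert all(r.observations[20] == alt for r in stack.reads)

    def test_no_errors_no_variant_stack_is_reference(self):
        region, window = _toy_region()
        profile = DepthProfile("R1", [25] * region.length)
        stack = simulate_read_stack(region, window, profile, [], 0.0, 1)
        assert all(r.observations == window.seq for r in stack.reads)

    def test_binomial_alt_count_expectation(self):
        """Mean alt reads over seeded replicates approximates depth x VAF."""
        region, window = _toy_region(length=24)
        profile = DepthProfile("R1", [257] * region.length)
        alt = "A" if window.seq[12] != "A" else "C"
        pv = PlantedVariant("R1", 12, window.seq[12], alt, 0.03)
        counts = []
        for rep in range(1000):
            stack = simulate_read_stack(
                region, window, profile, [pv], 0.0, np.random.default_rng([8, rep])
            )
            counts.append(sum(r.observations[12] == alt for r in stack.reads))
        assert np.mean(counts) == pytest.approx(257 * 0.03, abs=0.3)

    def test_planted_position_outside_region_rejected(self):
        region, window = _toy_region()
        profile = DepthProfile("R1", [30] * region.length)
        pv = PlantedVariant("R1", 39, "AA", "A", 0.5)  # ref spills past the end
        with pytest.raises(ConfigError, match="outside"):
            simulate_read_stack(region, window, profile, [pv], 0.0, 1)

    def test_strand_fraction_override(self):
        region, window = _toy_region()
        profile = DepthProfile("R1", [200] * region.length)
        alt = "A" if window.seq[20] != "A" else "C"
        pv = PlantedVariant("R1", 20, window.seq[20], alt, 0.5, strand_fraction=1.0)
        stack = simulate_read_stack(region, window, profile, [pv], 0.0, 1)
        alt_reads = [r for r in stack.reads if r.observations[20] == alt]
        assert alt_reads and all(r.strand == "+" for r in alt_reads)

    def test_planted_recovery_at_germline_conditions(self):
        """VAF-0.5 SNVs at mean depth 100 and 1% error are recovered >=99%
        of the time by the caller across seeded replicates."""
        region, window = _toy_region(length=30, seed=9)
        profile = DepthProfile("R1", [100] * region.length)
        alt = "A" if window.seq[15] != "A" else "C"
        pv = PlantedVariant("R1", 15, window.seq[15], alt, 0.5)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            stack = simulate_read_stack(
                region, window, profile, [pv], 0.01, np.random.default_rng([3, rep])
            )
            calls = call_variants(stack)
            hits += any((c.pos, c.alt) == (16, alt) for c in calls)
        assert hits / n_rep >= 0.99


class TestSimulateRun:
    def test_artifact_sharing_drives_blacklist_expectation(self):
        cfg = SimulationConfig(
            seed=13, n_regions=40, n_controls=3,
            control_artifact_sharing=(2, 1), n_runwide_artifacts=1,
            n_singleton_control_artifacts=0, n_homopolymer_artifacts=1,
        )
        bundle = simulate_run(cfg)
        shared = [t for t in bundle.truth if t.kind == "control_artifact"]
        single = [t for t in bundle.truth if t.kind == "singleton_control_artifact"]
        assert len(shared) == 1 and shared[0].blacklist_expected
        assert len(single) == 1 and not single[0].blacklist_expected
        carriers = {
            t.key: sum(any(c.key == t.key for c in cs) for cs in bundle.control_callsets)
            for t in shared + single
        }
        assert carriers[shared[0].key] == 2
        assert carriers[single[0].key] == 1

    def test_zero_artifacts_configured_empty_expected_blacklist(self):
        cfg = SimulationConfig(
            seed=14, n_regions=30, control_artifact_sharing=(),
            n_runwide_artifacts=0, n_singleton_control_artifacts=0,
            n_homopolymer_artifacts=0, include_low_vaf_somatic=False,
        )
        bundle = simulate_run(cfg)
        assert not any(t.blacklist_expected for t in bundle.truth)
        assert all(t.kind == "clean_snv" for t in bundle.truth)

    def test_bundle_deterministic_and_bytes_identical_on_disk(self, tmp_path):
        cfg = SimulationConfig(seed=15, n_regions=12, n_patients=2, n_controls=3,
                               n_runwide_artifacts=1, n_homopolymer_artifacts=1,
                               control_artifact_sharing=(2,),
                               n_singleton_control_artifacts=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(simulate_run(cfg), d1)
        write_bundle(simulate_run(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_truth_manifest_covers_every_planted_event(self, small_bundle):
        planted_keys = {
            (t.sample_id, t.key) for t in small_bundle.truth
        }
        assert len(planted_keys) == len(small_bundle.truth)  # no duplicates
        kinds = {t.kind for t in small_bundle.truth}
        assert "clean_snv" in kinds and "low_vaf_somatic" in kinds
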