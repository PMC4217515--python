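# Methods

This note documents the models and procedures implemented in `paneltriage`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Problem setting

Targeted gene-panel sequencing for primary immunodeficiencies captures the
coding exons (plus ~10 flanking bases) of ~170 genes and sequences them on a
semiconductor platform. Capture depth is strongly non-uniform across
regions, a small fraction of regions fails systematically, and the dominant
artifact modes are homopolymer-context miscalls, recurrent platform-specific
false positives, and run-wide batch artifacts. The pipeline's decision layer
must (a) call germline variants permissively enough to avoid false
negatives, (b) subtract recurrent artifacts learned from healthy controls,
(c) decide which surviving single-nucleotide variants are trustworthy
without orthogonal confirmation, and (d) report coverage gaps so that
clinically relevant regions with inadequate data are never silently passed.

## Pileup caller

Read evidence is represented as a *read stack*: per-read columnar allele
observations over a region window (base, deletion gap, or insertion string
per position). This deliberately abstracts away alignment; it is sufficient
for every downstream computation while keeping simulation desk-scale.

A candidate event (alternate base per column; identical deletion runs or
insertion strings across reads) is emitted when all predicates hold:

* depth ≥ 6 reads (SNV) / 15 (INDEL) at the event's anchor column;
* alt-supporting reads per strand ≥ 0 (SNV) / 5 (INDEL);
* variant score ≥ 10 Phred, where
  `score = −10·log10 P[Binomial(depth, ε) ≥ alt_count]`, capped at 4000.
  For SNV candidates ε is the *per-allele* substitution rate — one third of
  the per-base error rate (default 0.01), since a substitution error lands
  on one of three alternate bases; indel candidates use the full per-base
  rate. The per-base error rate is a caller setting, not an estimate from
  the data;
* variant allele frequency ≥ 0.1. This cutoff can be disabled
  (`min_allele_freq=None`), the re-analysis mode that recovers low-fraction
  somatic events such as reversion mutations (e.g. 3% VAF at 257× yields
  ~7.7 expected alt reads, far below the 10% cutoff but well above the score
  threshold);
* strand bias ≤ 0.95 (SNV) / 0.85 (INDEL), where bias is the majority-strand
  fraction of alt reads. A raw ratio ceiling over-rejects sparse evidence
  (three alt reads land on one strand 25% of the time under fair sampling),
  so the rejection additionally requires the strand split to be
  statistically inconsistent with Bernoulli(0.5) — a two-sided binomial test
  at α = 0.05 (`strand_bias_alpha`). At the evidence levels where a ratio
  ceiling is meaningful (≥ 20 alt reads) the test is essentially always
  significant when the ratio is exceeded, so the classical behaviour is
  preserved.

All thresholds are inclusive (≥ passes a minimum, ≤ passes a ceiling), and
tightening any single threshold can only shrink the call set — this
monotonicity is property-tested. Emitted calls are left-aligned and trimmed
to minimal representation. No claim of equivalence with any proprietary
caller is made; the score and bias laws are this package's own, chosen as
the simplest Phred-compatible formulations.

## Variant normalization

INDEL notation from callers is frequently non-canonical. `normalize_variant`
right-trims shared suffix bases (extending left with the preceding reference
base when an allele would empty), then left-trims shared prefixes, yielding
the leftmost minimal representation. The operation is idempotent and is
verified against a brute-force oracle that enumerates *every* anchored
representation of a deletion/insertion haplotype in windows ≤ 30 bp and
checks that all members of an equivalence class collapse to a single,
leftmost key. All identity-sensitive operations (blacklist matching, cohort
checks, concordance) work on normalized keys.

## Background filter

A variant enters the blacklist iff it is annotated predicted-deleterious and
appears as a called variant in **more than one** healthy control, regardless
of VAF or quality in the control ("presence" is what the filter acts on, not
strength). Deleteriousness is an input annotation, never computed here.
Matching against patient calls is exact on the normalized
(chrom, pos, ref, alt) key; positional-only matching was rejected because it
would erase true patient alleles at polymorphic sites. The blacklist
serializes as 4+-column BED with the key in column 4 (BED geometry alone
cannot carry allele identity) and the control carrier count in column 5.

## Triage

Eight criteria, each scored pass / fail / not-evaluable:

| criterion         | rule (defaults)                                      |
|-------------------|------------------------------------------------------|
| quality           | Phred q ≥ 30                                         |
| depth             | total reads ≥ 20                                     |
| vaf               | allele frequency ≥ 25%                               |
| not_in_controls   | key absent from every wild-type control call set     |
| not_in_runmates   | key absent from other samples in the same run        |
| no_read_covariants| alt-carrying reads share no second non-reference signal |
| context           | no homopolymer run (≥ 4 bases) or short tandem repeat (unit ≤ 3 spanning ≥ 8 bases) overlapping or within 1 base of the variant footprint |
| is_snv            | every INDEL requires independent confirmation        |

HIGH_CONFIDENCE requires every criterion to pass; a fail **or a
not-evaluable** outcome (missing stack, window, or cohort data) forces
NEEDS_CONFIRMATION — missing evidence never upgrades a call, the
conservative posture appropriate for clinical reporting. Verdicts name the
failing criteria exactly, as an audit contract. Thresholds are inclusive at
the boundary (q = 30, depth = 20, VAF = 25% passes). Separately, a call with
VAF below the germline threshold but ≥ 3 alt reads carries a
`somatic_suspect` flag directing manual alignment inspection; germline-depth
panels cannot call such variants reliably, so this is an annotation, not a
verdict.

Two context parameters are this package's quantification of "homopolymer run
or repeat region": minimum run 4 and repeat span 8 with unit ≤ 3, chosen to
catch the semiconductor-sequencing failure mode while leaving ordinary
sequence untouched; both are exposed in `TriageThresholds`, as is the
adjacency distance (default 1 base, the literal reading of "immediately
adjacent").

The co-variant check tolerates scattered sequencing errors: a secondary
mismatch disqualifies a variant only when shared by ≥ 2 alt reads **and** by
≥ 20% of them (`covariant_min_reads`, `covariant_min_fraction`). A true cis
co-variant sits near 100% of alt reads while independent errors at a 1%
per-base rate essentially never co-occur at 20% of reads; a pure
"ignore-singletons" rule, by contrast, would disqualify most true variants
at realistic depths (at 300×, two same-base errors in one column somewhere
in a 100-bp window are more likely than not). Setting the fraction to 0
recovers the singleton-only rule.

## Coverage QC

Per region: `mean_depth` is the arithmetic mean of per-base depths;
`pct_covered` is the percentage of bases with depth ≥ `covered_min_depth`
(default 1; the per-base cutoff is a reporting convention, exposed because
different laboratories use different values). Two distinct labels follow,
with strict inequalities:

* **flagged** — mean depth < 20 **or** pct < 100; the clinical-report set;
* **unreliable** — mean depth < 20 **and** pct < 90; regions that cannot be
  reliably sequenced.

`unreliable ⊆ flagged` holds by construction and is asserted. The panel
summary reports the unreliable percentage to one decimal (45 of 2455 regions
→ 1.8%). Gene roll-ups are length-weighted means of region percentages by
default; a uniform (per-region) mode is provided because reference gene
tables are sometimes sample-averaged, and the two can differ. A gene is
*suboptimal* when below 90% **and** more than 5 points under its
design-expected coverage. The clinical report lists every flagged region
(stable-sorted by gene and interval for diffability) and raises a prominent
warning when a user-supplied hotspot interval falls in a failed region.

## Concordance

The evaluation domain is the set of reference positions inside the
Sanger-interrogated intervals that also lie within exons padded by
`exon_flank_keep` (default 5) bases — intronic positions beyond ±5 are
excluded because 10-base capture flanks do not detect them reliably. Each
evaluated position contributes exactly one count: TP when a normalized key
is present in both call sets, FN for truth-only, FP for NGS-only, TN
otherwise, so `tp+fn+tn+fp` equals the domain size. Multi-base events match
at variant level (normalized keys identical) and occupy their anchor
position. TN accounting is therefore per interrogated reference base
excluding variant sites; the convention is stated here because reference
confusion tables built from tens of samples of Sanger amplicons (~59k TN
bases) depend on it. Metrics: sensitivity = 100·tp/(tp+fn),
specificity = 100·tn/(tn+fp), with the complementary FN/FP rates; the exact
identities sensitivity + fn_rate = 100 and specificity + fp_rate = 100 are
asserted before rounding (3-decimal default, 1-decimal display mode).

## Protocol comparison

Paired design: the same regions measured under two hybridization protocols.
Reported per metric (mean depth, percent coverage): median, quartiles
(linear interpolation), min/max per arm, optimized-minus-default deltas,
flag counts under the coverage rule, the regions whose coverage decreased,
and a descriptive linear regression (slope/intercept/R²) of the paired
scatter.

The Wilcoxon signed-rank test follows the classical convention: zero
differences dropped, mid-ranks for ties, V = sum of positive-difference
ranks, two-sided p. For n ≤ 25 the null distribution is computed exactly by
dynamic programming over doubled ranks (doubling keeps mid-ranks integral;
2^25 sign assignments are never enumerated explicitly), and the p-value is
2·min(P[V ≤ v], P[V ≥ v]) capped at 1. For larger n a normal approximation
with tie correction (variance reduced by Σ(t³−t)/48) and continuity
correction is used. The exact branch is verified against an exhaustive
sign-flip enumeration at n ≤ 10 and against an independent implementation on
tie-free data; the two branches agree within 10% relative p at the n = 25
switchover for non-extreme effects (in far tails any normal approximation's
relative error grows, a standard limitation).

## Cost model

Sanger reagent cost is linear in amplicons (default $10 each); the NGS panel
is a flat $580 per sample. The comparison flips exactly at the break-even
count, the smallest n with 10n > 580, i.e. 59 (58 amplicons ties at $580).
Labor is excluded — it dominates true costs but is not a reagent — though a
multiplier hook exists, default off. Known-family single-variant testing is
a 1-amplicon panel. The packaged panel fixture notes one internal
inconsistency: the SCID gene list reconciles with
its stated total (199 amplicons) only without AK2's 18, and the fixture
follows the stated total.

## Synthetic data

`SimulationConfig` defaults are the study conditions, not tuning knobs:

| parameter                  | default      | rationale                        |
|----------------------------|--------------|----------------------------------|
| depth law                  | log-normal, μ = ln 305, σ = 0.7 | heavy-tailed capture non-uniformity; median region depth ~305 reads |
| fraction_failing_regions   | 0.018        | systematically failing regions (forced mean < 20 with a zero stretch); the count is `round(f·n)` so full-size panels reproduce the reference failure rate deterministically |
| per_base_error_rate        | 0.01         | substitution errors only          |
| n_controls                 | 11           | background-filter cohort size     |
| n_patients                 | 4            | one sequencing run                |
| n_regions                  | 75           | desk-scale panel (~250 planted events) |
| region length              | 100–160 bp   | exon-sized targets                |
| somatic case               | VAF 0.03 at 257× | the low-fraction reversion scenario |
| clean_region_min_depth     | 60           | clean germline variants are planted only in adequately covered regions, so their intended verdict is well-defined |

The generated reference avoids homopolymer runs ≥ 3 except where
`homopolymer_spec` embeds them, so sequence context is controlled; clean
variants are planted at offsets that pass the context check (the generator
uses the same checker that triage uses — "clean" is defined, not hoped for).
Planted alt-read counts are Binomial(depth, VAF); strands Bernoulli(0.5)
with an optional per-variant override. Run bundles plant, per the truth
manifest: clean heterozygous SNVs (one per patient per eligible region,
distinct keys so run-mate checks stay independent), homopolymer-adjacent
artifacts, run-wide artifacts (same key in two patients), control-cohort
artifacts shared by a configured number of controls (blacklist-expected when
≥ 2), singleton-control artifacts, and the low-VAF somatic case with its
depth profile pinned at 257×. Control call sets are constructed directly
(they are consumed only as call sets); full read stacks are simulated for
patients. All randomness flows from the seed through named substreams;
fixed seed ⇒ byte-identical bundles on disk.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: flow-space/phasing error structure, indel error
modes, base-quality distributions (one Phred score per call), read-length
geometry and partial-region reads (all reads span their window; per-base
depth variation lives in the separate depth profiles), mapping ambiguity,
pseudogene cross-mapping, GC-driven coverage bias (failing regions are
selected at random, not by sequence), and CNVs. Recovery rates measured here
are therefore upper bounds on real-data performance of the *decision rules*,
not of an end-to-end wet-lab assay.

## Numerical and degenerate-input conventions

* Variant score at underflowing tails → capped at Phred 4000; zero depth is
  an error, zero alt reads scores 0.
* Strand bias with zero alt reads → not evaluable; in triage, not-evaluable
  blocks HIGH_CONFIDENCE; in the caller a candidate requires alt reads, so
  the case does not arise.
* Empty read stack → empty call set (not an error); empty depth profile →
  error.
* Wilcoxon with all-zero differences → explicit `NotComputable`, surfaced as
  an absent test result in reports.
* Concordance with empty denominators → `None` metrics, never 0/0.
* All report orderings are deterministic (sorted by locus or gene/interval);
  pipeline outputs embed a config hash and seed.

## Problem sizes

Default test-suite and acceptance problem sizes were chosen so the entire
suite runs in well under a minute of compute apart from the run-bundle
analyses (~15 s each): 75-region bundles (~250 planted events), 100
brute-force oracle windows of 20–50 bp × ≤ 50 reads, 100 seeded somatic
replicates, 2455-region depth simulation for the panel-rate check, and 100
random settings pairs for monotonicity. These sizes are the package's own
choice of desk-scale verification; all are configurable upward.

## Known limitations

* The caller assembles no MNVs and performs no realignment or genotype
  likelihood computation; INDEL candidates come only from explicit gap or
  insertion observations.
* The triage co-variant tolerance is a heuristic on shared-mismatch
  fractions; phased true double-heterozygotes within one amplicon would be
  (conservatively) sent to confirmation.
* TN accounting in concordance fixes one of several defensible conventions;
  reconciling against an external count requires matching it.
* The cost model is a reagent-only comparison in fixed prices; no
  multiplexing economics.
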