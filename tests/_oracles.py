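"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain loops, direct formulas, and
exhaustive enumeration. Nothing imports the code paths it checks beyond the
shared domain containers.
"""

import itertools
import math

from scipy import stats

from paneltriage.data_model import ReadStack


# ---------------------------------------------------------------------------
# Brute-force pileup caller
# ---------------------------------------------------------------------------


def brute_force_calls(stack: ReadStack, settings) -> set[tuple[int, str, str]]:
    """Enumerate every column/event and apply the caller predicates naively.

    Returns un-normalized (1-based pos, ref, alt) triples.
    """
    ref = stack.reference.upper()
    width = len(ref)
    out = set()

    def passes(alt_fwd, alt_rev, depth, is_indel):
        alt = alt_fwd + alt_rev
        if alt == 0 or depth == 0:
            return False
        min_cov = settings.min_cov_indel if is_indel else settings.min_cov_snp
        min_each = (
            settings.min_cov_each_strand_indel
            if is_indel
            else settings.min_cov_each_strand_snp
        )
        bias_max = (
            settings.strand_bias_max_indel if is_indel else settings.strand_bias_max_snp
        )
        if depth < min_cov or alt_fwd < min_each or alt_rev < min_each:
            return False
        err = settings.per_base_error_rate / (1.0 if is_indel else 3.0)
        tail = stats.binom.sf(alt - 1, depth, err)
        score = 4000.0 if tail == 0 else min(4000.0, -10.0 * math.log10(tail))
        if score < settings.min_variant_score:
            return False
        if settings.min_allele_freq is not None and alt / depth < settings.min_allele_freq:
            return False
        bias = max(alt_fwd, alt_rev) / alt
        if bias > bias_max:
            p = stats.binomtest(min(alt_fwd, alt_rev), alt, 0.5).pvalue
            if p < settings.strand_bias_alpha:
                return False
        return True

    depth_at = [
        sum(1 for r in stack.reads if r.observations[j] != ".") for j in range(width)
    ]

    for j in range(width):
        for base in "ACGT":
            if base == ref[j]:
                continue
            fwd = sum(
                1 for r in stack.reads if r.observations[j] == base and r.strand == "+"
            )
            rev = sum(
                1 for r in stack.reads if r.observations[j] == base and r.strand == "-"
            )
            if passes(fwd, rev, depth_at[j], is_indel=False):
                out.add((stack.start + j + 1, ref[j], base))

    # deletions: every maximal gap run with an in-window anchor
    events = {}
    for r in stack.reads:
        j = 0
        while j < width:
            if r.observations[j] == "-":
                k = j
                while k < width and r.observations[k] == "-":
                    k += 1
                if j >= 1:
                    events.setdefault(("D", j, k - j), []).append(r)
                j = k
            else:
                j += 1
        for off, seq in r.insertions.items():
            events.setdefault(("I", off, seq.upper()), []).append(r)
    for key, readers in events.items():
        fwd = sum(1 for r in readers if r.strand == "+")
        rev = len(readers) - fwd
        if key[0] == "D":
            _, j, span = key
            depth = max(depth_at[j - 1], len(readers))
            if passes(fwd, rev, depth, is_indel=True):
                out.add((stack.start + j, ref[j - 1 : j + span], ref[j - 1]))
        else:
            _, off, seq = key
            if passes(fwd, rev, depth_at[off], is_indel=True):
                out.add((stack.start + off + 1, ref[off], ref[off] + seq))
    return out


# ---------------------------------------------------------------------------
# Variant-representation equivalence by direct haplotype construction
# ---------------------------------------------------------------------------


def apply_event(window_seq: str, window_start: int, pos: int, ref: str, alt: str) -> str:
    """Haplotype obtained by substituting alt for ref at 1-based pos."""
    off = pos - 1 - window_start
    assert window_seq[off : off + len(ref)].upper() == ref.upper()
    return window_seq[:off] + alt + window_seq[off + len(ref):]


def enumerate_deletion_class(window_seq: str, haplotype: str, max_span: int = 3):
    """All VCF-style anchored deletion representations yielding ``haplotype``."""
    reps = []
    n = len(window_seq)
    for span in range(1, max_span + 1):
        for anchor in range(0, n - span):
            ref = window_seq[anchor : anchor + span + 1]
            alt = window_seq[anchor]
            if apply_event(window_seq, 0, anchor + 1, ref, alt) == haplotype:
                reps.append((anchor + 1, ref, alt))
    return reps


def enumerate_insertion_class(window_seq: str, haplotype: str, max_len: int = 3):
    """All VCF-style anchored insertion representations yielding ``haplotype``."""
    reps = []
    n = len(window_seq)
    alphabet = sorted(set(window_seq))
    for length in range(1, max_len + 1):
        for seq in itertools.product(alphabet, repeat=length):
            ins = "".join(seq)
            for anchor in range(0, n):
                ref = window_seq[anchor]
                alt = ref + ins
                if apply_event(window_seq, 0, anchor + 1, ref, alt) == haplotype:
                    reps.append((anchor + 1, ref, alt))
    return reps


# ---------------------------------------------------------------------------
# Exhaustive Wilcoxon signed-rank null by sign flipping
# ---------------------------------------------------------------------------


def signflip_wilcoxon(diffs) -> tuple[float, float]:
    """(V, two-sided p) by enumerating all 2^n sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = stats.rankdata([abs(x) for x in d])
    v_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    vs = []
    for signs in itertools.product((0, 1), repeat=n):
        vs.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(vs)
    p_le = sum(1 for v in vs if v <= v_obs + 1e-12) / total
    p_ge = sum(1 for v in vs if v >= v_obs - 1e-12) / total
    return float(v_obs), min(1.0, 2.0 * min(p_le, p_ge))
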