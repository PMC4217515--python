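import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from paneltriage.data_model import ReadStack, StackRead  # noqa: E402


def make_stack(reference, rows, chrom="chr1", start=0, insertions=None):
    """Build a ReadStack from (read_id, strand, observations) tuples."""
    reads = []
    insertions = insertions or {}
    for read_id, strand, obs in rows:
        reads.append(StackRead(read_id, strand, obs, insertions.get(read_id, {})))
    return ReadStack(chrom, start, reference, reads)


def uniform_stack(reference, alt_offset, alt_base, n_alt, n_ref, chrom="chr1", start=0):
    """Stack of full-window reads: n_alt carry alt_base at alt_offset, rest reference."""
    rows = []
    for i in range(n_alt):
        obs = reference[:alt_offset] + alt_base + reference[alt_offset + 1:]
        rows.append((f"a{i}", "+" if i % 2 == 0 else "-", obs))
    for i in range(n_ref):
        rows.append((f"r{i}", "+" if i % 2 == 0 else "-", reference))
    return make_stack(reference, rows, chrom=chrom, start=start)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic run bundle shared by pipeline-level tests."""
    from paneltriage.synthetic_data import SimulationConfig, simulate_run

    return simulate_run(SimulationConfig(seed=7, n_regions=30, n_patients=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
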