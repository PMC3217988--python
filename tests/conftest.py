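import io

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from srnamir.synthetic import (SimulationConfig, make_reference_sets,
                               make_est_collection, simulate_library)


@pytest.fixture(scope="session")
def small_sim():
    """A seeded 6k-read simulation shared across tests."""
    cfg = SimulationConfig(seed=11, n_reads=6000, n_hairpins=10, n_ests=20)
    refs = make_reference_sets(cfg)
    ests, planted = make_est_collection(cfg)
    reads, truth = simulate_library(cfg, refs, planted)
    return cfg, refs, ests, planted, reads, truth


def fastq_io(reads):
    buf = io.StringIO()
    for rid, seq, qual in reads:
        buf.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    buf.seek(0)
    return buf


@pytest.fixture
def fastq_of():
    return fastq_io
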