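import numpy as np
import pytest

import taxbench as tb


@pytest.fixture(scope="session")
def toy_registry() -> tb.Registry:
    """Three 20 kb microbial genomes plus a 50 kb host, sequences in memory."""
    reg = tb.Registry()
    for i, gc in enumerate((0.35, 0.50, 0.65)):
        sid = f"sp{i}"
        seq = tb.make_toy_genome(20_000, gc, 100 + i)
        reg.add(
            tb.annotate_species(sid, f"Toyus species{i}", seq, record_id=sid),
            sequence=seq,
        )
    host_seq = tb.make_toy_genome(50_000, 0.41, 999)
    reg.add(
        tb.annotate_species("host", "Hostus hostus", host_seq, record_id="host", host=True),
        sequence=host_seq,
    )
    return reg


@pytest.fixture(scope="session")
def tiny_scenario() -> tb.ScenarioConfig:
    """A fast scenario: 50 fragments per microbe at 10% prevalence."""
    return tb.ScenarioConfig(
        name="TINY",
        reads_per_species=50,
        per_species_prevalence=0.1,
        read_length=48,
        mean_phred=23,
        n_replicates=2,
        base_seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
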