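import pytest

from adaptrace import (
    AmpliconDesign,
    SimulationConfig,
    make_locus,
    make_reference,
    sample_prespacers,
    simulate_amplicon_reads,
)


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale study conditions: small genome, few hundred events."""
    base = dict(
        seed=7,
        chromosome_length=30_000,
        plasmid_length=8_000,
        n_transposase=2,
        n_rrna=1,
        n_provirus=0,
        feature_length=600,
        n_prespacers=150,
        n_reads=600,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def ref(cfg):
    return make_reference(cfg)


@pytest.fixture(scope="session")
def locus(cfg):
    return make_locus(cfg)


@pytest.fixture(scope="session")
def design(locus):
    return AmpliconDesign.from_locus(locus)


@pytest.fixture(scope="session")
def truth(ref, cfg):
    return sample_prespacers(ref, cfg)


@pytest.fixture(scope="session")
def library(locus, truth, design, cfg):
    """Error-free amplicon library with its realized truth table."""
    reads, updated = simulate_amplicon_reads(locus, truth, design, cfg)
    return reads, updated
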