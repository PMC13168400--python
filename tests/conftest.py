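"""Shared fixtures: a small synthetic study reused across test modules."""

import warnings

import pytest

from netdriver.synthetic import SimConfig, generate_network, simulate_counts

# anndata/scanpy emit chatty FutureWarnings on import; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning)


SMALL = dict(
    n_tf=5,
    n_mirna=10,
    n_target_genes=150,
    targets_per_driver=(3, 8),
    depth_range=(50_000, 80_000),
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(network, mrna, mirna, samples, truth) for one small simulated study."""
    network = generate_network(small_config)
    mrna, mirna, samples, truth = simulate_counts(network, small_config)
    return network, mrna, mirna, samples, truth


@pytest.fixture(scope="session")
def default_analysis():
    """Full analysis of one default-size study (2000 genes, 16 samples)."""
    from netdriver.pipeline import analyze

    config = SimConfig(seed=11)
    network = generate_network(config)
    mrna, mirna, samples, truth = simulate_counts(network, config)
    result = analyze(mrna, mirna, samples, network)
    return config, truth, result
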