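"""Shared fixtures: small simulated experiments with known truth."""

import pytest

from tnseqfit.simulate import FitnessComponent, SimConfig, simulate_experiment, simulate_library


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale conditions: 200 genes, 20 planted fitness genes."""
    return SimConfig(
        n_genes=200,
        n_barcodes=10_000,
        n_replicates=3,
        depth=400_000,
        bottleneck=40_000,
        fitness_effects={"invivo": [FitnessComponent(w_mean=-1.0, n_genes=20)]},
        seed=101,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_library(small_experiment):
    return small_experiment.library


@pytest.fixture(scope="session")
def saturating_library():
    """Library dense enough that every non-essential internal TA site is
    virtually certain to carry a barcode (~30x barcodes per site)."""
    cfg = SimConfig(
        n_genes=100,
        n_barcodes=80_000,
        max_barcodes_per_site=50,
        n_replicates=2,
        depth=400_000,
        essential_fraction=0.1,
        seed=202,
    )
    return simulate_library(cfg)
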