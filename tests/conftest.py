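import numpy as np
import pytest

from mhcpop import (
    SimulationConfig,
    TagScheme,
    build_allele_pool,
    simulate_genotypes,
    simulate_reads,
)
from mhcpop.simulate import MarkerModel


def small_config(seed=1, n_per_pop=6, pops=("A", "B", "C"), **kwargs):
    """A three-population miniature of the study design."""
    coords = {p: (-130.0 + 15.0 * i, 60.0 - 2.0 * i) for i, p in enumerate(pops)}
    defaults = dict(
        samples_per_population={p: n_per_pop for p in pops},
        coordinates=coords,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def demo_config():
    return small_config()


@pytest.fixture(scope="session")
def demo_pool(demo_config):
    return build_allele_pool(demo_config)


@pytest.fixture(scope="session")
def demo_truth(demo_config, demo_pool):
    return simulate_genotypes(demo_pool, demo_config)


@pytest.fixture(scope="session")
def demo_reads(demo_truth):
    return simulate_reads(demo_truth)


@pytest.fixture(scope="session")
def demo_scheme(demo_config, demo_reads):
    return TagScheme(
        demo_reads.forward_mids,
        demo_reads.reverse_mids,
        demo_config.forward_primer,
        demo_config.reverse_primer,
        demo_reads.assignment,
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Simulation with every artifact rate zeroed, for exact recovery."""
    from mhcpop.simulate import ReadModel

    cfg = small_config(
        seed=7,
        n_per_pop=8,
        read_model=ReadModel(
            mean_depth=400,
            depth_dispersion=20.0,
            per_base_error_rate=0.0,
            chimera_rate=0.0,
            noise_variant_rate=0.0,
            allele_amplification_bias_sd=0.0,
        ),
    )
    pool = build_allele_pool(cfg)
    truth = simulate_genotypes(pool, cfg)
    reads = simulate_reads(truth)
    return cfg, pool, truth, reads
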