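import numpy as np
import pytest

from introscan.synthetic import (
    SimFragmentConfig,
    SimPanelConfig,
    simulate_panel,
    simulate_reference_pair,
)

STANDARD_PANEL = dict(
    n_haplotypes_per_pop=40,
    pop_labels=("YRI-like", "EUR-like", "EAS-like", "AMR-like"),
    outgroup_pop="YRI-like",
    n_sites=120,
    region_length_bp=60_000,
    introgressed_freq_per_pop={
        "YRI-like": 0.0,
        "EUR-like": 0.2,
        "EAS-like": 0.12,
        "AMR-like": 0.15,
    },
    n_private_archaic_snps=28,
    segment_bounds_bp=(20_000, 40_000),
    alu_subhaplotype_fraction=0.7,
    mutation_density=0.3,
    seed=3,
)


@pytest.fixture(scope="session")
def panel_config():
    return SimPanelConfig(**STANDARD_PANEL)


@pytest.fixture(scope="session")
def panel_sim(panel_config):
    """(panel, archaic, truth) for the standard synthetic study."""
    return simulate_panel(panel_config)


@pytest.fixture(scope="session")
def ref_pair():
    return simulate_reference_pair(4_000, 2_000, 300, seed=7)


@pytest.fixture()
def frag_config():
    return SimFragmentConfig(target_coverage=30.0, seed=11)
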