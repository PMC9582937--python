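import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from budmine.synthetic_data import (
    BlockSpec,
    HubSpec,
    SimulationConfig,
    simulate_annotations,
    simulate_counts,
    simulate_genomes,
    simulate_network,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast two-chromosome study with every planted feature present."""
    return SimulationConfig(
        n_genes_per_species=400,
        n_chromosomes=2,
        frac_one_to_many=0.1,
        block_spec=(
            BlockSpec("chr1", "chr1", 11, 11, 10, "forward"),
            BlockSpec("chr2", "chr2", 21, 41, 8, "reverse"),
        ),
        class_sizes={"SHARED_UP": 30, "EARLY_ONLY": 30, "LATE_ONLY": 30, "DOWN": 30},
        hub_spec=HubSpec(
            n_hubs=2, hub_degree=8, background_edges=10, background_degree_cap=3
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Fully simulated small study: genomes, counts, network, annotations."""
    catalog_a, catalog_b, orthomap, truth = simulate_genomes(small_config)
    counts_a, design_a = simulate_counts(catalog_a, small_config, truth)
    counts_b, design_b = simulate_counts(catalog_b, small_config, truth)
    network, truth = simulate_network(truth, small_config)
    domains, terms = simulate_annotations(catalog_a, truth, small_config)
    return {
        "config": small_config,
        "catalog_a": catalog_a,
        "catalog_b": catalog_b,
        "orthomap": orthomap,
        "truth": truth,
        "counts_a": counts_a,
        "design_a": design_a,
        "counts_b": counts_b,
        "design_b": design_b,
        "network": network,
        "domains": domains,
        "terms": terms,
    }
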