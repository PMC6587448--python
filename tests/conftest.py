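import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from panforge.simulate import SimulationConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_config():
    """A compact five-variety draw used across module tests: 20 core and 10
    dispensable families, 5 variety-specific genes per variety, one planted
    tandem array per shape and one 8-anchor duplicated block."""
    return SimulationConfig(
        n_core_families=20,
        n_dispensable_families=10,
        n_specific_genes=5,
        gene_length_codons=(60, 120),
        n_chromosomes=2,
        td_arrays=(("zz13", 3, "chr1"), ("yz11", 2, "chr1")),
        wgd_blocks=(("zz13", 8),),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_pangenome(small_config)
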