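import pytest

from xciseq.scenarios import build_world
from xciseq.simulate import ChromosomeSpec, SimulationConfig, XCIProgram


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        chromosomes=(
            ChromosomeSpec("chr1", 60_000),
            ChromosomeSpec("chrX", 60_000, is_x=True),
        ),
        genes_per_chromosome=8,
        reads_per_gene=200,
        cutrun_fragments=2000,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(reference, calls, snps, filter_summary, pair, genes) for a tiny cross."""
    return build_world(small_config, XCIProgram())
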