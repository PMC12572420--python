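import pytest

from crossgwas.pipeline import PipelineParams, run_pipeline
from crossgwas.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale world: 4 studies, 4,000 SNPs, 40 genes, 6 traits."""
    return SimConfig(
        seed=11, n_snps=4000, n_genes=40, n_mediation_genes=8,
        n_traits=6, instruments_per_trait=8,
        n_region_contexts=4, n_cell_contexts=3, context_size=100,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    return run_pipeline(
        small_sim,
        PipelineParams(presso_n_sim=200, genome_background=100_000, seed=11),
    )
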