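import pytest

from sirna_callus.pipeline import Pipeline, PipelineConfig
from sirna_callus.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 11) -> SimulationConfig:
    """A reduced study: same structure, smaller genome, fast to simulate."""
    return SimulationConfig(
        genome_length=120_000,
        n_genes=30,
        n_duplex_loci=30,
        n_24nt_loci=10,
        n_cleavage_links=9,
        n_methyl_links=6,
        n_decoy_tags=10,
        n_decoy_de_genes=3,
        n_background_regions=20,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the small synthetic study."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(outdir=str(outdir), seed=11, simulate=small_config())
    manifest = Pipeline(cfg).run()
    return outdir, manifest, simulate_all(small_config())
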