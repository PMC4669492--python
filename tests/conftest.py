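import pytest

from spinachseq import synthetic_data as sd
from spinachseq.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    """Reduced problem size for unit tests (150 planted sites, 200 unigenes)."""
    return sd.SimulationConfig(
        n_unigenes=200,
        n_snp_sites=150,
        n_de_genes=20,
        n_artifact_contigs=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def scenario() -> sd.SpeciesScenario:
    return sd.default_scenario()


@pytest.fixture(scope="session")
def scenario_clean() -> sd.SpeciesScenario:
    return sd.default_scenario(mislabel=False)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return sd.generate_unigenes(small_config)


@pytest.fixture(scope="session")
def small_truth(small_catalog, scenario, small_config):
    return sd.plant_genotypes(small_catalog, scenario, small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full-default pipeline run shared by the end-to-end assertions."""
    out = tmp_path_factory.mktemp("pipeline_default")
    return run_pipeline(out_dir=out, seed=0)
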