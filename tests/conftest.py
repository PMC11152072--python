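import pytest

from nucleovar import PipelineConfig, SimulationConfig, run_pipeline


@pytest.fixture(scope="session")
def small_sim() -> SimulationConfig:
    """A desk-sized organism: 0.5 Mbp genome, 250 variant sites, 13 of 200 nuclei."""
    return SimulationConfig(
        genome_length=(300_000, 200_000),
        n_variant_sites=250,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_report(small_sim):
    """One full pipeline run shared by the end-to-end tests."""
    return run_pipeline(PipelineConfig(simulation=small_sim))
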