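import pytest

from specifex import normalization, pipeline, synthetic


@pytest.fixture(scope="session")
def default_bundle():
    """Default study-scale bundle (2000 genes, 2 cohorts x 10 couples x 2 treatments)."""
    return synthetic.generate_microarray(synthetic.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_bundle():
    return synthetic.generate_microarray(
        synthetic.GeneratorConfig(noise_sd=0.0, array_effect_sd=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def corrected_noise_free(noise_free_bundle):
    b = noise_free_bundle
    return normalization.reference_correct(
        normalization.log_standardize(b.G), normalization.log_standardize(b.R)
    )


@pytest.fixture(scope="session")
def default_report():
    """One full default pipeline run shared by pipeline and acceptance tests."""
    return pipeline.run_all(pipeline.RunConfig(seed=42))


@pytest.fixture(scope="session")
def cohort_table():
    return synthetic.load_cohort_fixture()
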