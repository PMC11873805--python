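import pytest

from foxa1class import DomainModel, GeneratorConfig, classify_cohort, generate_cohort


@pytest.fixture(scope="session")
def domain() -> DomainModel:
    return DomainModel()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick default-parameter cohort for pipeline-level tests."""
    return generate_cohort(GeneratorConfig(n_patients=600), seed=11)


@pytest.fixture(scope="session")
def full_cohort():
    """The all-tumors default cohort at the study's analysis scale."""
    return generate_cohort(GeneratorConfig(n_patients=5000), seed=1)


@pytest.fixture(scope="session")
def full_cohort_classes(full_cohort):
    samples, alterations = classify_cohort(
        full_cohort.variants,
        full_cohort.copy_number,
        sample_ids=full_cohort.features["sample_id"].tolist(),
    )
    return samples, alterations
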