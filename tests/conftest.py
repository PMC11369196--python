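import numpy as np
import pytest

from cpghm import ClassifierConfig, CpGHypermutatorModel, annotate_context
from cpghm.dnds import build_coding_model
from cpghm.simulate import SyntheticConfig, generate_catalog, generate_reference


@pytest.fixture(scope="session")
def default_cohort():
    """The default 2000-sample synthetic discovery cohort, annotated."""
    cohort = generate_catalog(SyntheticConfig(seed=0))
    cohort.catalog = annotate_context(cohort.catalog, cohort.reference.genome)
    return cohort


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Classifier results on the default cohort."""
    model = CpGHypermutatorModel(
        default_cohort.catalog,
        default_cohort.meta,
        regions=default_cohort.reference.regions,
        config=ClassifierConfig(rng_seed=0),
    )
    return model.fit()


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample cohort for cheaper unit-level checks."""
    cohort = generate_catalog(SyntheticConfig(seed=1, samples_per_cohort=50))
    cohort.catalog = annotate_context(cohort.catalog, cohort.reference.genome)
    return cohort


@pytest.fixture(scope="session")
def coding_model():
    ref = generate_reference(SyntheticConfig(seed=0))
    return ref, build_coding_model(ref.genome, ref.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
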