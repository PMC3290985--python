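import warnings

import pytest

from mcrscreen import (
    ExposureAssumptions,
    Measurement,
    SampleMixture,
    default_groundwater_config,
    generate_cohort,
    load_default_registry,
    run_full_analysis,
)
from mcrscreen.pd_registry import PlausibilityWarning

COHORT_SEED = 1
COHORT_SIZE = 618


@pytest.fixture(scope="session")
def registry():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlausibilityWarning)
        return load_default_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default ground-water cohort, shared across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PlausibilityWarning)
        config = default_groundwater_config(seed=COHORT_SEED, n_samples=COHORT_SIZE)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def default_summary(default_cohort, registry):
    return run_full_analysis(default_cohort, registry)


@pytest.fixture
def assumptions():
    return ExposureAssumptions()


def detect(analyte, concentration, dl=None):
    return Measurement(
        analyte=analyte,
        measured=True,
        detected=True,
        concentration=concentration,
        detection_limit=dl if dl is not None else max(concentration / 10, 1e-9),
    )


def nondetect(analyte, dl):
    return Measurement(
        analyte=analyte, measured=True, detected=False, detection_limit=dl
    )


def mixture(sample_id, *measurements):
    return SampleMixture(sample_id=sample_id, measurements=tuple(measurements))
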