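import numpy as np
import pytest

import nmrmetab as nm

REFERENCE_EFFECTS = {
    "lactate": {"case": 1.5},
    "glycine": {"case": 1.5},
    "phenylalanine": {"case": 1.5},
}


@pytest.fixture(scope="session")
def small_cohort():
    """8 + 8 cohort with a lactate effect; shared across cheap tests."""
    design = nm.CohortDesign(
        groups=(("case", 8), ("ctrl", 8)),
        effects={"lactate": {"case": 1.5}},
        seed=11,
    )
    return nm.simulate_cohort(design)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return nm.preprocess_spectra(
        list(small_cohort.spectra), list(small_cohort.sample_ids)
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference recovery design: fold 1.5 on three metabolites,
    25 + 25 samples."""
    design = nm.CohortDesign(
        groups=(("case", 25), ("ctrl", 25)),
        effects=REFERENCE_EFFECTS,
        seed=1,
    )
    return nm.simulate_cohort(design)


@pytest.fixture(scope="session")
def reference_matrix(reference_cohort):
    return nm.preprocess_spectra(
        list(reference_cohort.spectra), list(reference_cohort.sample_ids)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
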