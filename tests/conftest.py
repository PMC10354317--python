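import numpy as np
import pytest

from ramantriage.model import build_feature_matrix
from ramantriage.preprocess import PreprocessConfig, run_preprocessing
from ramantriage.spectra_io import CohortBundle
from ramantriage.synthetic_data import SimConfig, simulate_cohort, training_config


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient, 2-replicate cohort with ground truth (balanced classes)."""
    cfg = training_config(n_patients=20, replicates_per_patient=2, seed=42)
    spectra, patients, truths = simulate_cohort(cfg)
    return cfg, spectra, patients, truths


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    _, spectra, patients, _ = small_cohort
    return CohortBundle(patients=patients, spectra=spectra)


@pytest.fixture(scope="session")
def processed_small(small_bundle):
    return run_preprocessing(small_bundle, PreprocessConfig())


@pytest.fixture(scope="session")
def small_features(small_cohort, processed_small):
    _, _, _, truths = small_cohort
    labels = {t.patient_id: t.is_crc for t in truths}
    return build_feature_matrix(processed_small, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
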