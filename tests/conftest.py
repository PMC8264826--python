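import numpy as np
import pandas as pd
import pytest

from pulsedms.synthetic import (
    PulseSimConfig,
    StudySimConfig,
    TechRepSimConfig,
    simulate_pulsed_run,
    simulate_technical_replicates,
    simulate_toxicity_study,
)
from pulsedms.types import FeatureMatrix

# Seed for which the default pulsed run labels every scan correctly
# (off-scan contamination is Poisson, so a few seeds flip one off-scan).
CLEAN_SEED = 0


@pytest.fixture(scope="session")
def default_pulse():
    config = PulseSimConfig(seed=CLEAN_SEED)
    sample, truth = simulate_pulsed_run(config)
    return config, sample, truth


@pytest.fixture(scope="session")
def techrep():
    config = TechRepSimConfig(seed=1)
    matrix, truth = simulate_technical_replicates(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def study():
    config = StudySimConfig(seed=1)
    matrix, counts, meta, truth = simulate_toxicity_study(config)
    return config, matrix, counts, meta, truth


@pytest.fixture(scope="session")
def small_study():
    config = StudySimConfig(seed=7, n_drugs=4, n_concentrations=5,
                            replicates_per_group=6, n_dmso_groups=2,
                            n_death_groups=2, n_plates=3,
                            n_real_features=40, n_noise_features=40,
                            n_cytotoxic_drugs=2, n_perturbed_per_drug=5)
    matrix, counts, meta, truth = simulate_toxicity_study(config)
    return config, matrix, counts, meta, truth


def make_matrix(values, feature_mz=None, meta=None, sample_ids=None,
                feature_ids=None) -> FeatureMatrix:
    """Small FeatureMatrix builder for hand-written examples."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j:04d}" for j in range(m)]
    intensities = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    mz = pd.Series(feature_mz if feature_mz is not None
                   else np.linspace(100.0, 200.0, m), index=feature_ids, name="mz")
    if meta is None:
        meta = pd.DataFrame({
            "plate_id": "P1",
            "well": [f"A{i + 1:02d}" for i in range(n)],
            "role": "qc", "drug": "", "concentration_M": np.nan, "replicate": 1,
        }, index=sample_ids)
    return FeatureMatrix(intensities=intensities, feature_mz=mz, sample_meta=meta)


def random_matrix(rng, n=20, m=30, missing=0.2, plates=("P1", "P2")) -> FeatureMatrix:
    values = rng.lognormal(5, 1, size=(n, m))
    values[rng.random((n, m)) < missing] = np.nan
    sample_ids = [f"s{i}" for i in range(n)]
    feature_ids = [f"F{j:04d}" for j in range(m)]
    meta = pd.DataFrame({
        "plate_id": [plates[i % len(plates)] for i in range(n)],
        "well": [f"A{i + 1:02d}" for i in range(n)],
        "role": "qc", "drug": "", "concentration_M": np.nan, "replicate": 1,
    }, index=sample_ids)
    return make_matrix(values, meta=meta, sample_ids=sample_ids,
                       feature_ids=feature_ids)
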