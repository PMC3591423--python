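import numpy as np
import pytest

import platekin as pk
from platekin.fitting import FitOptions


@pytest.fixture(scope="session")
def wt_dls_model():
    """Hybrid model at wild-type-like parameters (mean 99.5 hr, s.d. 26.1 hr)."""
    return pk.LifespanModel(pk.lognormal_from_moments(99.5, 26.1), 0.0038)


@pytest.fixture(scope="session")
def study_law():
    """Reference lifespan law for identifiability studies: mean 100 hr, s.d. 25 hr."""
    return pk.lognormal_from_moments(100.0, 25.0)


@pytest.fixture(scope="session")
def lab():
    return pk.LabelingConfig(e1=0.9, e2=0.6, b_half=6.0, d=24.0)


@pytest.fixture(scope="session")
def quick_options():
    """Reduced multi-start schedule for desk-scale fits in tests."""
    return FitOptions(seed=11, starts_patience=15)


@pytest.fixture(scope="session")
def noiseless_dls_dataset(study_law, lab):
    """Noise-free replicate curves from a DLS truth with f = 0.8."""
    model = pk.LifespanModel(study_law, pk.r_from_f(study_law, 0.8))
    data = pk.generate_dataset(model, lab, sem_percent=0.0, n_replicates=6,
                               seed=1, platelet_count=(1183.0, 70.0))
    return model, data


@pytest.fixture(scope="session")
def noisy_fit(study_law, lab):
    """A converged DLS fit to mildly noisy data (f = 0.2 truth), shared by MC tests."""
    model = pk.LifespanModel(study_law, pk.r_from_f(study_law, 0.2))
    data = pk.generate_dataset(model, lab, sem_percent=0.2, n_replicates=6,
                               seed=7, platelet_count=(1183.0, 70.0))
    result = pk.fit(data, "DLS", options=FitOptions(seed=5, starts_patience=15))
    return model, data, result


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
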