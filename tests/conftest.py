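import numpy as np
import pytest

from adaptvd.expansion import ExpansionFunction
from adaptvd.model_core import (
    PKParameters,
    StructuralModel,
    build_schedule,
)
from adaptvd.synthetic_data import (
    generate_study,
    reference_model,
    transition_model,
)

# Published two-compartment base-model row (constant expansion):
# V1, V2 (L/kg), K, K12, K21 (1/day)
BASE_ROW = dict(v1=2.43, v2=0.00516, k=0.033, k12=0.183, k21=0.00287)
# Published exponentiated-Hill row
HILL_ROW = dict(v1=2.43, v2=0.00708, k=0.229, k12=0.183, k21=3.36)
HILL_EXPANSION = dict(emax=6.99, t50=49.0, hill=3.71)


@pytest.fixture(scope="session")
def schedule():
    """25 mg/kg Monday-Friday for 20 weeks (100 doses)."""
    return build_schedule(25.0, 20)


@pytest.fixture(scope="session")
def base_model():
    return StructuralModel(PKParameters(**BASE_ROW))


@pytest.fixture(scope="session")
def hill_model():
    return StructuralModel(
        PKParameters(**HILL_ROW),
        ExpansionFunction.hill_exp(**HILL_EXPANSION),
    )


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def trans_model():
    return transition_model()


@pytest.fixture(scope="session")
def noisy_dataset(ref_model):
    """Default-design noisy study from the reference truth."""
    return generate_study(
        ref_model, sigma_serum=0.1, sigma_spleen=0.1, seed=7, dt_max=0.25
    )


@pytest.fixture(scope="session")
def clean_dataset(ref_model):
    """Noise-free study: observations equal model predictions exactly."""
    return generate_study(
        ref_model, sigma_serum=0.0, sigma_spleen=0.0, seed=7, dt_max=0.25
    )


@pytest.fixture(scope="session")
def day_grid():
    return np.linspace(0.5, 140.0, 280)
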