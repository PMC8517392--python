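import numpy as np
import pytest

from pslwork import (
    CuffPressure,
    RAISED_COSINE_TEMPLATE,
    ValveEvents,
    generate_cohort,
    scale_to_cycle,
)


@pytest.fixture
def events() -> ValveEvents:
    """Typical resting valve timings: IVC 65 ms, ejection 305 ms, IVR 75 ms."""
    return ValveEvents(0.0, 0.065, 0.370, 0.445)


@pytest.fixture
def cuff() -> CuffPressure:
    return CuffPressure(sbp=120.0, dbp=78.0)


@pytest.fixture
def pressure_curve(events, cuff):
    return scale_to_cycle(RAISED_COSINE_TEMPLATE, events, cuff)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 50-vs-50 synthetic cohort, shared across tests."""
    table, bundles = generate_cohort(seed=1)
    return table, bundles


def exact_moments(base: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale a sample so its mean and ddof-1 SD are exact."""
    z = (base - base.mean()) / base.std(ddof=1)
    return z * sd + mean
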