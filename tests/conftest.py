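import numpy as np
import pytest
from hypothesis import settings

import stresslstm as sl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: The nine variables associated with stress in the reference analysis.
REFERENCE_SELECTED = frozenset(
    {
        "gender",
        "age",
        "height",
        "weight",
        "sleep_duration",
        "pulse_rate",
        "sbp",
        "drinking",
        "smoking",
    }
)


@pytest.fixture(scope="session")
def default_cohort():
    """One reference-sized cohort (640 low / 633 high), fixed seed."""
    return sl.generate_cohort(sl.default_spec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def perturbed_params(T=4, n=3, m=1, seed=11, scale=0.3):
    """Random small model with non-zero biases, for gradient-style tests."""
    params = sl.init_params(T=T, n=n, m=m, seed=seed)
    prng = np.random.default_rng(seed + 1)
    arrays = {
        name: np.asarray(a) + prng.normal(0.0, scale, np.shape(a))
        for name, a in params.named_arrays()
    }
    return params.replace_arrays(arrays)


def zeroed_params(T=9, n=1, m=1):
    """All-zero weights and biases (useful closed-form fixed points)."""
    params = sl.init_params(T=T, n=n, m=m, seed=0)
    zero = {name: np.zeros_like(np.asarray(a)) for name, a in params.named_arrays()}
    return params.replace_arrays(zero)
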