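import numpy as np
import pytest

from retikin.model import reference_parameters, solve_steady_state


@pytest.fixture(scope="session")
def ref():
    """Bundled reference parameter set and group plasma mass."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_params(ref):
    return ref[0]


@pytest.fixture(scope="session")
def ref_m5(ref):
    return ref[1]


@pytest.fixture(scope="session")
def ref_ss(ref_params, ref_m5):
    return solve_steady_state(ref_params, ref_m5)


@pytest.fixture(scope="session")
def sample_times():
    """The full study sampling grid, days."""
    return np.array([0.25, 0.375, 0.5, 1, 2, 4, 7, 11, 14, 21, 28, 35, 49, 63, 77, 91],
                    dtype=float)
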