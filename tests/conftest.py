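import numpy as np
import pytest

# Keep the hypothesis-free default test run deterministic: a few suites use
# module-level numpy generators seeded explicitly; nothing here relies on
# global random state.


@pytest.fixture(autouse=True)
def _no_global_numpy_seed_leakage():
    state = np.random.get_state()
    yield
    np.random.set_state(state)
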