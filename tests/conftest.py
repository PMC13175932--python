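import warnings

import numpy as np
import pytest

import ratdyn


@pytest.fixture(autouse=True)
def _quiet_pipeline_warnings():
    """The identification pipeline warns about degenerate null clusters by
    design; tests assert on results, not on the chatter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def mm_dataset():
    return ratdyn.simulate(ratdyn.benchmark_spec("mm"), seed=0)


@pytest.fixture(scope="session")
def mm_result():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ratdyn.run_benchmark("mm", seed=0)


@pytest.fixture(scope="session")
def competence_result():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ratdyn.run_benchmark("competence", seed=0)


@pytest.fixture(scope="session")
def penicillin_result():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ratdyn.run_benchmark("penicillin", seed=0)


@pytest.fixture(scope="session")
def glycolysis_result():
    """The seven-state benchmark at a reduced trajectory count (the
    identification outcome is unchanged; see docs/methods.md)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ratdyn.run_benchmark("glycolysis", seed=0, n_trajectories=100)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
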