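import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepinsulin.bifurcation import compute_diagram
from hepinsulin.profiles import by_label
from hepinsulin.simulate import simulate
from hepinsulin.synth import SynthesisDesign, default_truth, synthesize

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def truth_params(truth):
    return truth[0]


@pytest.fixture(scope="session")
def m4(truth):
    return truth[1]


@pytest.fixture(scope="session")
def feeding_traj(truth):
    params, v = truth
    return simulate(v, params, by_label("feeding"), t_end=120.0)


@pytest.fixture(scope="session")
def diagram(truth_params):
    return compute_diagram(truth_params)


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    params, v = truth
    return synthesize(params, v, SynthesisDesign(noise_cv=0.05, seed=20240917))


@pytest.fixture(scope="session")
def clean_dataset(truth):
    """Noise-free dataset generated on the fast integration path, so the
    fitting objective evaluated at the truth reproduces it exactly."""
    params, v = truth
    return synthesize(
        params, v,
        SynthesisDesign(noise_cv=0.0, replicates=1, seed=0, solver="rk4"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
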