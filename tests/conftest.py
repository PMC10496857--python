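import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from muellerpol import decompose_image, generate_image, scenario_presets
from muellerpol.simulate import NoiseSpec, depolarizer_mueller, retarder_mueller

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRESETS = ("single", "parallel", "crossed45", "crossed90")


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_retarder_depolarizer(rng, n=1):
    """(n, 4, 4) stack of random physical retarder x isotropic-depolarizer
    pixels plus their generating parameters."""
    delta = rng.uniform(1.0, 170.0, n)
    theta = rng.uniform(0.0, 180.0, n)
    a = rng.uniform(0.5, 1.0, n)
    M = retarder_mueller(delta, theta)
    M[..., 1:, 1:] *= a[:, None, None]
    return M, delta, theta, a


def random_physical_matrix(rng):
    """One random physical Mueller matrix: diattenuator, retarder and
    diagonal depolarizer composed in random order.

    The depolarizer coefficients are rejection-sampled against the coherency
    positivity constraints (all of 1 +/- a1 +/- a2 +/- a3 with an even number
    of minus signs must be non-negative); without that an anisotropic
    diagonal depolarizer need not be physical.
    """
    from muellerpol import diattenuator_matrix

    delta = rng.uniform(1.0, 170.0)
    theta = rng.uniform(0.0, 180.0)
    while True:
        a1, a2, a3 = rng.uniform(0.55, 1.0, 3)
        if (
            1 + a1 - a2 - a3 >= 0
            and 1 - a1 + a2 - a3 >= 0
            and 1 - a1 - a2 + a3 >= 0
        ):
            break
    dvec = rng.normal(size=3)
    dvec *= rng.uniform(0.0, 0.4) / np.linalg.norm(dvec)
    parts = [
        retarder_mueller(delta, theta),
        depolarizer_mueller(a1, a2, a3),
        diattenuator_matrix(np.linalg.norm(dvec), dvec),
    ]
    rng.shuffle(parts)
    M = parts[0] @ parts[1] @ parts[2]
    # keep the sample log-admissible: an eigenvalue pair on the negative real
    # axis (retardance driven to ~180 deg by the anisotropic factors) has no
    # real principal logarithm -- the documented failure mode, excluded here
    w = np.linalg.eigvals(M)
    if np.any((w.real <= 0) & (np.abs(w.imag) < 1e-6)):
        return random_physical_matrix(rng)
    return M


@pytest.fixture(scope="session")
def noiseless_preset_decompositions():
    """The four canonical scenes at 64x64, noiseless, decomposed with both
    methods; shared across tests because decomposition dominates runtime."""
    out = {}
    for name in PRESETS:
        stack, _ = scenario_presets(name)
        img, truth = generate_image(stack, NoiseSpec(element_sigma=0.0, seed=11), (64, 64))
        out[name] = (img, truth, decompose_image(img, method="both"))
    return out
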