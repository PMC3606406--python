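import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import splaynet as sn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# canonical parameter set used throughout tests and docs
A, G, ALPHA = 1.3, 0.4, 9.0


@pytest.fixture(scope="session")
def lif():
    return sn.lif_field(A)


@pytest.fixture(scope="session")
def lif_generic():
    """The LIF drive wrapped as a generic field: forces the numeric code paths."""
    return sn.custom_field(
        lambda u: A - np.asarray(u, dtype=float),
        derivatives=(
            lambda u: np.full_like(np.asarray(u, float), -1.0),
            lambda u: np.zeros_like(np.asarray(u, float)),
            lambda u: np.zeros_like(np.asarray(u, float)),
        ),
        label="lif-as-generic",
    )


@pytest.fixture(scope="session")
def splay50(lif):
    return sn.lif_splay_exact(A, G, ALPHA, 50)


@pytest.fixture(scope="session")
def spectrum50(lif, splay50):
    return sn.spectrum(splay50, lif, G, ALPHA)
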