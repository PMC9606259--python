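import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vcfkit import KineticModel, VoltageProtocol, make_step_protocol

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_model(rng: np.random.Generator) -> KineticModel:
    """A random but physically moderate three-state model."""
    g2, g3 = rng.uniform(-2.0, 2.0, size=2)
    gb12, gb23 = rng.uniform(1.0, 5.0, size=2)
    q2, q3 = rng.uniform(-2.0, 0.0, size=2)
    qb12, qb23 = rng.uniform(-2.0, 0.0, size=2)
    return KineticModel(
        g_state=(0.0, g2, g3),
        q_state=(0.0, q2, q3),
        g_barrier=(gb12, gb23),
        q_barrier=(qb12, qb23),
        tau_ms=float(rng.uniform(0.5, 2.0)),
    )


def random_protocol(rng: np.random.Generator) -> VoltageProtocol:
    n_seg = int(rng.integers(2, 5))
    segs = tuple(
        (float(rng.uniform(5.0, 50.0)), float(rng.uniform(-80.0, 80.0)))
        for _ in range(n_seg)
    )
    return VoltageProtocol(segments=segs, dt_ms=1.0)


@pytest.fixture(scope="session")
def step_protocols():
    return make_step_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
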