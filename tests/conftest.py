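import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_partition():
    """Two groups of sizes 2 and 3 -> blocks of sizes {1, 6, 3}."""
    from snba.core import Partition

    return Partition(
        assignment={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
    )


@pytest.fixture
def tiny_study(rng):
    """5-node, 2-group study with a planted effect in the (A, B) block."""
    from snba.synth import PlantedEffect, generate_study
    from snba.core import Partition

    part = Partition(
        assignment={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
    )
    study, truth = generate_study(
        partition=part,
        affected=[PlantedEffect(block=("A", "B"), pi=0.5, delta=2.0)],
        n1=8,
        n2=8,
        seed=rng,
    )
    return study, truth
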