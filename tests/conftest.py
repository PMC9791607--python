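import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class ScriptedRng:
    """Deterministic stand-in for a Generator: plays back scripted draws."""

    def __init__(self, integers=(), randoms=()):
        self._integers = list(integers)
        self._randoms = list(randoms)

    def integers(self, *_args, **_kwargs):
        return self._integers.pop(0)

    def random(self):
        return self._randoms.pop(0) if self._randoms else 0.0


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
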