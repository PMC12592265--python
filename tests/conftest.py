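import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antnav.types import Trajectory

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def _make_traj(thorax, head=None, fps=25.0, t=None, **labels) -> Trajectory:
    """Trajectory from a thorax point list; head defaults to +2 mm in x."""
    thorax = np.asarray(thorax, dtype=float)
    if t is None:
        t = np.arange(len(thorax)) / fps
    if head is None:
        head = thorax + np.array([2.0, 0.0])
    return Trajectory(t=t, head=np.asarray(head, float), thorax=thorax,
                      frame_rate=fps, **labels)


@pytest.fixture
def make_traj():
    return _make_traj


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
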