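import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from eegrcnn.nn.blocks import BlockSpec
from eegrcnn.nn.network import ArchitectureSpec


@pytest.fixture
def tiny_arch():
    """Small architecture for fast training tests (same topology)."""
    def make(n_class: int = 2) -> ArchitectureSpec:
        return ArchitectureSpec(
            blocks=[
                BlockSpec(4, kernels=(4, 3, 2)),
                BlockSpec(8, kernels=(4, 3, 2)),
                BlockSpec(4, kernels=(4, 3, 2), projection_shortcut=False),
            ],
            rnn_layers=[8, 8],
            dense_units=16,
            n_class=n_class,
        )
    return make


@pytest.fixture
def tiny_windows():
    """Separable 1-s two-class windows at 100 Hz (normal vs ictal texture)."""
    from eegrcnn.synthetic import gen_class_windows

    def make(n_per_class: int = 20, classes=("normal", "ictal"), seed: int = 0):
        return gen_class_windows(
            n_per_class, classes=classes, fs=100.0, window_s=1.0, seed=seed
        )
    return make
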