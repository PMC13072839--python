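import numpy as np
import pytest

from ovograde.synthetic import SyntheticEggSpec, render_view


@pytest.fixture
def clean_spec():
    """Noise-free centered phantom."""
    return SyntheticEggSpec(yolk_area_fraction=0.40)


@pytest.fixture
def clean_view(clean_spec):
    """(image, egg_truth, yolk_truth) of the noise-free phantom at 0 deg."""
    return render_view(clean_spec, 0, np.random.default_rng(0))


@pytest.fixture
def noisy_spec():
    """Eccentric phantom with moderate sensor noise."""
    return SyntheticEggSpec(
        yolk_area_fraction=0.45,
        yolk_offset=(6.0, -4.0),
        noise_sigma=8.0,
        angle_jitter=0.02,
    )
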