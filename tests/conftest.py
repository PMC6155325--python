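import numpy as np
import pytest

from spraydep.synthetic_afm import GenerationParams, ParticleField, render_height_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_bump_map():
    """One 0.5 nm particle exactly on a pixel centre, no noise, 4 nm pixels."""
    field = ParticleField(
        positions=np.array([[200.0, 200.0]]),
        heights=np.array([0.5]),
        widths=np.array([5.0]),
        extent=(400.0, 400.0),
    )
    return render_height_map(field, pixel_size=4.0, noise_sd=0.0)


@pytest.fixture
def separated_field():
    """100 well-separated particles on a jittered grid, exact ground truth."""
    gen = np.random.default_rng(3)
    xs, ys = np.meshgrid(np.arange(10), np.arange(10))
    pos = np.column_stack([xs.ravel(), ys.ravel()]) * 190.0 + 100.0
    pos = pos + gen.uniform(-30, 30, (100, 2))
    return ParticleField(
        positions=pos,
        heights=np.full(100, 0.4),
        widths=np.full(100, 5.0),
        extent=(2000.0, 2000.0),
    )
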