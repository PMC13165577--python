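import numpy as np
import pytest

from hemoflow.chip_model import ChipGeometry
from hemoflow.synthetic_data import RenderSettings, _draw_particles


@pytest.fixture(scope="session")
def geometry():
    return ChipGeometry()


@pytest.fixture(scope="session")
def render_settings():
    return RenderSettings()


def make_particle_pair(shift_x, shift_y=0.0, shape=(120, 160), seed=7,
                       density_per_px=0.05, amp=40.0, sigma=1.2, noise=0.0):
    """Two frames of Gaussian tracer speckle, the second shifted by a known
    displacement.

    Rendered on a larger virtual scene and cropped 20 px inside, so shifted
    content enters the view consistently (a genuine translation, free of
    wraparound artefacts).
    """
    h, w = shape
    margin = 20
    big = (h + 2 * margin, w + 2 * margin)
    rng = np.random.default_rng(seed)
    n = int(density_per_px * big[0] * big[1] / (sigma * sigma))
    xs = rng.uniform(0, big[1], n)
    ys = rng.uniform(0, big[0], n)
    noise_a = rng.normal(0, noise, shape) if noise > 0 else 0.0
    noise_b = rng.normal(0, noise, shape) if noise > 0 else 0.0

    def render(dx, dy, extra):
        img = np.full(big, 200.0)
        _draw_particles(img, xs + dx, ys + dy, amp, sigma, 0, big[0])
        return img[margin:margin + h, margin:margin + w] + extra

    return render(0, 0, noise_a), render(shift_x, shift_y, noise_b)
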