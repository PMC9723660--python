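import numpy as np
import pytest

import microph as m


@pytest.fixture(scope="session")
def phys():
    """Default photophysics: unbuffered two-point line, SNR ≈ 20 camera."""
    return m.Photophysics()


@pytest.fixture(scope="session")
def small_scene():
    """A 100 × 100 µm single-frame scene config for fast rendering tests."""
    return m.SceneConfig(field_width_um=100, field_height_um=100, n_frames=1, seed=7)


def render_uniform(cfg, phys, ph, layout=None, seed=0, noise=True):
    """Render one frame of a uniform-pH scene; returns (field, layout, image)."""
    field = m.generate_field(cfg, "uniform", {"ph": ph})
    if layout is None:
        layout = m.place_cells(cfg, seed=seed)
    img = m.render_frame(field, layout, phys, cfg, 0, seed=seed + 1, noise=noise)
    return field, layout, img


def idw_oracle(points, values, target, p=2.0, k=None, exclude=None):
    """Naive double-loop IDW reference implementation."""
    d = []
    for i, (x, y) in enumerate(points):
        if exclude is not None and i == exclude:
            continue
        d.append((np.hypot(x - target[0], y - target[1]), values[i]))
    coincident = [z for dist, z in d if dist < 1e-9]
    if coincident:
        return float(np.mean(coincident))
    if k is not None and k < len(d):
        d = sorted(d)[:k]
    num = sum(z * dist ** (-p) for dist, z in d)
    den = sum(dist ** (-p) for dist, z in d)
    return num / den
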