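import numpy as np
import pytest

from fruitsize.synthetic import SceneParams, generate_scene


def circle_points(a: float, b: float, r: float, n: int, jitter: float = 0.0,
                  seed: int | None = None) -> np.ndarray:
    """n points on (or radially jittered about) a circle."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    radii = np.full(n, r, dtype=float)
    if jitter > 0:
        radii = radii + np.random.default_rng(seed).normal(0.0, jitter, n)
    return np.column_stack([a + radii * np.cos(t), b + radii * np.sin(t)])


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless, unoccluded scene bundle with its parameters."""
    params = SceneParams(seed=11)
    image, depth, truth = generate_scene(params)
    return params, image, depth, truth


@pytest.fixture()
def disk_image():
    """Bright disk (radius 30 at (50, 50)) on a dark background."""
    yy, xx = np.mgrid[0:100, 0:100]
    return np.where(np.hypot(xx - 50, yy - 50) <= 30, 200, 60).astype(np.uint8)
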