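import math

import numpy as np
import pytest

from cryptmech.geometry import Contour


def sampled_circle(n: int = 720, radius: float = 1.0, center=(0.0, 0.0)) -> Contour:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = np.column_stack([np.cos(t), np.sin(t)]) * radius + np.asarray(center)
    return Contour(pts)


def random_simple_polygon(rng: np.random.Generator, n_min: int = 5, n_max: int = 40) -> Contour:
    """Star-shaped (hence simple) polygon with random radii and angles."""
    n = int(rng.integers(n_min, n_max + 1))
    angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, n))
    # enforce distinct angles so no duplicate vertices appear
    angles += np.linspace(0.0, 1e-6, n)
    radii = rng.uniform(0.2, 2.0, n)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return Contour(pts)


@pytest.fixture
def circle720() -> Contour:
    return sampled_circle(720)


@pytest.fixture
def unit_square() -> Contour:
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def hexagon() -> Contour:
    t = np.linspace(0.0, 2.0 * math.pi, 6, endpoint=False)
    return Contour(np.column_stack([np.cos(t), np.sin(t)]))
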