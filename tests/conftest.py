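import numpy as np
import pytest

from patic.geometry import Contour


@pytest.fixture
def unit_square():
    return Contour([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def equilateral_triangle():
    return Contour([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_star_polygon(rng, n_min=4, n_max=12):
    """Random simple (star-convex) polygon for invariance suites."""
    n = int(rng.integers(n_min, n_max + 1))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    # enforce a minimal angular gap so no near-duplicate vertices occur
    while np.min(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) < 0.05:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 1.5, n)
    v = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return Contour(v, kind="polygon")


def dense_psi_p(contour, p, n_samples=100_000):
    """Independent dense-sampling evaluation of the normal-angle integral.

    Riemann sum of exp(i p theta_n) over n_samples points placed uniformly
    in arc length along the boundary, dividing by 2*pi.  Used as the oracle
    against the per-edge closed form.
    """
    v = contour.vertices
    e = np.roll(v, -1, axis=0) - v
    seg_len = np.linalg.norm(e, axis=1)
    total = seg_len.sum()
    acc = 0.0 + 0.0j
    for d, L in zip(e, seg_len):
        k = max(1, int(round(n_samples * L / total)))
        theta = np.arctan2(-d[0], d[1])
        # k midpoint samples along the edge, each weighted by L / k
        acc += np.sum(np.full(k, np.exp(1j * p * theta))) * (L / k)
    return acc / (2 * np.pi)
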