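import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160218)


def random_smooth_contour(rng, center, mean_radius, wobble=0.2, n_points=8):
    """Control points of a star-shaped (hence non-self-intersecting) contour."""
    cx, cy = center
    # near-even angular spacing keeps the interpolating spline star-shaped
    angles = np.linspace(0, 2 * np.pi, n_points, endpoint=False) + rng.uniform(
        -np.pi / (3 * n_points), np.pi / (3 * n_points), n_points
    )
    radii = mean_radius * (1.0 + wobble * rng.uniform(-1, 1, n_points))
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def random_band_mask(rng, shape=(90, 90), r_in=(12, 18), r_out=(28, 40)):
    """A ragged annular mask around the image centre (synthetic cortex)."""
    rows, cols = shape
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(xx - cx, yy - cy)
    inner = rng.uniform(*r_in) * (1 + 0.1 * np.sin(2 * theta + rng.uniform(0, 6)))
    outer = rng.uniform(*r_out) * (1 + 0.1 * np.sin(3 * theta + rng.uniform(0, 6)))
    return (r >= inner) & (r <= outer)
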