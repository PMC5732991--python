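import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import box

from retstereo import defaults
from retstereo.synthetic import DensityField

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def outline():
    return defaults.default_outline()


@pytest.fixture(scope="session")
def small_fields(outline):
    """Reduced-density fields: same spatial structure, ~2% of the cell load."""
    return defaults.default_fields(outline, density_scale=0.02)


@pytest.fixture()
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


def quadrature_integral(field: DensityField, outline, n: int = 400) -> float:
    """Independent oracle: midpoint quadrature of a density field over an outline."""
    x0, y0, x1, y1 = outline.boundary.bounds
    xs = np.linspace(x0, x1, n, endpoint=False) + (x1 - x0) / (2 * n)
    ys = np.linspace(y0, y1, n, endpoint=False) + (y1 - y0) / (2 * n)
    gx, gy = np.meshgrid(xs, ys)
    inside = outline.contains_points(gx.ravel(), gy.ravel())
    vals = np.asarray(field(gx.ravel(), gy.ravel()))
    cell = (x1 - x0) / n * (y1 - y0) / n
    return float((vals * inside).sum() * cell)
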