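import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wallstereo as ws

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_rect_region(length=2000.0, thickness=700.0, y0=0.0, x0=0.0, pixel_size=2.0):
    """Rectangular wall: outer border at y=y0 (top), inner at y=y0+thickness."""
    x = np.linspace(x0, x0 + length, 201)
    outer = ws.BorderPolyline(
        np.column_stack([x, np.full_like(x, y0)]), role="outer"
    )
    inner = ws.BorderPolyline(
        np.column_stack([x, np.full_like(x, y0 + thickness)]), role="inner"
    )
    return ws.build_wall_region(inner, outer, pixel_size)


def make_annulus_region(r_in=700.0, r_out=1000.0, pixel_size=2.0, n=2048):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    center = r_out + 20.0
    ring = lambda r: center + np.column_stack([r * np.cos(th), r * np.sin(th)])
    inner = ws.BorderPolyline(ring(r_in), role="inner", closed=True)
    outer = ws.BorderPolyline(ring(r_out), role="outer", closed=True)
    return ws.build_wall_region(inner, outer, pixel_size), (center, center)


@pytest.fixture(scope="session")
def rect_region():
    return make_rect_region()


@pytest.fixture(scope="session")
def rect_field(rect_region):
    return ws.compute_relative_position_field(rect_region, spacing=2.0)


@pytest.fixture(scope="session")
def annulus():
    """(region, center) for the r_in=700 / r_out=1000 annulus."""
    return make_annulus_region()


@pytest.fixture(scope="session")
def annulus_field(annulus):
    region, _ = annulus
    return ws.compute_relative_position_field(region, spacing=2.0)
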