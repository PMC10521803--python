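import numpy as np
import pytest

from craniometrics import HeadSpec, PlanarContour, generate_head
from craniometrics.slicing import axial_plane


@pytest.fixture(scope="session")
def default_head():
    """Canonical noise-free ellipsoid head: L=200, W=150, H=100."""
    spec = HeadSpec(length_mm=200.0, width_mm=150.0, height_mm=100.0)
    mesh, landmarks, truth = generate_head(spec)
    return spec, mesh, landmarks, truth


@pytest.fixture(scope="session")
def bullet_head():
    """Scaphocephaly-like head whose max-OFD slice sits above the plane."""
    spec = HeadSpec(length_mm=205.0, width_mm=140.0, height_mm=95.0,
                    occipital_bullet=10.0, frontal_bossing=5.0)
    mesh, landmarks, truth = generate_head(spec)
    return spec, mesh, landmarks, truth


def make_circle_contour(radius, n=400, z=0.0, center=(0.0, 0.0)):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th),
                           np.full(n, z)])
    return PlanarContour(pts, axial_plane(z))


def make_ellipse_contour(semi_x, semi_y, n=720, z=0.0):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([semi_x * np.cos(th), semi_y * np.sin(th), np.full(n, z)])
    return PlanarContour(pts, axial_plane(z))


def ellipse_perimeter(semi_a, semi_b):
    """Quadrature oracle for the perimeter of an ellipse."""
    from scipy.integrate import quad

    a, b = max(semi_a, semi_b), min(semi_a, semi_b)
    val, _ = quad(lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2),
                  0.0, 2.0 * np.pi, limit=200)
    return val
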