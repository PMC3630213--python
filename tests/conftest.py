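import numpy as np
import pytest

from leafsurf.surface import SurfaceMesh


@pytest.fixture()
def rng(request):
    """Independent, deterministic generator per test (order-insensitive)."""
    seed = int.from_bytes(request.node.name.encode()[:8].ljust(8, b"x"), "little")
    return np.random.default_rng(seed % 2**31)


@pytest.fixture(scope="session")
def flat_mesh_small():
    """Flat 60x60 grid mesh over [0, 100]^2 (fast geodesic fixture)."""
    g = np.linspace(0.0, 100.0, 60)
    X, Y = np.meshgrid(g, g)
    return SurfaceMesh.from_grid(X, Y, np.zeros_like(X))


@pytest.fixture(scope="session")
def flat_mesh_fine():
    """Flat 200x200 crosshatch mesh over [0, 100]^2 (accuracy fixture)."""
    g = np.linspace(0.0, 100.0, 200)
    X, Y = np.meshgrid(g, g)
    return SurfaceMesh.from_grid(X, Y, np.zeros_like(X), crosshatch=True)


@pytest.fixture(scope="session")
def hemisphere_mesh():
    """Height-field cap of a radius-100 sphere on a 200x200 crosshatch grid."""
    r = 100.0
    R = r * np.sin(np.deg2rad(50))
    g = np.linspace(-R, R, 200)
    X, Y = np.meshgrid(g, g)
    inside = X**2 + Y**2 <= (0.999 * R) ** 2
    Z = np.sqrt(np.clip(r**2 - X**2 - Y**2, 0.0, None))
    return SurfaceMesh.from_grid(X, Y, Z, mask=inside, crosshatch=True)
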