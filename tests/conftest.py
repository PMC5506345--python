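import numpy as np
import pytest

from retfshape.mesh import TriSurface
from retfshape.preprocess import BMOEllipse
from retfshape.template import canonical_annulus_template
from retfshape.varifold import Fshape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tilted_ellipse():
    return BMOEllipse(
        center=np.array([0.1, -0.2, 0.05]),
        plane_normal=np.array([0.1, 0.05, 1.0]),
        major_axis_dir=np.array([1.0, 0.0, -0.1]),
        semi_major=0.9,
        semi_minor=0.7,
    )


@pytest.fixture
def small_annulus_fshape():
    """~200-vertex annular fshape with a superior-lobe signal."""
    tmpl = canonical_annulus_template(n_rings=6, n_theta=24)
    theta = np.rad2deg(
        np.arctan2(tmpl.surface.vertices[:, 1], tmpl.surface.vertices[:, 0])
    )
    sig = 0.1 + 0.05 * np.exp(-(((theta - 90.0) / 40.0) ** 2))
    return Fshape(tmpl.surface, sig)


def random_mesh_fshape(rng, n_vertices=8, n_tris=10, scale=0.5):
    """Small random valid triangle soup with a random signal."""
    while True:
        v = rng.normal(size=(n_vertices, 3)) * scale
        f = rng.integers(0, n_vertices, size=(n_tris, 3))
        f = np.array([row for row in f if len(set(row)) == 3])
        if len(f) >= 3:
            surf = TriSurface(v, f)
            if surf.face_areas().min() > 1e-6:
                return Fshape(surf, rng.normal(0.1, 0.03, n_vertices))
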