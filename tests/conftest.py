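import numpy as np
import pytest
import trimesh

from gdas.mesh import TriSurface, orient_outward
from gdas.synthetic import SyntheticScenario


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriSurface:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return orient_outward(TriSurface(np.asarray(m.vertices), np.asarray(m.faces)))


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere(4, 1.0)


@pytest.fixture(scope="session")
def scenario_data():
    """Default synthetic study: planted 5-mode model on a hippocampus-like
    ellipsoid, 5 sampled shapes, 38 protocol landmarks."""
    return SyntheticScenario().build()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def point_surface_distance(surface: TriSurface, points: np.ndarray) -> np.ndarray:
    """Exact distance from each point to the triangulated surface
    (clamped-barycentric closest point per face, minimum over faces)."""
    tri = surface.vertices[surface.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    pts = np.asarray(points, float)
    out = np.empty(len(pts))
    for n, p in enumerate(pts):
        ap = p - a
        d1 = np.einsum("fc,fc->f", ab, ap)
        d2 = np.einsum("fc,fc->f", ac, ap)
        bp = p - b
        d3 = np.einsum("fc,fc->f", ab, bp)
        d4 = np.einsum("fc,fc->f", ac, bp)
        cp = p - c
        d5 = np.einsum("fc,fc->f", ab, cp)
        d6 = np.einsum("fc,fc->f", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = np.maximum(va + vb + vc, 1e-300)
        v = np.clip(vb / denom, 0.0, 1.0)
        w = np.clip(vc / denom, 0.0, 1.0)
        # start from interior projection, then overwrite edge/vertex regions
        closest = a + v[:, None] * ab + w[:, None] * ac
        # vertex regions
        m = (d1 <= 0) & (d2 <= 0)
        closest[m] = a[m]
        m = (d3 >= 0) & (d4 <= d3)
        closest[m] = b[m]
        m = (d6 >= 0) & (d5 <= d6)
        closest[m] = c[m]
        # edge AB
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
        closest[m] = a[m] + np.clip(t[m], 0, 1)[:, None] * ab[m]
        # edge AC
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
        closest[m] = a[m] + np.clip(t[m], 0, 1)[:, None] * ac[m]
        # edge BC
        m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        den2 = (d4 - d3) + (d5 - d6)
        t = np.where(den2 != 0, (d4 - d3) / np.where(den2 != 0, den2, 1.0), 0.0)
        closest[m] = b[m] + np.clip(t[m], 0, 1)[:, None] * (c[m] - b[m])
        out[n] = np.sqrt(((p - closest) ** 2).sum(axis=1).min())
    return out
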