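"""Synthetic study data: templates, planted shape models, sampled shapes,
protocol landmarks, voxelized segmentations and T1-like images.

Everything the fitting pipeline consumes can be generated here, seeded
and in world mm, emulating a hippocampus ROI study: an elongated
ellipsoidal template (anterior-posterior axis ~40 mm), a small planted
momentum-PCA model, shapes sampled from it, the 38-landmark slice
protocol (two tip landmarks plus 9 slices x 4 margin landmarks), landmark
noise at multiples of the voxel-derived base variance, and images whose
inside/outside intensities follow Gaussian mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes

from .attachment import AppearanceModel, LandmarkSet, sigma2_from_voxels
from .image import BinarySegmentation, ScalarImage3D
from .mesh import TriSurface, orient_outward
from .pca import ShapePCAModel, metric_gram
from .shooting import KernelSpec, default_kernel_width, shoot

__all__ = [
    "make_template",
    "plant_model",
    "sample_momenta",
    "sample_shapes",
    "place_protocol_landmarks",
    "add_landmark_noise",
    "isosurface",
    "render_t1",
    "default_appearance_model",
    "SyntheticScenario",
    "ScenarioData",
]


def make_template(axes=(20.0, 8.0, 7.0), subdivisions: int = 3) -> TriSurface:
    """Hippocampus-like elongated ellipsoid: an icosphere subdivided
    ``subdivisions`` times and anisotropically scaled to semi-axes
    ``axes`` (mm).  Closed and wound outward."""
    axes = np.asarray(axes, float)
    if np.any(axes <= 0):
        raise ValueError("axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices) * axes
    return orient_outward(TriSurface(verts, np.asarray(ico.faces)))


def plant_model(
    template: TriSurface,
    d_syn: int = 5,
    decay: float = 0.5,
    lambda1: float = 25.0,
    seed: int = 0,
    kernel: KernelSpec | None = None,
) -> ShapePCAModel:
    """Plant a momentum-PCA model with known spectrum.

    Components are built from low-frequency spatial bumps (Gaussian
    envelopes around random surface vertices times random directions),
    Gram-Schmidt orthonormalized in the kernel metric.  Eigenvalues decay
    geometrically, lambda_i = lambda1 * decay^(i-1); the mean momentum is
    zero.  ``lambda1`` is in squared kernel-metric (RKHS velocity-norm)
    units; the default 25 makes a 1-sd leading mode displace the surface
    by a few mm at its peak, a realistic population variability for a
    ~40 mm subcortical structure.
    """
    if not (0 < decay < 1):
        raise ValueError("decay must lie in (0, 1) for strictly decreasing eigenvalues")
    rng = np.random.default_rng(seed)
    x = template.vertices
    if kernel is None:
        kernel = KernelSpec(default_kernel_width(x))
    G = metric_gram(x, kernel)
    bump_width = 0.5 * float(np.linalg.norm(x.max(0) - x.min(0)))

    comps = []
    attempts = 0
    while len(comps) < d_syn:
        attempts += 1
        if attempts > 50 * d_syn:
            raise RuntimeError("failed to generate independent momentum bumps")
        c = x[rng.integers(len(x))]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        env = np.exp(-np.sum((x - c) ** 2, axis=1) / (2 * bump_width**2))
        b = env[:, None] * d
        for u in comps:  # Gram-Schmidt in the kernel metric
            b = b - np.einsum("kc,kl,lc->", u, G, b) * u
        nrm = np.sqrt(np.einsum("kc,kl,lc->", b, G, b))
        if nrm < 1e-8:
            continue
        comps.append(b / nrm)

    lam = lambda1 * decay ** np.arange(d_syn)
    model = ShapePCAModel(
        template, np.zeros_like(x), np.array(comps), lam, kernel
    )
    # training-distance reference for empirical P-values: chi distribution
    # of a seeded training draw from the planted model itself
    ks = rng.normal(size=(650, d_syn)) * np.sqrt(lam)
    model.training_distances = np.sqrt((ks**2 / lam).sum(axis=1))
    return model


def sample_momenta(model: ShapePCAModel, n: int, seed: int = 0):
    """Coefficients k_i ~ N(0, lambda_i) i.i.d. and their momentum fields."""
    rng = np.random.default_rng(seed)
    ks = rng.normal(size=(n, model.n_components)) * np.sqrt(model.eigenvalues)
    alphas = np.array([model.momentum_from_coefficients(k) for k in ks])
    return ks, alphas


def sample_shapes(model: ShapePCAModel, n: int, seed: int = 0, n_steps: int = 10):
    """Sample shapes from the model: list of (k, TriSurface) via shooting."""
    ks, alphas = sample_momenta(model, n, seed)
    out = []
    for k, alpha in zip(ks, alphas):
        traj = shoot(model.template.vertices, alpha, model.kernel, n_steps)
        out.append((k, model.template.with_vertices(traj.endpoint)))
    return out


# ---------------------------------------------------------------------------
# Landmark protocol
# ---------------------------------------------------------------------------

def _principal_frame(vertices: np.ndarray):
    """Centered coordinates and principal axes ordered by descending extent,
    with deterministic signs (largest component positive)."""
    c = vertices.mean(axis=0)
    cov = np.cov((vertices - c).T)
    evals, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T  # rows: longest first
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return c, axes


def _plane_contour(vertices, faces, coord, level):
    """Points where mesh edges cross the plane coord == level."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    va, vb = coord[e[:, 0]], coord[e[:, 1]]
    crossing = (va - level) * (vb - level) < 0
    if not crossing.any():
        return None
    t = (level - va[crossing]) / (vb[crossing] - va[crossing])
    return vertices[e[crossing, 0]] + t[:, None] * (
        vertices[e[crossing, 1]] - vertices[e[crossing, 0]]
    )


def place_protocol_landmarks(surface: TriSurface, n_slices: int = 9) -> LandmarkSet:
    """Slice-protocol landmarks on an elongated closed surface.

    One landmark at each tip of the longest (anterior-posterior)
    principal axis, then ``n_slices`` evenly spaced cross-section planes
    between the tips; on each cross-section contour the 4 extremal points
    along the two transverse principal directions (superior, inferior,
    medial, lateral).  All landmarks snap to the nearest surface vertex.
    Ordering: head tip, tail tip, then slice-major (sup, inf, med, lat),
    38 landmarks for the default 9 slices.
    """
    if not surface.is_closed():
        raise ValueError("landmark protocol requires a closed surface")
    V = surface.vertices
    c, axes = _principal_frame(V)
    P = (V - c) @ axes.T  # rows of axes: AP, then transverse by extent
    ap = P[:, 0]

    idx = [int(np.argmax(ap)), int(np.argmin(ap))]  # head tip, tail tip
    lo, hi = ap.min(), ap.max()
    fractions = (np.arange(1, n_slices + 1)) / (n_slices + 1)
    for frac in fractions:
        level = lo + frac * (hi - lo)
        contour = _plane_contour(V, surface.faces, ap, level)
        if contour is None:
            raise ValueError("slice plane misses the surface: not simply elongated")
        Pc = (contour - c) @ axes.T
        for pick in (
            np.argmax(Pc[:, 1]),  # superior
            np.argmin(Pc[:, 1]),  # inferior
            np.argmax(Pc[:, 2]),  # medial
            np.argmin(Pc[:, 2]),  # lateral
        ):
            p = contour[int(pick)]
            idx.append(int(np.argmin(np.sum((V - p) ** 2, axis=1))))
    idx = np.array(idx)
    return LandmarkSet(V[idx], idx)


def add_landmark_noise(landmarks: LandmarkSet, variance: float, seed: int = 0) -> LandmarkSet:
    """I.i.d. zero-mean Gaussian perturbation with per-coordinate
    ``variance`` (mm^2); the template vertex indices are dropped because
    the noisy points no longer sit on vertices."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return LandmarkSet(landmarks.points.copy(), None)
    rng = np.random.default_rng(seed)
    noisy = landmarks.points + rng.normal(scale=np.sqrt(variance), size=landmarks.points.shape)
    return LandmarkSet(noisy, None)


# ---------------------------------------------------------------------------
# Voxel targets and T1-like images
# ---------------------------------------------------------------------------

def isosurface(seg: BinarySegmentation) -> TriSurface:
    """Marching-cubes isosurface of a binary volume at level 0.5, in
    world mm.  Deliberately unsmoothed: the jagged voxelized boundary is
    the kind of target the currents matching must be robust to."""
    verts, faces, _, _ = marching_cubes(seg.data.astype(np.float64), level=0.5)
    world = verts @ seg.affine[:3, :3].T + seg.affine[:3, 3]
    return orient_outward(TriSurface(world, faces))


def default_appearance_model() -> AppearanceModel:
    """T1-like intensity mixtures (arbitrary units, roughly 0-255):
    a narrow unimodal subcortical-gray interior (3 components) against a
    heterogeneous exterior of CSF, white matter and cortical gray
    (4 components, partially overlapping the interior)."""
    from .attachment import GaussianMixture1D

    inside = GaussianMixture1D(
        weights=[0.6, 0.3, 0.1], means=[105.0, 115.0, 95.0], variances=[64.0, 100.0, 81.0]
    )
    outside = GaussianMixture1D(
        weights=[0.25, 0.35, 0.25, 0.15],
        means=[35.0, 160.0, 120.0, 80.0],
        variances=[225.0, 144.0, 196.0, 256.0],
    )
    return AppearanceModel(inside, outside)


def render_t1(
    seg: BinarySegmentation,
    model: AppearanceModel,
    blur_mm: float = 0.0,
    seed: int = 0,
) -> ScalarImage3D:
    """Draw voxel intensities from the inside mixture within the
    segmentation and the outside mixture elsewhere; optional Gaussian
    blur (mm) emulates partial-volume averaging."""
    rng = np.random.default_rng(seed)
    data = np.empty(seg.data.shape)
    n_in = int(seg.data.sum())
    data[seg.data] = model.inside.sample(n_in, rng)
    data[~seg.data] = model.outside.sample(data.size - n_in, rng)
    if blur_mm > 0:
        data = gaussian_filter(data, sigma=blur_mm / seg.spacing)
    return ScalarImage3D(data, seg.affine.copy())


# ---------------------------------------------------------------------------
# Scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """Study conditions for the simulated landmark-robustness experiment.

    Defaults mirror the simulated design: 5 shapes drawn from the planted
    PCA model, 38 protocol landmarks, additive landmark noise at
    (0.01, 0.1, 1, 10, 100) times the voxel-derived base variance
    sigma^2 = ((0.93/2)^2 + (0.93/2)^2 + (2.0/2)^2)/3 mm^2.
    """

    axes: tuple = (20.0, 8.0, 7.0)
    subdivisions: int = 2
    d_syn: int = 5
    decay: float = 0.5
    lambda1: float = 25.0
    n_shapes: int = 5
    base_variance: float = sigma2_from_voxels(0.93, 0.93, 2.0)
    noise_multipliers: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    seed: int = 0

    def build(self) -> "ScenarioData":
        template = make_template(self.axes, self.subdivisions)
        model = plant_model(
            template, self.d_syn, self.decay, self.lambda1, seed=self.seed
        )
        shapes = sample_shapes(model, self.n_shapes, seed=self.seed + 1)
        landmarks = place_protocol_landmarks(template)
        return ScenarioData(self, template, model, shapes, landmarks)


@dataclass
class ScenarioData:
    """Generated artifacts of a :class:`SyntheticScenario`."""

    scenario: SyntheticScenario
    template: TriSurface
    model: ShapePCAModel
    shapes: list  # [(k_true, TriSurface), ...]
    template_landmarks: LandmarkSet

    def target_landmarks(self, shape_index: int, noise_multiplier: float, seed: int):
        """Landmarks of a sampled shape: the flowed positions of the
        template landmark vertices, plus protocol placement noise."""
        _, surf = self.shapes[shape_index]
        clean = LandmarkSet(
            surf.vertices[self.template_landmarks.vertex_indices],
            self.template_landmarks.vertex_indices,
        )
        var = noise_multiplier * self.scenario.base_variance
        return add_landmark_noise(clean, var, seed=seed)
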