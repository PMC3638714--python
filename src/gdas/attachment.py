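"""Data-attachment energies E2 and their surface-vertex gradients.

Three interchangeable terms measure how well the deformed template fits
the observed data:

* **currents**: the squared distance between two oriented surfaces in a
  kernel dual space, computed from face centers and area-weighted
  normals — no point correspondence needed;
* **landmarks**: summed squared distances between flowed template
  landmarks (vertices) and target landmarks;
* **image**: integrated log-likelihood of voxels being misclassified by
  an inside/outside Gaussian-mixture appearance model.

Each term exposes ``energy(deformed)`` and ``gradient(deformed)``, the
latter returning one 3-vector per deformed-template vertex (dE2/dx).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .image import ScalarImage3D
from .mesh import TriSurface, face_geometry
from .shooting import KernelSpec
from .voxelize import voxelize_mask

__all__ = [
    "LandmarkSet",
    "GaussianMixture1D",
    "AppearanceModel",
    "CurrentsAttachment",
    "LandmarkAttachment",
    "ImageAttachment",
    "currents_energy",
    "currents_gradient",
    "landmark_energy",
    "landmark_gradient",
    "sigma2_from_voxels",
    "fit_mixture_em",
    "fit_appearance",
    "histogram_equalize",
    "image_energy",
    "image_gradient",
    "read_landmarks",
    "write_landmarks",
]


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Ordered landmark coordinates (world mm); template landmarks also
    carry the vertex indices they sit on."""

    points: np.ndarray
    vertex_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("landmarks must be a nonempty (K, 3) array")
        if self.vertex_indices is not None:
            self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
            if len(self.vertex_indices) != len(self.points):
                raise ValueError("vertex_indices length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def read_landmarks(path: str) -> LandmarkSet:
    """One 'x y z' per line, ordered; '#' comments allowed."""
    pts = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                pts.append([float(t) for t in ln.split()[:3]])
    return LandmarkSet(np.array(pts))


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    with open(path, "w") as fh:
        for p in landmarks.points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def landmark_energy(deformed_landmarks: LandmarkSet, target_landmarks: LandmarkSet) -> float:
    """E2 = sum_i ||X_i(1) - Y_i||^2 (matched order)."""
    X, Y = deformed_landmarks.points, target_landmarks.points
    if X.shape != Y.shape:
        raise ValueError("landmark sets must have equal size and order")
    return float(np.sum((X - Y) ** 2))


def landmark_gradient(
    deformed: TriSurface,
    template_landmarks: LandmarkSet,
    target_landmarks: LandmarkSet,
) -> np.ndarray:
    """dE2/dx: zero off-landmark, 2 (x_{l(j)} - Y_j) at landmark vertices."""
    idx = template_landmarks.vertex_indices
    if idx is None:
        raise ValueError("template landmarks must carry vertex indices")
    grad = np.zeros_like(deformed.vertices)
    np.add.at(grad, idx, 2.0 * (deformed.vertices[idx] - target_landmarks.points))
    return grad


def sigma2_from_voxels(dx: float, dy: float, dz: float) -> float:
    """Landmark-placement variance on the order of voxel size:
    ((dx/2)^2 + (dy/2)^2 + (dz/2)^2) / 3, in mm^2."""
    return ((dx / 2.0) ** 2 + (dy / 2.0) ** 2 + (dz / 2.0) ** 2) / 3.0


# ---------------------------------------------------------------------------
# Currents surface matching
# ---------------------------------------------------------------------------

def _pair_sum(c1, N1, c2, N2, ks: KernelSpec) -> float:
    diff = c1[:, None, :] - c2[None, :, :]
    K = ks.gamma(np.einsum("ijc,ijc->ij", diff, diff))
    return float(np.einsum("ic,ij,jc->", N1, K, N2))


def currents_energy(deformed: TriSurface, target: TriSurface, ks: KernelSpec) -> float:
    """Squared currents distance ||S - S'||^2 = self + self' - 2 cross."""
    if deformed.n_faces == 0 or target.n_faces == 0:
        raise ValueError("currents energy of an empty mesh")
    gd = face_geometry(deformed)
    gt = face_geometry(target)
    return (
        _pair_sum(gd.centers, gd.normals, gd.centers, gd.normals, ks)
        - 2.0 * _pair_sum(gd.centers, gd.normals, gt.centers, gt.normals, ks)
        + _pair_sum(gt.centers, gt.normals, gt.centers, gt.normals, ks)
    )


def currents_gradient(deformed: TriSurface, target: TriSurface, ks: KernelSpec) -> np.ndarray:
    """Vertex gradient of the currents energy.

    Per face f, with P_f the kernel-smoothed normal field (self minus
    target) at c_f and Q_f the kernel-derivative moment, each corner i
    receives P_f x e_{f,i} + (4/3) Q_f.
    """
    gd = face_geometry(deformed)
    gt = face_geometry(target)

    dss = gd.centers[:, None, :] - gd.centers[None, :, :]
    s_ss = np.einsum("ijc,ijc->ij", dss, dss)
    Kss = ks.gamma(s_ss)
    dst = gd.centers[:, None, :] - gt.centers[None, :, :]
    s_st = np.einsum("ijc,ijc->ij", dst, dst)
    Kst = ks.gamma(s_st)

    P = Kss @ gd.normals - Kst @ gt.normals  # (M, 3)

    nn_ss = gd.normals @ gd.normals.T
    nn_st = gd.normals @ gt.normals.T
    Q = np.einsum("ij,ijc->ic", ks.dgamma(s_ss) * nn_ss, dss) - np.einsum(
        "ij,ijc->ic", ks.dgamma(s_st) * nn_st, dst
    )

    grad = np.zeros_like(deformed.vertices)
    for i in range(3):
        contrib = np.cross(P, gd.edges[:, i]) + (4.0 / 3.0) * Q
        np.add.at(grad, deformed.faces[:, i], contrib)
    return grad


# ---------------------------------------------------------------------------
# Appearance model: 1-D Gaussian mixtures fit by EM
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixture1D:
    """Weights, means and variances of a univariate Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("mixture variances must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def log_pdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        lw = np.log(self.weights[:, None])
        ll = (
            -0.5 * np.log(2.0 * np.pi * self.variances[:, None])
            - (x.ravel()[None, :] - self.means[:, None]) ** 2
            / (2.0 * self.variances[:, None])
        )
        out = logsumexp(lw + ll, axis=0)
        return out.reshape(x.shape)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.log_pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return rng.normal(self.means[comp], np.sqrt(self.variances[comp]))


@dataclass
class AppearanceModel:
    """Inside and outside intensity mixtures of a homogeneous structure."""

    inside: GaussianMixture1D
    outside: GaussianMixture1D

    def log_ratio(self, intensities) -> np.ndarray:
        """g(I) = log p_ext(I) - log p_int(I)."""
        return self.outside.log_pdf(intensities) - self.inside.log_pdf(intensities)


def fit_mixture_em(
    data: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[GaussianMixture1D, np.ndarray]:
    """Maximum-likelihood Gaussian mixture via EM.

    Initialisation: means at evenly spread sample quantiles, pooled
    variance, uniform weights.  A component whose variance collapses
    below 1e-8 of the data variance is re-seeded at a random data point
    (seeded RNG) with pooled variance.  Returns the mixture and the
    per-iteration log-likelihood trace (non-decreasing between
    re-initialisations; EM guarantee).
    """
    x = np.asarray(data, float).ravel()
    Q = int(n_components)
    if len(x) < 10 * Q:
        raise ValueError("need at least 10 samples per mixture component")
    rng = np.random.default_rng(seed)
    pooled = max(x.var(), 1e-12)
    floor = 1e-8 * pooled
    means = np.quantile(x, (np.arange(Q) + 0.5) / Q)
    var = np.full(Q, pooled)
    w = np.full(Q, 1.0 / Q)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        lw = np.log(w)[:, None]
        ll = (
            -0.5 * np.log(2 * np.pi * var[:, None])
            - (x[None, :] - means[:, None]) ** 2 / (2 * var[:, None])
        )
        joint = lw + ll
        norm = logsumexp(joint, axis=0)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(joint - norm[None, :])  # (Q, n)

        nk = resp.sum(axis=1)
        w = nk / len(x)
        means = resp @ x / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk

        collapsed = (var < floor) | ~np.isfinite(var)
        if collapsed.any():
            warnings.warn("mixture component collapsed; re-initialising", stacklevel=2)
            for qi in np.nonzero(collapsed)[0]:
                means[qi] = x[rng.integers(len(x))]
                var[qi] = pooled
                w = np.maximum(w, 1e-6)
                w /= w.sum()
            prev = -np.inf
            continue
        if loglik - prev < tol * abs(loglik) and np.isfinite(prev):
            break
        prev = loglik

    order = np.argsort(means)
    return GaussianMixture1D(w[order] / w.sum(), means[order], var[order]), np.array(trace)


def fit_appearance(
    inside_intensities: np.ndarray,
    outside_intensities: np.ndarray,
    q_int: int = 3,
    q_ext: int = 4,
    seed: int = 0,
) -> AppearanceModel:
    """EM-fitted inside/outside mixtures (defaults: 3 inside, 4 outside
    components, the standard configuration for T1 subcortical gray vs the
    heterogeneous surround)."""
    mi, _ = fit_mixture_em(inside_intensities, q_int, seed=seed)
    mo, _ = fit_mixture_em(outside_intensities, q_ext, seed=seed + 1)
    return AppearanceModel(mi, mo)


def histogram_equalize(
    image: ScalarImage3D,
    reference_intensities: np.ndarray,
    roi_mask: np.ndarray,
    levels: int = 256,
) -> ScalarImage3D:
    """Monotone intensity map matching the ROI's empirical CDF to a
    reference CDF, applied voxelwise to the whole image.

    The map is discretized on ``levels`` quantiles and interpolated
    piecewise-linearly in between.
    """
    roi_vals = image.data[np.asarray(roi_mask, bool)]
    if roi_vals.size == 0:
        raise ValueError("empty ROI mask")
    probs = (np.arange(levels) + 0.5) / levels
    src_q = np.quantile(roi_vals, probs)
    ref_q = np.quantile(np.asarray(reference_intensities, float), probs)
    # enforce strict monotonicity of the source knots for interpolation
    src_q = np.maximum.accumulate(src_q)
    mapped = np.interp(image.data, src_q, ref_q)
    return ScalarImage3D(mapped, image.affine.copy())


# ---------------------------------------------------------------------------
# Inside/outside image energy
# ---------------------------------------------------------------------------

def _check_surface_in_image(surface: TriSurface, image: ScalarImage3D) -> None:
    vox = image.world_to_voxel(surface.vertices)
    hi = np.array(image.data.shape) - 1
    if np.any(vox < -0.5) or np.any(vox > hi + 0.5):
        raise ValueError("surface extends outside the image domain")


def image_energy(surface: TriSurface, image: ScalarImage3D, model: AppearanceModel) -> float:
    """Voxel-sum discretization of the misclassification energy:
    sum over inside voxels of log p_ext(I) plus outside voxels of
    log p_int(I), times the voxel volume."""
    _check_surface_in_image(surface, image)
    inside = voxelize_mask(surface, image.data.shape, image.affine)
    lp_ext = model.outside.log_pdf(image.data)
    lp_int = model.inside.log_pdf(image.data)
    total = lp_ext[inside].sum() + lp_int[~inside].sum()
    return float(total * image.voxel_volume)


def image_gradient(surface: TriSurface, image: ScalarImage3D, model: AppearanceModel) -> np.ndarray:
    """Face-center quadrature of the boundary integral: per vertex,
    (1/3) sum over incident faces of g(c_f) N_f with
    g = log[p_ext(I)/p_int(I)] trilinearly sampled at face centers."""
    _check_surface_in_image(surface, image)
    geo = face_geometry(surface)
    g = model.log_ratio(image.sample(geo.centers))
    grad = np.zeros_like(surface.vertices)
    contrib = (g[:, None] * geo.normals) / 3.0
    for i in range(3):
        np.add.at(grad, surface.faces[:, i], contrib)
    return grad


# ---------------------------------------------------------------------------
# Attachment-term objects consumed by the optimizer
# ---------------------------------------------------------------------------

@dataclass
class CurrentsAttachment:
    """Currents matching against a fixed target surface."""

    target: TriSurface
    kernel: KernelSpec

    def __post_init__(self):
        self._gt = face_geometry(self.target)
        self._self_term = _pair_sum(
            self._gt.centers, self._gt.normals, self._gt.centers, self._gt.normals, self.kernel
        )

    def energy(self, deformed: TriSurface) -> float:
        gd = face_geometry(deformed)
        return (
            _pair_sum(gd.centers, gd.normals, gd.centers, gd.normals, self.kernel)
            - 2.0 * _pair_sum(gd.centers, gd.normals, self._gt.centers, self._gt.normals, self.kernel)
            + self._self_term
        )

    def gradient(self, deformed: TriSurface) -> np.ndarray:
        return currents_gradient(deformed, self.target, self.kernel)


@dataclass
class LandmarkAttachment:
    """Landmark matching: template landmarks (vertex indices) vs targets."""

    template_landmarks: LandmarkSet
    target_landmarks: LandmarkSet

    def __post_init__(self):
        if self.template_landmarks.vertex_indices is None:
            raise ValueError("template landmarks must carry vertex indices")
        if len(self.template_landmarks) != len(self.target_landmarks):
            raise ValueError("landmark count mismatch")

    def energy(self, deformed: TriSurface) -> float:
        idx = self.template_landmarks.vertex_indices
        X = deformed.vertices[idx]
        return float(np.sum((X - self.target_landmarks.points) ** 2))

    def gradient(self, deformed: TriSurface) -> np.ndarray:
        return landmark_gradient(deformed, self.template_landmarks, self.target_landmarks)


@dataclass
class ImageAttachment:
    """Inside/outside appearance matching against a fixed image."""

    image: ScalarImage3D
    model: AppearanceModel

    def energy(self, deformed: TriSurface) -> float:
        return image_energy(deformed, self.image, self.model)

    def gradient(self, deformed: TriSurface) -> np.ndarray:
        return image_gradient(deformed, self.image, self.model)
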