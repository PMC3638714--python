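"""Tangent-space PCA of initial momentum fields.

Statistics are taken under the Riemannian (kernel) inner product of the
momentum representation at the template configuration,

    <alpha, beta>_T = sum_{k,l} K(x_k0, x_l0) (a_k . b_l),

so a principal component is itself a momentum field and the model doubles
as a generator: shooting the template with alpha = mean + sum_i k_i u_i
produces a shape whose typicality is measured by the Mahalanobis distance
sqrt(sum_i k_i^2 / lambda_i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mesh import TriSurface
from .shooting import KernelSpec, _sqdist

__all__ = [
    "ShapePCAModel",
    "momentum_inner_product",
    "metric_gram",
    "fit_pca",
    "project",
    "reconstruct",
    "mahalanobis",
    "p_value",
    "save_model",
    "load_model",
]


def metric_gram(template_vertices: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Kernel matrix K(x_k0, x_l0) on the template vertices."""
    x = np.asarray(template_vertices, float)
    return kernel.gamma(_sqdist(x, x))


def momentum_inner_product(
    alpha: np.ndarray,
    beta: np.ndarray,
    template: TriSurface,
    kernel: KernelSpec,
    gram: np.ndarray | None = None,
) -> float:
    """<alpha, beta>_T = sum_kl K(x_k0, x_l0) a_k.b_l (symmetric, PSD)."""
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    if a.shape != (template.n_vertices, 3) or b.shape != a.shape:
        raise ValueError("momentum fields must be (L, 3) bound to the template")
    G = metric_gram(template.vertices, kernel) if gram is None else gram
    return float(np.einsum("kc,kl,lc->", a, G, b))


@dataclass
class ShapePCAModel:
    """Momentum-PCA shape model anchored at a template surface.

    ``components`` has shape (D, L, 3) with <u_i, u_j>_T = delta_ij;
    ``eigenvalues`` are the per-component variances, sorted descending.
    ``training_distances`` are Mahalanobis distances of the training set,
    kept for empirical P-values.
    """

    template: TriSurface
    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    kernel: KernelSpec
    training_distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.components = np.asarray(self.components, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        L = self.template.n_vertices
        if self.mean.shape != (L, 3):
            raise ValueError("mean momentum must be (L, 3)")
        if self.components.ndim != 3 or self.components.shape[1:] != (L, 3):
            raise ValueError("components must be (D, L, 3)")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def momentum_from_coefficients(self, k: np.ndarray) -> np.ndarray:
        """alpha = mean + sum_i k_i u_i."""
        k = np.asarray(k, float)
        return self.mean + np.einsum("i,ilc->lc", k, self.components)


def fit_pca(
    momenta,
    template: TriSurface,
    kernel: KernelSpec,
    variance_fraction: float = 0.95,
    max_components: int | None = None,
) -> ShapePCAModel:
    """Gram-matrix PCA of momentum fields under the kernel metric.

    The Gram matrix of centered samples is eigendecomposed; components are
    the corresponding linear combinations of centered samples normalised
    to unit metric norm, and lambda_m = (m-th eigenvalue) / (n - 1).  The
    retained dimension is the smallest reaching ``variance_fraction`` of
    the total variance (optionally capped at ``max_components``).
    """
    A = np.asarray(momenta, float)  # (n, L, 3)
    n = len(A)
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    G = metric_gram(template.vertices, kernel)
    mean = A.mean(axis=0)
    C = A - mean
    gram = np.einsum("ikc,kl,jlc->ij", C, G, C)
    gram = 0.5 * (gram + gram.T)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(evals.max(initial=0.0), 0.0) * 1e-12
    rank = int(np.sum(evals > tol))
    lam_all = np.maximum(evals, 0.0) / (n - 1)
    total = lam_all.sum()
    cum = np.cumsum(lam_all)
    D = int(np.searchsorted(cum, variance_fraction * total) + 1)
    if max_components is not None and D > max_components:
        D = max_components
    if D > rank:
        import warnings

        warnings.warn(
            f"requested dimension truncated to numerical rank {rank}", stacklevel=2
        )
        D = rank

    comps = np.einsum("im,ilc->mlc", evecs[:, :D], C)  # (D, L, 3), norm sqrt(eval)
    comps /= np.sqrt(evals[:D])[:, None, None]
    model = ShapePCAModel(template, mean, comps, lam_all[:D], kernel)

    ks = np.array([project(a, model, gram=G) for a in A])
    model.training_distances = np.array([mahalanobis(k, model) for k in ks])
    return model


def project(alpha: np.ndarray, model: ShapePCAModel, gram: np.ndarray | None = None) -> np.ndarray:
    """Coefficients k_i = <alpha - mean, u_i>_T."""
    G = metric_gram(model.template.vertices, model.kernel) if gram is None else gram
    diff = np.asarray(alpha, float) - model.mean
    return np.einsum("ilc,lm,mc->i", model.components, G, diff)


def reconstruct(k: np.ndarray, model: ShapePCAModel) -> np.ndarray:
    """Momentum field mean + sum_i k_i u_i."""
    return model.momentum_from_coefficients(k)


def mahalanobis(k: np.ndarray, model: ShapePCAModel) -> float:
    """sqrt(sum_i k_i^2 / lambda_i): coefficient deviations in sd units."""
    k = np.asarray(k, float)
    lam = model.eigenvalues[: len(k)]
    if np.any(lam <= 0):
        raise ValueError("zero eigenvalue in Mahalanobis distance")
    return float(np.sqrt(np.sum(k * k / lam)))


def p_value(distance: float, model: ShapePCAModel) -> float:
    """Empirical right-tail P-value of a Mahalanobis distance.

    Uses (r + 1) / (n + 1) smoothing, r = number of training distances
    >= the query, so P never reaches exactly 0.
    """
    d = model.training_distances
    if len(d) < 20:
        raise ValueError("model carries too few training distances for P-values")
    r = int(np.sum(d >= distance))
    return (r + 1) / (len(d) + 1)


# ---------------------------------------------------------------------------
# Model archive (single .npz with a JSON header)
# ---------------------------------------------------------------------------

_MODEL_VERSION = 1


def save_model(model: ShapePCAModel, path: str) -> None:
    header = json.dumps(
        {"format": "gdas-shape-pca", "version": _MODEL_VERSION,
         "kernel_tau": model.kernel.tau, "kernel_family": model.kernel.family}
    )
    np.savez(
        path,
        header=np.array(header),
        vertices=model.template.vertices,
        faces=model.template.faces,
        mean=model.mean,
        components=model.components,
        eigenvalues=model.eigenvalues,
        training_distances=model.training_distances,
    )


def load_model(path: str) -> ShapePCAModel:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "gdas-shape-pca":
            raise ValueError("not a shape-PCA model archive")
        kernel = KernelSpec(float(header["kernel_tau"]), header["kernel_family"])
        return ShapePCAModel(
            TriSurface(z["vertices"], z["faces"]),
            z["mean"], z["components"], z["eigenvalues"], kernel,
            z["training_distances"],
        )
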