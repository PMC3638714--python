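"""Geodesic shooting for point-set LDDMM.

A deformation is encoded by the template vertex set ``x0`` and an initial
momentum field ``a0`` (one 3-vector per vertex).  The pair evolves under
the point-set geodesic (Hamiltonian) equations

    dx_k/dt =  sum_l gamma_kl a_l
    da_k/dt = -2 sum_l gamma'_kl (a_l . a_k) (x_k - x_l)

with gamma_kl = gamma(||x_k - x_l||^2) and the Gaussian kernel
gamma(s) = exp(-s / (2 tau^2)).  The flow extends to any ambient point by
interpolation through the kernel, defining a diffeomorphism phi whose
Jacobian satisfies the momentum conservation law

    a_l(t) = Dphi(t, x_l)^{-T} a_l(0).

Integration is classical RK4 on [0, 1]; the Hamiltonian
H = 1/2 sum_kl gamma_kl a_k.a_l is conserved along exact geodesics and its
drift is the integration-quality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelSpec",
    "GeodesicTrajectory",
    "kernel_eval",
    "default_kernel_width",
    "shoot",
    "flow_points",
    "check_conservation",
    "hamiltonian",
    "hamiltonian_drift",
]


@dataclass(frozen=True)
class KernelSpec:
    """Radially symmetric Gaussian smoothing kernel of width ``tau`` (mm)."""

    tau: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("kernel width tau must be positive")
        if self.family != "gaussian":
            raise ValueError("only the gaussian kernel family is supported")

    # gamma and derivatives as functions of squared distance s
    def gamma(self, s):
        return np.exp(-s / (2.0 * self.tau**2))

    def dgamma(self, s):
        return -self.gamma(s) / (2.0 * self.tau**2)

    def d2gamma(self, s):
        return self.gamma(s) / (4.0 * self.tau**4)


def kernel_eval(x, y, kernel: KernelSpec):
    """K(x, y) = exp(-||x - y||^2 / (2 tau^2)); symmetric, in (0, 1]."""
    d2 = np.sum((np.asarray(x, float) - np.asarray(y, float)) ** 2, axis=-1)
    return kernel.gamma(d2)


def default_kernel_width(vertices: np.ndarray) -> float:
    """Default deformation-kernel width: a quarter of the bounding-box diagonal."""
    v = np.asarray(vertices, float)
    return 0.25 * float(np.linalg.norm(v.max(axis=0) - v.min(axis=0)))


def _sqdist(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - y[None, :, :]
    return np.einsum("klc,klc->kl", diff, diff)


def _rhs(x: np.ndarray, a: np.ndarray, kernel: KernelSpec):
    """Right-hand side of the geodesic equations."""
    s = _sqdist(x, x)
    G = kernel.gamma(s)
    Gp = kernel.dgamma(s)
    dx = G @ a
    W = Gp * (a @ a.T)
    da = -2.0 * (W.sum(axis=1)[:, None] * x - W @ x)
    return dx, da


@dataclass
class GeodesicTrajectory:
    """Time-discretized geodesic states on [0, 1] (n_steps + 1 of each)."""

    times: np.ndarray       # (n+1,)
    positions: np.ndarray   # (n+1, L, 3)
    momenta: np.ndarray     # (n+1, L, 3)
    kernel: KernelSpec
    integrator: str = "rk4"

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    @property
    def x0(self) -> np.ndarray:
        return self.positions[0]

    @property
    def a0(self) -> np.ndarray:
        return self.momenta[0]

    @property
    def endpoint(self) -> np.ndarray:
        return self.positions[-1]


def _rk4_step(x, a, h, kernel):
    k1x, k1a = _rhs(x, a, kernel)
    k2x, k2a = _rhs(x + 0.5 * h * k1x, a + 0.5 * h * k1a, kernel)
    k3x, k3a = _rhs(x + 0.5 * h * k2x, a + 0.5 * h * k2a, kernel)
    k4x, k4a = _rhs(x + h * k3x, a + h * k3a, kernel)
    xn = x + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
    an = a + (h / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
    return xn, an


def shoot(
    x0: np.ndarray,
    a0: np.ndarray,
    kernel: KernelSpec,
    n_steps: int = 10,
) -> GeodesicTrajectory:
    """Integrate the geodesic equations from (x0, a0) over t in [0, 1]."""
    x = np.asarray(x0, dtype=np.float64)
    a = np.asarray(a0, dtype=np.float64)
    if x.shape != a.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("x0 and a0 must both be (L, 3) arrays")
    h = 1.0 / n_steps
    xs = np.empty((n_steps + 1,) + x.shape)
    as_ = np.empty_like(xs)
    xs[0], as_[0] = x, a
    for i in range(n_steps):
        x, a = _rk4_step(x, a, h, kernel)
        if not (np.isfinite(x).all() and np.isfinite(a).all()):
            raise FloatingPointError(f"geodesic integration diverged at step {i + 1}")
        xs[i + 1], as_[i + 1] = x, a
    t = np.linspace(0.0, 1.0, n_steps + 1)
    return GeodesicTrajectory(t, xs, as_, kernel)


# ---------------------------------------------------------------------------
# Flowing ambient points (and their Jacobians) through the diffeomorphism
# ---------------------------------------------------------------------------

def _velocity_at(q, x, a, kernel):
    """v(q) = sum_l K(q, x_l) a_l for a batch of points q."""
    s = _sqdist(q, x)
    return kernel.gamma(s) @ a


def _velocity_jac_at(q, x, a, kernel):
    """dv/dq at each q: sum_l 2 gamma'(||q - x_l||^2) a_l (q - x_l)^T."""
    diff = q[:, None, :] - x[None, :, :]            # (n, L, 3)
    s = np.einsum("nlc,nlc->nl", diff, diff)
    w = 2.0 * kernel.dgamma(s)                      # (n, L)
    return np.einsum("nl,lc,nld->ncd", w, a, diff)  # (n, 3, 3)


def flow_points(
    traj: GeodesicTrajectory,
    points: np.ndarray,
    with_jacobian: bool = False,
    return_path: bool = False,
):
    """Transport arbitrary points through the diffeomorphism of a trajectory.

    Re-integrates the coupled system (x, a, phi[, Dphi]) with RK4 from the
    trajectory's initial condition, so applying it to the control points
    reproduces the trajectory endpoints exactly.  With ``with_jacobian``
    the Jacobian flow dJ/dt = (dv/dx)(phi) J, J(0) = I, is carried along.
    """
    q = np.atleast_2d(np.asarray(points, dtype=np.float64)).copy()
    x, a = traj.x0.copy(), traj.a0.copy()
    kernel = traj.kernel
    n = traj.n_steps
    h = 1.0 / n
    J = np.tile(np.eye(3), (len(q), 1, 1)) if with_jacobian else None
    qs = [q.copy()]
    Js = [J.copy()] if with_jacobian else None

    weights = (1.0, 2.0, 2.0, 1.0)
    for _ in range(n):
        # control-system stages (x, a): stage i evaluated at x + c_i h k_{i-1}
        kx1, ka1 = _rhs(x, a, kernel)
        z2 = (x + 0.5 * h * kx1, a + 0.5 * h * ka1)
        kx2, ka2 = _rhs(*z2, kernel)
        z3 = (x + 0.5 * h * kx2, a + 0.5 * h * ka2)
        kx3, ka3 = _rhs(*z3, kernel)
        z4 = (x + h * kx3, a + h * ka3)
        kx4, ka4 = _rhs(*z4, kernel)
        stages = ((x, a), z2, z3, z4)
        incr = (0.0, 0.5 * h, 0.5 * h, h)

        kq = []
        kJ = [] if with_jacobian else None
        for s_idx, (xs_, as_) in enumerate(stages):
            q_s = q if s_idx == 0 else q + incr[s_idx] * kq[s_idx - 1]
            kq.append(_velocity_at(q_s, xs_, as_, kernel))
            if with_jacobian:
                J_s = J if s_idx == 0 else J + incr[s_idx] * kJ[s_idx - 1]
                kJ.append(_velocity_jac_at(q_s, xs_, as_, kernel) @ J_s)

        q = q + (h / 6.0) * sum(w * k for w, k in zip(weights, kq))
        if with_jacobian:
            J = J + (h / 6.0) * sum(w * k for w, k in zip(weights, kJ))
        x = x + (h / 6.0) * (kx1 + 2 * kx2 + 2 * kx3 + kx4)
        a = a + (h / 6.0) * (ka1 + 2 * ka2 + 2 * ka3 + ka4)
        qs.append(q.copy())
        if with_jacobian:
            Js.append(J.copy())

    if return_path:
        return (np.array(qs), np.array(Js)) if with_jacobian else np.array(qs)
    return (q, J) if with_jacobian else q


def check_conservation(traj: GeodesicTrajectory) -> float:
    """Maximum relative residual of the momentum conservation law.

    Integrates the Jacobian flow Dphi(t, x_l) at the control points and
    compares Dphi^{-T} a_l(0) against the integrated momenta a_l(t).
    """
    paths, Jacs = flow_points(traj, traj.x0, with_jacobian=True, return_path=True)
    a0 = traj.a0
    scale = max(float(np.linalg.norm(traj.momenta, axis=2).max()), 1e-300)
    worst = 0.0
    for i in range(len(traj.times)):
        J = Jacs[i]
        det = np.linalg.det(J)
        if np.any(np.abs(det) < 1e-12):
            raise FloatingPointError("singular Jacobian: diffeomorphism violated numerically")
        # Dphi^{-T} a0  ==  solve(Dphi^T, a0)
        transported = np.linalg.solve(np.swapaxes(J, 1, 2), a0[..., None])[..., 0]
        err = np.linalg.norm(transported - traj.momenta[i], axis=1).max()
        worst = max(worst, err / scale)
    return worst


def hamiltonian(x: np.ndarray, a: np.ndarray, kernel: KernelSpec) -> float:
    """H = 1/2 sum_kl gamma_kl (a_k . a_l); conserved along geodesics."""
    G = kernel.gamma(_sqdist(np.asarray(x, float), np.asarray(x, float)))
    return 0.5 * float(np.einsum("kc,kl,lc->", np.asarray(a, float), G, np.asarray(a, float)))


def write_momentum(momentum: np.ndarray, path: str) -> None:
    """Plain-text momentum table, one 'ax ay az' row per template vertex."""
    np.savetxt(path, np.asarray(momentum, float), fmt="%.17g")


def read_momentum(path: str) -> np.ndarray:
    a = np.loadtxt(path, ndmin=2)
    if a.shape[1] != 3:
        raise ValueError("momentum table must have 3 columns")
    return a


def hamiltonian_drift(traj: GeodesicTrajectory) -> float:
    """max_t |H(t) - H(0)| / H(0) (0 when H(0) = 0)."""
    H = np.array([hamiltonian(x, a, traj.kernel)
                  for x, a in zip(traj.positions, traj.momenta)])
    if H[0] == 0.0:
        return float(np.abs(H).max())
    return float(np.abs(H - H[0]).max() / abs(H[0]))
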