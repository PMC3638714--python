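# Methods

## Model

A shape is represented as the endpoint of a geodesic flow of a template
surface under the large-deformation diffeomorphic metric mapping (LDDMM)
point-set model.  For a closed triangulated template with vertices
x₁⁰…x_L⁰, the control variable is the **initial momentum** α = (a₁…a_L),
one 3-vector per vertex.  With the Gaussian kernel
K(x, y) = exp(−‖x−y‖²/2τ²) and γ_kl = γ(‖x_k−x_l‖²), the vertices and
momenta evolve by the point-set geodesic (Hamiltonian) equations

    dx_k/dt =  Σ_l γ_kl a_l
    da_k/dt = −2 Σ_l γ′_kl (a_l·a_k)(x_k − x_l)

on t ∈ [0, 1].  The flow extends to every ambient point through the
kernel, dφ/dt = Σ_l K(φ, x_l(t)) a_l(t), giving a diffeomorphism: the
deformed surface keeps the template's topology by construction.  Along
the flow the momentum obeys the conservation law
a_l(t) = Dφ(t, x_l)^{−T} a_l(0), and the Hamiltonian
H = ½ Σ_kl γ_kl a_k·a_l is constant; both are used as integration
diagnostics, not constraints.

**Shape prior.**  Tangent-space PCA is taken under the Riemannian
(kernel) inner product at the template,
⟨α, β⟩_T = Σ_kl K(x_k⁰, x_l⁰) a_k·b_l, which equals the RKHS norm of the
initial velocity field.  A model consists of a mean momentum ᾱ,
orthonormal components u₁…u_D and variances λ₁ ≥ … ≥ λ_D.  Fitting is by
the Gram-matrix (dual) route: eigendecompose G_ij = ⟨α_i−ᾱ, α_j−ᾱ⟩_T,
λ_m = eig_m/(n−1) (unbiased convention), components normalised to unit
metric norm.  Coefficients of a momentum are k_i = ⟨α−ᾱ, u_i⟩_T; the
Mahalanobis distance √(Σ k_i²/λ_i) measures typicality, with empirical
right-tail P-values smoothed as (r+1)/(n+1) so P never reaches 0.

**Segmentation energy.**  Over coefficients k the objective is
E(k) = Σ_n k_n²/λ_n + E2(S^α)/σ², with α = ᾱ + Σ k_n u_n and S^α the
template flowed to t = 1.  Three interchangeable attachment terms E2:

* **currents** — the squared kernel-dual distance between oriented
  surfaces, computed from face centers c_f and area-weighted normals
  N_f = ½ e_{f,3} × e_{f,2} (self + self − 2·cross double sums); no
  point correspondence required, robust to jagged voxelized targets;
* **landmarks** — Σ_i ‖X_i(1) − Y_i‖² over template-vertex landmarks
  flowed by the same geodesic, with σ² set from voxel size as
  ((Δx/2)² + (Δy/2)² + (Δz/2)²)/3 (for 0.93×0.93×2.0 mm voxels this
  evaluates to 0.477483 mm²);
* **image** — ∫_int log p_ext(I) + ∫_ext log p_int(I), the integrated
  log-likelihood of misclassification under inside/outside Gaussian
  mixtures, discretized as a sum over voxel centers (parity scan
  conversion decides sides).

**Gradient.**  dE/dk_n = 2k_n/λ_n + σ^{-2}(dE2/dα)ᵀu_n, where dE2/dα is
obtained by pulling the attachment's vertex gradient dE2/dx(1) back
through the flow.  This package uses the *discrete* adjoint of the RK4
integrator: reverse-mode propagation through every RK4 stage with
analytic Jacobian-transpose products of the geodesic right-hand side, so
the computed gradient is exact (to round-off) for the trajectory the
optimizer integrates; central-difference checks agree to ~1e−9.
The currents gradient is closed-form (per face f at corner i:
P_f × e_{f,i} + (4/3)Q_f, with P_f the kernel-smoothed normal field and
Q_f the kernel-derivative moment).  The image gradient uses the
face-center quadrature (1/3)Σ_{f∋k} g(c_f)N_f with
g = log(p_ext/p_int) trilinearly sampled; it is *not* the exact
derivative of the voxel-sum energy, and directional derivatives agree
with the voxel sum at the few-percent level on smooth cases (tested at
5%).

**Optimization.**  Gradient descent on k from k = 0 (the mean shape)
with a backtracking line search: the step halves until the energy
decreases and grows by 1.5× after an immediate acceptance; convergence
when the relative energy change stays below 1e−6 for 3 consecutive
iterations (500-iteration cap).  Everything is deterministic given the
configuration.

## Numerical choices

* Integrator: classical RK4, default 10 steps on [0, 1] (20 in accuracy
  checks).  Observed endpoint convergence order ≈ 4; Hamiltonian drift
  ≤ 1e−6 for momenta up to the kernel-width scale.
* Deformation-kernel width τ defaults to ¼ of the template bounding-box
  diagonal; the surface-matching kernel K_S is independent (default
  5 mm).
* Face normals follow N_f = ½ e_{f,3} × e_{f,2}; with counter-clockwise
  winding this vector points *inward*, so constructors wind faces such
  that it points outward (signed-volume check, `orient_outward`).
* Curvature: mean curvature from the cotangent Laplacian, Gaussian from
  the angle deficit, mixed-Voronoi vertex areas; the smoothness score
  ∫(κ₁²+κ₂²)dA uses κ₁²+κ₂² = 4H²−2K and reaches 8π on a sphere within
  2% at ≥ 5000 faces.
* Inside/outside: generalized winding number (van Oosterom–Strackee
  solid angles); tie rule |w| > ½.  Voxelization is independent parity
  scan conversion along grid columns with a fixed sub-voxel nudge
  against edge-grazing degeneracies.
* Mixture EM: means initialised at evenly spread sample quantiles,
  pooled variance, uniform weights; tol 1e−7 relative log-likelihood,
  ≤ 500 iterations; a component collapsing below 1e−8 of the data
  variance is re-seeded at a random data point (seeded RNG).  Mixture
  densities are floored at 1e−300 before logs.  Histogram equalization
  maps 256 ROI quantiles onto reference quantiles, piecewise-linear in
  between.
* κ overlap: (p_agree − p_random)/(1 − p_random) with
  p_random = q_a q_b + (1−q_a)(1−q_b).  κ depends on the probing domain
  Ω; Monte-Carlo mode probes the union bounding box of both foregrounds
  expanded by 20% and reports it, exact mode counts same-grid voxels.
  Absolute κ values are therefore not comparable across domain choices.
* Surface distances are nearest-*vertex*, pooled both ways — cheap and
  well-defined but mesh-resolution dependent; d50/d80 are the smallest
  distances whose empirical c.d.f. reaches 0.5/0.8.

## Synthetic study conditions

The generator (`gdas.synthetic`) emulates a hippocampus ROI study
without any clinical data:

* **Template**: icosphere scaled to semi-axes (20, 8, 7) mm — an
  elongated, hippocampus-scale ellipsoid.  Subdivision 2 (162 vertices)
  is the default study size so that full fits run in seconds on one
  CPU; subdivision 3 (642 vertices) is used where only geometry is
  exercised.
* **Planted shape model**: 5 components built from low-frequency
  Gaussian momentum bumps, Gram–Schmidt orthonormalized in the kernel
  metric; eigenvalues λ₁·(1, ½, ¼, ⅛, 1/16) with λ₁ = 25, which makes a
  1-sd leading mode displace the surface by ≈ 2–4 mm — realistic
  population variability for a 40 mm structure.
* **Landmark protocol**: one landmark at each tip of the
  anterior–posterior (longest principal) axis plus 9 evenly spaced
  cross-section planes, each contributing its 4 extremal contour points
  along the transverse principal directions: 38 landmarks, fixed
  ordering, snapped to surface vertices.  Placement noise is i.i.d.
  Gaussian with per-coordinate variance at (0.01, 0.1, 1, 10, 100)×
  the voxel-derived base σ² = 0.477483 mm².
* **Images**: voxelized segmentations (scan conversion), jagged
  marching-cubes isosurfaces as currents targets, and T1-like volumes
  with intensities drawn from inside (3-component) / outside
  (4-component) Gaussian mixtures, optional Gaussian blur for
  partial-volume effect.

What the generator does **not** emulate: real MR physics (bias fields,
Rician noise), rater-specific landmark bias, multi-structure scenes, or
the irregular topology-preserving variability of real hippocampi.
Passing tests therefore demonstrate the correctness and robustness of
the machinery under the stated model, not clinical accuracy.

## Robustness experiment

`gdas.evaluate.robustness_report` reruns the simulated design: for each
sampled shape and noise level, GDAS (base σ², prior active) and a
classical landmark-LDDMM baseline are fit to the same noisy landmarks
and scored by exact-voxel κ against the ground-truth voxelization at
1 mm.  The baseline shoots one free momentum per landmark with the same
integrator and is run in its exact-matching regime (attachment weight
σ²/100) so it nearly interpolates the landmarks — the behaviour of a
traditional landmark-matching pipeline, and deliberately so: with
heavily corrupted landmarks it overfits, and the comparison shows the
prior-constrained fit degrading gracefully (higher mean κ, smaller
spread across shapes at 100× noise).

## Known limitations

* The currents energy is O(M·M′) in face counts; fine targets (dense
  marching-cubes isosurfaces) dominate runtime.
* The image term assumes a homogeneous inside/outside appearance; no
  spatially varying model, no multi-channel images.
* Landmark targets are assumed pre-aligned; a least-squares similarity
  (Umeyama) utility is provided outside the optimization loop.
* Template estimation from a population is out of scope — the template
  is always an input.
* Nearest-vertex distance reports depend on mesh resolution, and κ on
  the probing domain; both are reported with their settings rather than
  normalised away.
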