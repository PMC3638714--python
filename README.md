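# gdas — geodesically controlled diffeomorphic active shapes

Segmentation and registration of closed anatomical surfaces (hippocampus
and other subcortical structures) for researchers running ROI-based
morphometry pipelines.  A template surface is deformed by a **geodesic
diffeomorphic flow** encoded entirely by an initial momentum field, and
that momentum is constrained to the span of a **tangent-space PCA**
shape model, so every fit stays a topology-preserving deformation that
looks like the training population — robust where unconstrained
registration overfits noisy data.

## The model

For a template with vertices x₁⁰…x_L⁰ and Gaussian kernel
K(x,y) = exp(−‖x−y‖²/2τ²), the initial momentum α = (a₁…a_L) drives the
point-set geodesic equations

    dx_k/dt =  Σ_l γ_kl a_l,      da_k/dt = −2 Σ_l γ′_kl (a_l·a_k)(x_k−x_l),

whose flow extends to a diffeomorphism of all of ℝ³.  With a PCA model
(mean ᾱ, orthonormal components u_n under the kernel metric, variances
λ_n), segmentation minimises over coefficients k:

    E(k) = Σ_n k_n²/λ_n  +  E2(S^α)/σ²,    α = ᾱ + Σ_n k_n u_n,

where E2 is one of three interchangeable data-attachment terms:
**surface currents** (kernel-dual distance between oriented meshes),
**landmarks** (squared distances of flowed template landmarks), or an
**inside/outside image model** (integrated misclassification
log-likelihood under Gaussian mixtures).  The gradient of E2 with
respect to α is computed by the exact discrete adjoint of the RK4
shooting integrator.  Recovered coefficients carry uncertainty-free
interpretation: Mahalanobis distance √(Σ k_n²/λ_n) and empirical
P-values measure shape typicality.

Everything needed to exercise the pipeline is generated synthetically
(`gdas.synthetic`): hippocampus-like ellipsoidal templates, planted
momentum-PCA models, sampled shapes, the 38-landmark slice protocol
with calibrated placement noise, voxelized segmentations, jagged
isosurfaces and T1-like images.

## Worked example

`examples/landmark_matching.py` draws a shape from the planted model,
places the 38 protocol landmarks, corrupts them with placement noise at
the voxel-derived base variance σ² = 0.477 mm², and fits:

```
planted coefficients : [ 1.728  2.905  0.826 -2.304  1.132]
recovered coefficients: [ 1.941  2.754  1.337 -2.492  1.   ]
Mahalanobis error     : 0.261 sd
kappa vs ground truth : 0.967
iterations            : 12  (converged: True)
```

The five planted PCA coefficients are recovered to a fraction of a
standard deviation despite the noisy landmarks, and the fitted surface
overlaps the ground-truth voxelization with chance-corrected κ = 0.97
(κ ≈ 0.8 is considered good for subcortical structures).

`examples/robustness_experiment.py` repeats the fit over 5 shapes at
0.1×, 1× and 100× the base landmark noise, against a classical
exact-matching landmark-LDDMM baseline:

```
                 kappa_gdas        kappa_lddmm
                       mean    std        mean    std
noise_multiplier
0.1                   0.991  0.001       0.986  0.004
1.0                   0.979  0.009       0.954  0.011
100.0                 0.795  0.060       0.530  0.070
```

At low noise the two methods agree; at 100× noise the unconstrained
baseline overfits and collapses while the prior-constrained fit
degrades gracefully — the robustness property the method exists for.

The other examples cover currents matching to a jagged isosurface
(`surface_matching.py`, κ = 0.998 with a ~25× smoother surface than the
isosurface target), mixture-EM appearance training plus image-driven
segmentation (`image_segmentation.py`), and shape statistics with
P-values (`shape_statistics.py`).

## Layout

```
src/gdas/
  mesh.py       surfaces, face geometry, curvature, inside/outside, I/O
  image.py      3-D images and segmentations (NIfTI via nibabel)
  shooting.py   geodesic shooting, flows, conservation diagnostics
  pca.py        kernel-metric tangent-space PCA, Mahalanobis, P-values
  attachment.py currents / landmark / image energies and gradients, EM
  optimize.py   adjoint gradient, descent driver, LDDMM baseline
  synthetic.py  templates, planted models, landmark protocol, T1 rendering
  evaluate.py   kappa overlap, distance c.d.f.s, robustness experiment
docs/methods.md   full model description and numerical choices
examples/         one narrative script per capability
```
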