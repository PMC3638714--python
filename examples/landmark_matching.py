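"""Landmark-driven segmentation with a shape prior.

Builds the default synthetic study (planted 5-mode shape model on a
hippocampus-like ellipsoid), draws one target shape, places the
38-landmark slice protocol, adds placement noise at the voxel-derived
base variance, and fits the PCA coefficients.  Prints the recovered
coefficients against the planted truth, the Mahalanobis error in sd
units, and the overlap with the ground-truth voxelization.
"""

import numpy as np

from gdas.attachment import LandmarkAttachment
from gdas.evaluate import surface_kappa
from gdas.optimize import GDASConfig, gdas_fit
from gdas.pca import mahalanobis
from gdas.synthetic import SyntheticScenario
from gdas.voxelize import voxelize

data = SyntheticScenario().build()
k_true, target_surface = data.shapes[0]

targets = data.target_landmarks(0, noise_multiplier=1.0, seed=7)
attach = LandmarkAttachment(data.template_landmarks, targets)
config = GDASConfig(sigma2=data.scenario.base_variance, step_size=0.05,
                    max_iter=200, tol=1e-8)
result = gdas_fit(data.model, attach, config)

truth = voxelize(target_surface, spacing=1.0, padding=5.0)
kappa = surface_kappa(result.surface, truth)

np.set_printoptions(precision=3, suppress=True)
print("planted coefficients :", k_true)
print("recovered coefficients:", result.k)
print(f"Mahalanobis error     : {mahalanobis(result.k - k_true, data.model):.3f} sd")
print(f"kappa vs ground truth : {kappa:.3f}")
print(f"iterations            : {len(result.energy_trace) - 1}"
      f"  (converged: {result.converged})")
# The Mahalanobis error says how far, in per-mode standard deviations, the
# recovered shape coefficients sit from the planted ones; kappa is the
# chance-corrected volume overlap (1 = perfect, ~0.8 is a good subcortical
# segmentation).
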