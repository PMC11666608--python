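"""Recover a known rigid transform with Coherent Point Drift.

A bone-surface point sample is rotated and translated by a known pose; rigid
CPD (an EM fit of a Gaussian mixture with the moving points as centroids,
scale fixed at 1) must recover the inverse pose.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from bisym import CPDParams, RigidTransform, rigid_cpd
from bisym.cpd import farthest_point_sample
from bisym.synthetic import SyntheticPairSpec, canonical_right_tibia

bone = canonical_right_tibia(SyntheticPairSpec())
pts = bone.vertices[farthest_point_sample(bone.vertices, 500, seed=0)]

applied = RigidTransform(
    Rotation.from_rotvec(np.radians(18.0) * np.array([0.2, 0.9, 0.4]) / np.linalg.norm([0.2, 0.9, 0.4])).as_matrix(),
    np.array([8.0, -5.0, 12.0]),
)
moving = applied.apply(pts)

recovered, report = rigid_cpd(moving, pts, CPDParams())
residual = recovered.compose(applied)  # should be the identity

print(f"EM iterations: {report.iterations_run}, converged: {report.converged}")
print(f"residual rotation: {residual.rotation_angle_deg():.2e} deg")
print(f"residual translation: {np.linalg.norm(residual.translation):.2e} mm")
# Residuals at the 1e-6 level mean the recovered transform undoes the applied
# pose to numerical precision - the registration engine behind every
# superposition step of the symmetry pipeline.
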