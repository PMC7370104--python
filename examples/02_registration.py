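"""Recover a known rigid misalignment with landmark pre-alignment
followed by best-fit ICP at 0.01 mm precision.

This mirrors superimposing a segmented model, exported in its own
coordinate frame, onto the reference model: four anatomical landmarks
give a coarse alignment and the surface-based refinement finishes it.
"""

import numpy as np

from condylometry import (
    PhantomSpec,
    RigidTransform,
    apply_rigid,
    icp_refine,
    landmark_align,
    make_condyle_phantom,
)

mesh, landmarks = make_condyle_phantom(PhantomSpec(seed=3))

# displace the model by a known motion: 18 degrees, ~12 mm translation
motion = RigidTransform.from_axis_angle([1.0, 0.5, 0.2], 18.0, [8.0, -6.0, 5.0])
moved_mesh = apply_rigid(mesh, motion)
moved_landmarks = apply_rigid(landmarks, motion)

init = landmark_align(moved_landmarks, landmarks)
result = icp_refine(moved_mesh, mesh, init=init)

recovered = result.transform.apply_points(moved_mesh.vertices)
worst = np.abs(recovered - mesh.vertices).max()

print(f"ICP converged={result.converged} after {result.iterations} iterations")
print(f"final RMS surface distance : {result.rms:.2e} mm (precision 0.01 mm)")
print(f"worst vertex discrepancy   : {worst:.2e} mm")
# Both numbers should be far below the 0.01 mm precision contract.
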