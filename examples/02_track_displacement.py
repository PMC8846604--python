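"""Track a known rigid shift with multi-level NCC block matching.

A noiseless speckle pair shifted by exactly 4 samples axially and 1 A-line
laterally; the tracker should recover the shift at every interior block.
"""

import numpy as np

import echostrain as es

imaging = es.ImagingConfig(depth=8.0, lines=48)
motion = es.MotionModel.rigid_shift((4 * imaging.dz, imaging.pitch))
scene = es.SceneConfig(imaging=imaging, motion=motion, n_frames=4,
                       snr_db=None, seed=3)
seq, gt = es.generate_sequence(scene)

field = es.estimate_displacement_multilevel(seq.frames[:2], es.BMConfig(),
                                            regularizer="none")
interior = (slice(3, -3), slice(5, -5))
print(f"block grid          : {field.axial.shape}")
print(f"median axial shift  : {np.median(field.axial[interior]):.6f} samples (true 4)")
print(f"median lateral shift: {np.median(field.lateral[interior]):.6f} lines (true 1)")
print(f"max interior error  : {max(np.abs(field.axial[interior] - 4).max(), np.abs(field.lateral[interior] - 1).max()):.2e}")
# Interior blocks recover the shift exactly: an integer displacement keeps
# the matched windows bit-identical, so the correlation peak is exactly one
# and no sub-sample interpolation is needed.
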