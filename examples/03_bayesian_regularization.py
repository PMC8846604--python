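"""Bayesian regularization of similarity surfaces under heavy noise.

Tracks one frame pair of a beating-wall phantom at 5 dB sonographic SNR with
plain NCC and with spatial Bayesian regularization (SBR), and compares the
per-block error against the analytic ground truth.
"""

import numpy as np

import echostrain as es
from echostrain.experiments import desk_cyclic_scene, _wall_block_mask

scene = desk_cyclic_scene(seed=11, snr_db=5.0)
seq, gt = es.generate_sequence(scene)

t = 3  # a mid-cycle frame pair
results = {}
for reg in ("none", "sbr"):
    results[reg] = es.estimate_displacement_multilevel(
        seq.frames[t:t + 2], es.BMConfig(), reg, es.RegularizationParams())

f0 = results["none"]
zz, xx = np.meshgrid(f0.rows_mm, f0.cols_mm, indexing="ij")
wall = _wall_block_mask(f0, scene.motion)
pos = np.stack([zz.ravel(), xx.ravel()], axis=1)
u_true = gt.interframe_displacement(pos, t).reshape(zz.shape + (2,))

for reg, f in results.items():
    err = np.hypot(f.axial_mm - u_true[..., 0], f.lateral_mm - u_true[..., 1])
    name = "NCC (no regularization)" if reg == "none" else "SBR"
    print(f"{name:24s}: wall median error {np.median(err[wall]) * 1e3:6.1f} um, "
          f"95th pct {np.percentile(err[wall], 95) * 1e3:6.1f} um")
# The Bayesian posterior pools each block's correlation surface with its four
# neighbors, suppressing the false peaks that 5 dB noise induces; the 95th
# percentile error should drop by several-fold relative to plain NCC.
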