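"""Generate a synthetic RF speckle sequence and check its noise calibration.

Builds a 4-frame zero-motion scene at 15 dB sonographic SNR and verifies the
realized signal-to-noise power ratio in the reference ROI.
"""

import numpy as np

import echostrain as es

imaging = es.ImagingConfig(depth=8.0, lines=48)
scene = es.SceneConfig(imaging=imaging, n_frames=4, snr_db=15.0, seed=1)
noisy, gt = es.generate_sequence(scene)
clean, _ = es.generate_sequence(
    es.SceneConfig(imaging=imaging, n_frames=4, snr_db=None, seed=1))

frame = noisy.frames[0]
print(f"frame grid     : {frame.shape[0]} samples x {frame.shape[1]} lines "
      f"({imaging.depth} mm x {(imaging.lines - 1) * imaging.pitch:.1f} mm)")
print(f"axial sampling : {imaging.sampling_frequency} MHz "
      f"({imaging.dz * 1e3:.2f} um/sample)")

z0, z1, x0, x1 = (frame.shape[0] // 8, 3 * frame.shape[0] // 8,
                  frame.shape[1] // 4, 3 * frame.shape[1] // 4)
sig = clean.frames[0].samples[z0:z1, x0:x1]
noise = noisy.frames[0].samples[z0:z1, x0:x1] - sig
snr_meas = 10 * np.log10(np.mean(sig ** 2) / np.mean(noise ** 2))
print(f"requested SNR_s: 15.0 dB, realized in ROI: {snr_meas:.2f} dB")
# The realized ratio fluctuates with the finite ROI size but should sit
# within a fraction of a dB of the request: the generator calibrates the
# noise variance against the noiseless signal power of this exact ROI.
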