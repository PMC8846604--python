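"""Lagrangian strain over a full cardiac cycle on a beating-wall phantom.

Runs the complete pipeline (phantom -> tracking -> median filter -> mesh ->
accumulation -> least-squares strain -> segmental curves) for NCC and the
simultaneous spatiotemporal Bayesian regularizer, and prints the total
temporal relative error (TTR) of the radial strain curves.
"""

import numpy as np

import echostrain as es
from echostrain.experiments import desk_cyclic_scene

scene = desk_cyclic_scene(seed=11, snr_db=5.0)

for reg in ("ncc", "stbr2"):
    cfg = es.PipelineConfig(scene=scene, regularizer=reg, seed=11)
    report = es.run_pipeline(cfg)
    print(f"{reg:6s}: radial TTR {report['ttr_radial_pct']:6.2f} %,  "
          f"longitudinal TTR {report['ttr_longitudinal_pct']:6.2f} %,  "
          f"radial bias {report['bias_radial_pct']:+.2f} %")
# TTR measures how far each segmental strain-versus-time curve strays from
# the prescribed wall motion (0% = exact).  At 5 dB the spatiotemporal
# posterior should cut the radial TTR well below plain NCC.
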