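"""Benchmark experiments on the synthetic phantom.

These are the package's standard validation runs: translation recovery,
uniform-strain recovery, and the noise-robustness comparison of the
displacement estimators on a beating-wall phantom.  Problem sizes are desk
scale (see docs/methods.md); every run is a pure function of its seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .bayes import RegularizationParams
from .blockmatch import BMConfig, estimate_displacement_multilevel
from .phantom import ImagingConfig, MotionModel, SceneConfig, generate_sequence
from .pipeline import (default_mesh, evaluate_against_truth, strain_records,
                       track_sequence)
from .strain import median_filter_field, segment_strain_curves

#: block-grid margin (rows, cols) excluded as "interior": the outermost
#: blocks overlap the frame-edge transients of the windowed-sinc up-sampler
#: and the decimation filters
EDGE_MARGIN_BLOCKS = (3, 5)


def desk_imaging(depth: float = 8.0, lines: int = 48) -> ImagingConfig:
    return ImagingConfig(depth=depth, lines=lines)


def desk_cyclic_scene(seed: int, snr_db=5.0, n_frames: int = 17) -> SceneConfig:
    """Beating annular wall in speckle, one full cycle plus the extra frame
    the spatiotemporal window needs.

    The 16-frame cycle keeps the frame-to-frame velocity change small enough
    that the smooth-velocity assumption behind temporal regularization holds,
    as it does in real acquisitions (tens to hundreds of frames per cycle).
    """
    imaging = ImagingConfig(depth=9.5, lines=52)
    motion = MotionModel.cyclic_wall(center=(10.5, 5.0), r_endo=3.5, r_epi=5.5,
                                     theta_span=(-0.65, 0.65),
                                     peak_radial_strain=0.08,
                                     peak_longitudinal_strain=-0.06,
                                     cycle_frames=n_frames - 1)
    return SceneConfig(imaging=imaging, motion=motion, n_frames=n_frames,
                       snr_db=snr_db, seed=seed)


def translation_recovery(seed: int, shift_samples: float = 4.0,
                         shift_lines: float = 1.0):
    """Noiseless rigid-shift tracking; returns the maximum absolute error of
    the interior blocks (in samples / lines)."""
    imaging = desk_imaging()
    motion = MotionModel.rigid_shift((shift_samples * imaging.dz,
                                      shift_lines * imaging.pitch))
    scene = SceneConfig(imaging=imaging, motion=motion, n_frames=4,
                        snr_db=None, seed=seed)
    seq, _ = generate_sequence(scene)
    f = estimate_displacement_multilevel(seq.frames[:2], BMConfig(), "none")
    mr, mc = EDGE_MARGIN_BLOCKS
    interior = (slice(mr, -mr), slice(mc, -mc))
    err_ax = float(np.abs(f.axial[interior] - shift_samples).max())
    err_lat = float(np.abs(f.lateral[interior] - shift_lines).max())
    return err_ax, err_lat, int(f.axial[interior].size)


def uniform_strain_recovery(seed: int, strain_per_frame: float = 0.01,
                            snr_db: float = 40.0):
    """End-to-end axial-strain recovery on a uniform-strain phantom.

    Returns (mean LS axial strain at frame 1, relative error vs the
    prescribed strain, number of evaluated points).
    """
    imaging = desk_imaging()
    center = (imaging.depth / 2, (imaging.lines - 1) * imaging.pitch / 2)
    motion = MotionModel.uniform_strain((strain_per_frame, 0.0), center)
    scene = SceneConfig(imaging=imaging, motion=motion, n_frames=4,
                        snr_db=snr_db, seed=seed)
    seq, gt = generate_sequence(scene)
    fields = [median_filter_field(f)
              for f in track_sequence(seq, BMConfig(), "ncc")]
    mesh = default_mesh(gt, fields, 2400)
    tracked, records = strain_records(mesh, fields)
    good = records[1].flags == 0
    mean_strain = float(records[1].E[good, 0, 0].mean())
    rel_err = abs(mean_strain - strain_per_frame) / strain_per_frame
    return mean_strain, float(rel_err), int(good.sum())


def _wall_block_mask(field, motion: MotionModel):
    zz, xx = np.meshgrid(field.rows_mm, field.cols_mm, indexing="ij")
    p = motion.parameters
    cz, cx = p["center"]
    r = np.hypot(zz - cz, xx - cx)
    th = np.arctan2(xx - cx, -(zz - cz))
    t0, t1 = p["theta_span"]
    return ((r > p["r_endo"] - 0.3) & (r < p["r_epi"] + 0.3)
            & (th > t0 * 0.9) & (th < t1 * 0.9))


def cyclic_noise_benchmark(seed: int, snr_db=5.0,
                           methods: Sequence[str] = ("ncc", "sbr", "stbr2"),
                           reg_params: Optional[RegularizationParams] = None,
                           mesh_points: int = 2400) -> dict:
    """Track one noisy cardiac cycle with several estimators.

    Returns, per method, the wall-region displacement RMSE (mm, pooled over
    all frame pairs on the blocks every method left unflagged) and the mean
    radial / longitudinal TTR of the full Lagrangian strain pipeline.
    """
    if reg_params is None:
        reg_params = RegularizationParams()
    scene = desk_cyclic_scene(seed, snr_db)
    seq, gt = generate_sequence(scene)
    fields = {m: track_sequence(seq, BMConfig(), m, reg_params)
              for m in methods}
    f0 = next(iter(fields.values()))[0]
    wall = _wall_block_mask(f0, scene.motion)
    zz, xx = np.meshgrid(f0.rows_mm, f0.cols_mm, indexing="ij")
    pos = np.stack([zz.ravel(), xx.ravel()], axis=1)
    n_pairs = scene.n_frames - 1
    common = [np.logical_and.reduce([fields[m][t].flags == 0 for m in methods])
              for t in range(n_pairs)]
    out = {}
    for m in methods:
        sq, n = 0.0, 0
        for t in range(n_pairs):
            u_true = gt.interframe_displacement(pos, t).reshape(zz.shape + (2,))
            f = fields[m][t]
            e2 = ((f.axial_mm - u_true[..., 0]) ** 2
                  + (f.lateral_mm - u_true[..., 1]) ** 2)
            mask = wall & common[t]
            sq += float(e2[mask].sum())
            n += int(mask.sum())
        rmse = float(np.sqrt(sq / max(n, 1)))
        mfields = [median_filter_field(f) for f in fields[m]]
        mesh = default_mesh(gt, mfields, mesh_points)
        tracked, records = strain_records(mesh, mfields)
        curves = segment_strain_curves(records, tracked)
        rep = evaluate_against_truth(records, tracked, gt, curves)
        out[m] = {"rmse_mm": rmse,
                  "ttr_radial_pct": rep["ttr_radial_pct"],
                  "ttr_longitudinal_pct": rep["ttr_longitudinal_pct"],
                  "n_blocks": n}
    return out
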