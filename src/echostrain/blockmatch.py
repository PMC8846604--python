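"""Multi-level 2-D NCC block matching on RF ultrasound frames.

The tracker matches zero-normalized kernels from a pre-deformation frame
against a search region in the post-deformation frame, producing one
similarity-metric image (SMI) per block: the NCC surface over integer
(axial, lateral) lags.  A coarse-to-fine pyramid with align-and-stretch
companding between levels extends the effective search range while keeping
per-level searches small.  SMIs can be handed to the Bayesian regularizers in
:mod:`echostrain.bayes` before peak extraction.

Conventions: axis 0 is axial (depth, sample index grows with depth), axis 1
is lateral (A-line index).  Displacements are post-relative-to-pre.  Lag
grids are stored with an explicit ``lag_offset`` (the lag of element [0, 0]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.interpolate import RegularGridInterpolator

from ._interp import FLAG_ZERO_VAR, subsample_peak, upsample_axis

log = logging.getLogger(__name__)

@dataclass
class RFFrame:
    """One real-valued RF frame with its acquisition geometry.

    ``axial_fs`` in MHz, ``pitch`` in mm, ``center_frequency`` in MHz,
    ``sos`` (speed of sound) in m/s.
    """
    samples: np.ndarray
    axial_fs: float
    pitch: float
    center_frequency: float
    sos: float = 1540.0
    frame_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("RF frame must be a 2-D (samples x lines) grid")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF frame contains non-finite values")
        if min(self.axial_fs, self.pitch, self.center_frequency, self.sos) <= 0:
            raise ValueError("RF frame geometry must be positive")

    @property
    def shape(self):
        return self.samples.shape

    @property
    def dz_mm(self) -> float:
        """Axial sample spacing in mm (round-trip: c / (2 fs))."""
        return (self.sos * 1e-3) / (2.0 * self.axial_fs)

    @property
    def wavelength_samples(self) -> float:
        return self.axial_fs / self.center_frequency


@dataclass
class BMConfig:
    """Block-matching configuration.

    Per-level lists run coarse -> fine and must have length ``n_levels``.
    Kernel lengths are given axially in wavelengths (converted to samples at
    each level's sampling rate, rounded to the nearest odd integer) and
    laterally in A-lines.  Search half-ranges are in level samples/lines.
    ``upsample`` is the (axial, lateral) RF up-sampling factor applied before
    the pyramid is built.
    """
    n_levels: int = 3
    axial_decimation: Sequence[int] = (3, 2, 1)
    lateral_decimation: Sequence[int] = (2, 1, 1)
    axial_kernel_wavelengths: Sequence[float] = (8.0, 5.0, 3.0)
    lateral_kernel_lines: Sequence[int] = (13, 11, 9)
    kernel_overlap_pct: Sequence[float] = (25.0, 50.0)
    search_axial: Sequence[int] = (10, 5, 2)
    search_lateral: Sequence[int] = (5, 4, 3)
    upsample: Sequence[int] = (1, 2)
    refine_step: float = 0.01

    def __post_init__(self):
        for name in ("axial_decimation", "lateral_decimation",
                     "axial_kernel_wavelengths", "lateral_kernel_lines",
                     "search_axial", "search_lateral"):
            if len(getattr(self, name)) != self.n_levels:
                raise ValueError(f"{name} must have length n_levels={self.n_levels}")
        if any(f < 1 or int(f) != f for f in list(self.axial_decimation) + list(self.lateral_decimation)):
            raise ValueError("decimation factors must be positive integers")
        if not all(0 <= o < 100 for o in self.kernel_overlap_pct):
            raise ValueError("kernel overlaps must lie in [0, 100)")
        if any(int(u) != u or u < 1 for u in self.upsample):
            raise ValueError("upsample factors must be positive integers")

    @classmethod
    def table1(cls) -> "BMConfig":
        """Parameter set used for full-scale (125-frame, 78.84 MHz) studies."""
        return cls(n_levels=3,
                   axial_decimation=(3, 2, 1), lateral_decimation=(2, 1, 1),
                   axial_kernel_wavelengths=(8.0, 5.0, 1.0),
                   lateral_kernel_lines=(15, 12, 10),
                   kernel_overlap_pct=(10.0, 90.0),
                   upsample=(1, 2))

    @classmethod
    def desk(cls) -> "BMConfig":
        """Default desk-scale parameters (see docs/methods.md)."""
        return cls()


@dataclass
class SMI:
    """Similarity-metric image: NCC over integer lags for one block."""
    values: np.ndarray
    lag_offset: tuple[int, int]
    block_location: tuple[int, int]
    frame_pair: tuple[int, int]


@dataclass
class SMIStack:
    """SMIs for every block of one frame pair at one level.

    ``values`` has shape (n_rows, n_cols, n_axial_lags, n_lateral_lags);
    ``rows``/``cols`` are kernel-center coordinates in the level grid.
    """
    values: np.ndarray
    lag_offset: tuple[int, int]
    rows: np.ndarray
    cols: np.ndarray
    frame_pair: tuple[int, int]
    flags: np.ndarray

    def smi(self, i: int, j: int) -> SMI:
        return SMI(self.values[i, j], self.lag_offset,
                   (int(self.rows[i]), int(self.cols[j])), self.frame_pair)


@dataclass
class DisplacementField:
    """Inter-frame displacement on the block grid.

    ``axial``/``lateral`` are in (original) samples and lines;
    ``rows``/``cols`` are block-center coordinates in the same units.
    """
    axial: np.ndarray
    lateral: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    dz_mm: float
    pitch_mm: float
    frame_pair: tuple[int, int] = (0, 1)
    flags: np.ndarray = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(np.shape(self.axial), dtype=int)

    @property
    def axial_mm(self) -> np.ndarray:
        return self.axial * self.dz_mm

    @property
    def lateral_mm(self) -> np.ndarray:
        return self.lateral * self.pitch_mm

    @property
    def rows_mm(self) -> np.ndarray:
        return self.rows * self.dz_mm

    @property
    def cols_mm(self) -> np.ndarray:
        return self.cols * self.pitch_mm


@dataclass
class _LevelConfig:
    """Resolved per-level geometry (units: level samples / lines)."""
    kernel: tuple[int, int]
    search: tuple[int, int]
    step: tuple[int, int]
    rows: np.ndarray = field(default=None)
    cols: np.ndarray = field(default=None)


def _round_odd(x: float) -> int:
    k = int(round(x))
    if k % 2 == 0:
        k += 1 if x >= k else -1
    return max(k, 3)


def resolve_level(frame_shape, config: BMConfig, level: int,
                  wavelength_samples: float) -> _LevelConfig:
    """Kernel sizes, search ranges and the block grid for one pyramid level."""
    ka = _round_odd(config.axial_kernel_wavelengths[level] * wavelength_samples)
    kl = int(config.lateral_kernel_lines[level])
    if kl % 2 == 0:
        kl += 1
    sa, sl = int(config.search_axial[level]), int(config.search_lateral[level])
    step_a = max(1, int(round(ka * (1.0 - config.kernel_overlap_pct[0] / 100.0))))
    step_l = max(1, int(round(kl * (1.0 - config.kernel_overlap_pct[1] / 100.0))))
    lc = _LevelConfig(kernel=(ka, kl), search=(sa, sl), step=(step_a, step_l))
    h, w = frame_shape
    ma, ml = ka // 2 + sa, kl // 2 + sl
    rows = np.arange(ma, h - ma, step_a)
    cols = np.arange(ml, w - ml, step_l)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(
            f"level {level}: frame {frame_shape} too small for kernel {ka}x{kl} "
            f"with search ({sa},{sl})")
    lc.rows, lc.cols = rows, cols
    return lc


def upsample_rf(frame: RFFrame, axial_factor: int, lateral_factor: int) -> RFFrame:
    """Densify an RF frame by integer factors with 2-D windowed-sinc
    interpolation; original samples are preserved at their nodes."""
    for f in (axial_factor, lateral_factor):
        if int(f) != f or f < 1:
            raise ValueError("up-sampling factors must be integers >= 1")
    out = upsample_axis(frame.samples, int(axial_factor), axis=0)
    out = upsample_axis(out, int(lateral_factor), axis=1)
    return RFFrame(out, frame.axial_fs * axial_factor,
                   frame.pitch / lateral_factor, frame.center_frequency,
                   frame.sos, frame.frame_index)


def _decimate_axis(a: np.ndarray, q: int, axis: int) -> np.ndarray:
    if q == 1:
        return a
    return signal.resample_poly(a, up=1, down=q, axis=axis, padtype="line")


def build_pyramid(frame: RFFrame, config: BMConfig) -> list[RFFrame]:
    """Anti-aliased decimation pyramid, coarse -> fine, per the configured
    per-level factors.  A level with factors (1, 1) equals the input."""
    levels = []
    for lv in range(config.n_levels):
        fa, fl = int(config.axial_decimation[lv]), int(config.lateral_decimation[lv])
        if fa < 1 or fl < 1:
            raise ValueError("decimation factors must be >= 1")
        s = _decimate_axis(frame.samples, fa, axis=0)
        s = _decimate_axis(s, fl, axis=1)
        levels.append(RFFrame(s, frame.axial_fs / fa, frame.pitch * fl,
                              frame.center_frequency, frame.sos, frame.frame_index))
    return levels


def compute_smi_stack(pre: RFFrame, post: RFFrame, lc: _LevelConfig,
                      frame_pair: tuple[int, int] = (0, 1)) -> SMIStack:
    """Zero-normalized cross-correlation surfaces for every block.

    values[i, j, a, l] is the NCC between the pre-frame kernel centered at
    (rows[i], cols[j]) and the equal-sized post-frame window displaced by lag
    (a + lag_offset[0], l + lag_offset[1]).  Zero-variance kernels or windows
    yield a correlation of 0 at that lag and flag the block.
    """
    ka, kl = lc.kernel
    sa, sl = lc.search
    rows, cols = lc.rows, lc.cols
    pre_s, post_s = pre.samples, post.samples
    wpre = sliding_window_view(pre_s, (ka, kl))
    wpost = sliding_window_view(post_s, (ka, kl))
    r0 = rows - ka // 2
    c0 = cols - kl // 2
    p = wpre[np.ix_(r0, c0)].reshape(rows.size, cols.size, -1)
    p0 = p - p.mean(axis=-1, keepdims=True)
    pnorm = np.sqrt((p0 ** 2).sum(axis=-1))
    flags = np.zeros((rows.size, cols.size), dtype=int)
    flags[pnorm <= 1e-12] |= FLAG_ZERO_VAR
    out = np.zeros((rows.size, cols.size, 2 * sa + 1, 2 * sl + 1))
    for a, da in enumerate(range(-sa, sa + 1)):
        for l, dl in enumerate(range(-sl, sl + 1)):
            q = wpost[np.ix_(r0 + da, c0 + dl)].reshape(rows.size, cols.size, -1)
            q0 = q - q.mean(axis=-1, keepdims=True)
            qnorm = np.sqrt((q0 ** 2).sum(axis=-1))
            denom = pnorm * qnorm
            ok = denom > 1e-12
            corr = np.zeros_like(denom)
            np.divide((p0 * q0).sum(axis=-1), denom, out=corr, where=ok)
            flags[~ok] |= FLAG_ZERO_VAR
            out[:, :, a, l] = corr
    np.clip(out, -1.0, 1.0, out=out)
    return SMIStack(out, (-sa, -sl), rows, cols, frame_pair, flags)


def compute_smi(pre: RFFrame, post: RFFrame, block_location: tuple[int, int],
                lc: _LevelConfig) -> SMI:
    """NCC surface for a single block (see :func:`compute_smi_stack`)."""
    one = _LevelConfig(kernel=lc.kernel, search=lc.search, step=lc.step,
                       rows=np.array([block_location[0]]),
                       cols=np.array([block_location[1]]))
    ka, kl = lc.kernel
    sa, sl = lc.search
    h, w = pre.shape
    r, c = block_location
    if (r - ka // 2 - sa < 0 or r + ka // 2 + sa >= h
            or c - kl // 2 - sl < 0 or c + kl // 2 + sl >= w):
        raise ValueError("kernel + search window must lie inside both frames")
    stack = compute_smi_stack(pre, post, one, (pre.frame_index, post.frame_index))
    return stack.smi(0, 0)


def compand_rf(post: RFFrame, disp: DisplacementField):
    """Align the post frame by the estimated displacement ("companding").

    The block-grid field is bilinearly interpolated to the sample grid and
    rounded to integer sample shifts; the post frame is gathered at the
    shifted indices (edge replication outside).  Integer gathers introduce no
    resampling error; the sub-sample remainder is left for the next matching
    pass.  Returns the aligned frame; the per-sample shifts are available via
    :func:`_compand_with_shifts`.
    """
    aligned, _, _ = _compand_with_shifts(post, disp)
    return aligned


def _compand_with_shifts(post: RFFrame, disp: DisplacementField):
    h, w = post.shape
    rr = np.arange(h)
    cc = np.arange(w)

    def interp(vals):
        f = RegularGridInterpolator((disp.rows, disp.cols), vals,
                                    bounds_error=False, fill_value=None)
        rg = np.clip(rr, disp.rows[0], disp.rows[-1])
        cg = np.clip(cc, disp.cols[0], disp.cols[-1])
        pts = np.stack(np.meshgrid(rg, cg, indexing="ij"), axis=-1)
        return f(pts)

    if disp.rows.size > 1 and disp.cols.size > 1:
        uz = interp(disp.axial)
        ux = interp(disp.lateral)
    else:  # degenerate single-row/col grid: constant extension
        uz = np.full((h, w), float(np.mean(disp.axial)))
        ux = np.full((h, w), float(np.mean(disp.lateral)))
    sz = np.rint(uz).astype(int)
    sx = np.rint(ux).astype(int)
    src_r = np.clip(rr[:, None] + sz, 0, h - 1)
    src_c = np.clip(cc[None, :] + sx, 0, w - 1)
    aligned = RFFrame(post.samples[src_r, src_c], post.axial_fs, post.pitch,
                      post.center_frequency, post.sos, post.frame_index)
    return aligned, sz, sx


def _peaks_from_surfaces(surfaces: np.ndarray, lag_offset, refine_step: float):
    nr, nc = surfaces.shape[:2]
    az = np.zeros((nr, nc))
    al = np.zeros((nr, nc))
    flags = np.zeros((nr, nc), dtype=int)
    for i in range(nr):
        for j in range(nc):
            a, l, f = subsample_peak(surfaces[i, j], lag_offset,
                                     refine_step=refine_step)
            az[i, j], al[i, j], flags[i, j] = a, l, f
    return az, al, flags


def estimate_displacement_multilevel(frames: Sequence[RFFrame], config: BMConfig,
                                     regularizer: str = "none",
                                     reg_params=None) -> DisplacementField:
    """Coarse-to-fine displacement estimation for one frame pair.

    ``frames`` holds 2 consecutive RF frames for ``regularizer`` in
    {"none", "ncc", "sbr"} or 4 consecutive frames for {"stbr1", "stbr2"}
    (four frames give the minimum set of three SMIs per block in time).  The
    estimated pair is always the middle pair; the outer frames only feed the
    temporal likelihoods.  Per level: up-sample -> pyramid -> SMIs ->
    optional Bayesian regularization -> sub-sample peaks -> compand.

    Returns the finest-level field in original samples / lines.
    """
    from . import bayes  # local import to avoid a cycle

    regularizer = {"ncc": "none"}.get(regularizer, regularizer)
    if regularizer not in ("none", "sbr", "stbr1", "stbr2"):
        raise ValueError(f"unknown regularizer {regularizer!r}")
    need = 4 if regularizer.startswith("stbr") else 2
    if len(frames) != need:
        raise ValueError(
            f"regularizer {regularizer!r} requires exactly {need} consecutive "
            f"frames (got {len(frames)}); spatiotemporal regularization needs "
            "four frames for a minimum set of three SMIs")
    if reg_params is None:
        reg_params = bayes.RegularizationParams()

    up_a, up_l = (int(u) for u in config.upsample)
    ups = [upsample_rf(f, up_a, up_l) for f in frames]
    pyramids = [build_pyramid(f, config) for f in ups]
    wavelength_up = ups[0].wavelength_samples  # samples per wavelength, upsampled grid

    pairs = [(i, i + 1) for i in range(len(frames) - 1)]
    mid = len(pairs) // 2
    acc = [None] * len(pairs)  # fields in upsampled units, on each level's block grid
    flags_mid = None

    for lv in range(config.n_levels):
        fa = int(config.axial_decimation[lv])
        fl = int(config.lateral_decimation[lv])
        shape = pyramids[0][lv].shape
        lam = wavelength_up / fa
        lc = resolve_level(shape, config, lv, lam)
        stacks = []
        base_shift = []
        for p, (i, j) in enumerate(pairs):
            post_lv = pyramids[j][lv]
            if acc[p] is None:
                aligned = post_lv
                sz = np.zeros(shape, dtype=int)
                sx = np.zeros(shape, dtype=int)
            else:
                lvl_field = DisplacementField(
                    axial=acc[p].axial / fa, lateral=acc[p].lateral / fl,
                    rows=acc[p].rows / fa, cols=acc[p].cols / fl,
                    dz_mm=post_lv.dz_mm, pitch_mm=post_lv.pitch,
                    frame_pair=(i, j), flags=acc[p].flags)
                aligned, sz, sx = _compand_with_shifts(post_lv, lvl_field)
            stacks.append(compute_smi_stack(pyramids[i][lv], aligned, lc, (i, j)))
            base_shift.append((sz[np.ix_(lc.rows, lc.cols)],
                               sx[np.ix_(lc.rows, lc.cols)]))

        # regularization -> peak surfaces per pair
        surfaces = [st.values for st in stacks]
        if regularizer != "none":
            spacing = lc.step
            pdfs = [bayes.smi_to_pdf(v) for v in surfaces]
            # companding references: each block's SMI lags are residuals
            # relative to its own integer shift
            refs = [bs for bs in base_shift]
            if regularizer == "sbr":
                surfaces = [bayes.sbr_posterior(pdfs[0], reg_params, spacing,
                                                lag_ref=refs[0])]
            else:
                # side pairs tracked with SBR (stage-1), middle with STBR
                side = [bayes.sbr_posterior(g, reg_params, spacing, lag_ref=r)
                        for g, r in zip(pdfs, refs)]
                if regularizer == "stbr1":
                    mid_post = bayes.stbr1_posterior(pdfs[0], pdfs[1], pdfs[2],
                                                     reg_params, spacing,
                                                     lag_refs=refs)
                else:
                    mid_post = bayes.stbr2_posterior(pdfs[0], pdfs[1], pdfs[2],
                                                     reg_params, spacing,
                                                     lag_refs=refs)
                surfaces = [side[0], mid_post, side[2]]

        new_acc = []
        for p in range(len(pairs)):
            res_a, res_l, fl_pk = _peaks_from_surfaces(
                surfaces[p], stacks[p].lag_offset, config.refine_step)
            fl_all = fl_pk | stacks[p].flags
            tot_a = (base_shift[p][0] + res_a) * fa  # back to upsampled units
            tot_l = (base_shift[p][1] + res_l) * fl
            new_acc.append(DisplacementField(
                axial=tot_a, lateral=tot_l,
                rows=lc.rows * fa, cols=lc.cols * fl,
                dz_mm=ups[0].dz_mm, pitch_mm=ups[0].pitch,
                frame_pair=pairs[p], flags=fl_all))
            if p == mid:
                flags_mid = fl_all
        acc = new_acc

    final = acc[mid]
    pair_global = (frames[pairs[mid][0]].frame_index,
                   frames[pairs[mid][1]].frame_index)
    return DisplacementField(
        axial=final.axial / up_a, lateral=final.lateral / up_l,
        rows=final.rows / up_a, cols=final.cols / up_l,
        dz_mm=frames[0].dz_mm, pitch_mm=frames[0].pitch,
        frame_pair=pair_global, flags=flags_mid)
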