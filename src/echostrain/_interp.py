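"""Windowed-sinc interpolation primitives.

Shared by the RF up-sampler and by sub-sample peak refinement on correlation
surfaces and posteriors.  The interpolator is a Hann-windowed sinc with a
half-width of 8 samples: a standard compromise between pass-band flatness and
kernel support that keeps interpolation exact at the sample nodes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

DEFAULT_HALF_WIDTH = 8

# bit flags attached to peak / block estimates
FLAG_OK = 0
FLAG_DEGENERATE = 1  # flat surface, no usable peak
FLAG_BOUNDARY = 2    # integer peak on the lag-grid boundary (search exhausted)
FLAG_ZERO_VAR = 4    # zero-variance kernel or window in the NCC
FLAG_FROZEN = 8      # tracked point left the displacement grid
FLAG_TEMPORAL_FALLBACK = 16  # temporal neighbor missing, fell back to SBR


def hann_sinc_kernel(factor: int, half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """FIR taps of a Hann-windowed sinc low-pass for integer up-sampling.

    Taps are spaced 1/factor apart and span ``half_width`` original samples on
    each side, so original samples are reproduced exactly (sinc zeros).
    """
    t = np.arange(-half_width * factor, half_width * factor + 1) / factor
    window = 0.5 * (1.0 + np.cos(np.pi * t / half_width))
    return np.sinc(t) * window


def upsample_axis(a: np.ndarray, factor: int, axis: int,
                  half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Densify ``a`` along ``axis`` by an integer factor with windowed sinc.

    Output length is ``(n - 1) * factor + 1`` so both end samples remain grid
    nodes; the original samples are preserved bit-exactly at their nodes.
    """
    if factor == 1:
        return np.array(a, dtype=float, copy=True)
    a = np.moveaxis(np.asarray(a, dtype=float), axis, 0)
    n = a.shape[0]
    stuffed = np.zeros(((n - 1) * factor + 1,) + a.shape[1:])
    stuffed[::factor] = a
    kernel = hann_sinc_kernel(factor, half_width)
    out = ndimage.convolve1d(stuffed, kernel, axis=0, mode="constant", cval=0.0)
    # nodes: convolution only sees original samples at integer offsets where
    # sinc vanishes except at zero, so restore them exactly against rounding
    out[::factor] = a
    return np.moveaxis(out, 0, axis)


def sinc_interp_weights(x: np.ndarray, n: int,
                        half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Row-stochastic-ish weight matrix evaluating samples ``0..n-1`` at ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    d = x[:, None] - np.arange(n)[None, :]
    w = np.sinc(d) * 0.5 * (1.0 + np.cos(np.pi * np.clip(d, -half_width, half_width) / half_width))
    w[np.abs(d) > half_width] = 0.0
    return w


def sinc_interp_2d(values: np.ndarray, xa: np.ndarray, xl: np.ndarray,
                   half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Evaluate the separable windowed-sinc interpolant of a 2-D surface on
    the tensor grid ``xa`` x ``xl`` (index coordinates)."""
    wa = sinc_interp_weights(xa, values.shape[0], half_width)
    wl = sinc_interp_weights(xl, values.shape[1], half_width)
    return wa @ values @ wl.T


def _tie_break(candidates: np.ndarray, lag_offset: tuple[int, int]) -> np.ndarray:
    """Among equal maxima pick the lowest-magnitude lag (Euclidean), then the
    smallest axial lag, then the smallest lateral lag."""
    lags = candidates + np.asarray(lag_offset)
    mag = (lags ** 2).sum(axis=1)
    order = np.lexsort((lags[:, 1], lags[:, 0], mag))
    return candidates[order[0]]


def integer_argmax(values: np.ndarray, lag_offset: tuple[int, int] = (0, 0)):
    """Argmax with the documented deterministic tie-break.

    Returns (index, lag) where index is into ``values`` and lag includes the
    offset of the lag grid.
    """
    vmax = values.max()
    cand = np.argwhere(values == vmax)
    idx = _tie_break(cand, lag_offset)
    lag = idx + np.asarray(lag_offset)
    return tuple(int(i) for i in idx), (int(lag[0]), int(lag[1]))


PEAK_HALF_WIDTH = 4


@lru_cache(maxsize=8192)
def _refine_weights(n: int, i0: int, half_width: int, n_steps: int,
                    refine_step: float):
    """Fine-grid positions and sinc weights around integer index ``i0``.

    The same (grid size, peak index) pairs recur for every block of a level,
    so the weight matrices are memoized."""
    offsets = np.arange(-n_steps, n_steps + 1) * refine_step
    x = np.clip(i0 + offsets, 0, n - 1)
    w = sinc_interp_weights(x, n, half_width)
    x.setflags(write=False)
    w.setflags(write=False)
    return x, w


def subsample_peak(values: np.ndarray, lag_offset: tuple[int, int] = (0, 0),
                   refine_step: float = 0.01, span: float = 1.0,
                   half_width: int = PEAK_HALF_WIDTH,
                   exact_peak_tol: float = 1e-9):
    """Sub-sample peak of a similarity surface or posterior.

    The integer argmax is refined by evaluating the 2-D windowed-sinc
    interpolant on a fine grid (spacing ``refine_step`` lags) within ``span``
    lags of the peak.  The refinement window half-width is 4 lags: on the
    small truncated surfaces a search region provides, a long sinc window is
    dominated by the asymmetric far tails of the correlation peak and biases
    the sub-sample estimate, while 4 taps track broad and narrow peaks alike.  A correlation value of exactly one means the windows
    are perfectly aligned, so refinement is skipped (it could only add
    interpolation noise).  Boundary maxima are returned unrefined and
    flagged; flat surfaces return lag (0, 0) with a degenerate flag.

    Returns ``(axial, lateral, flags)`` with the displacement corrected by
    ``lag_offset``.
    """
    values = np.asarray(values, dtype=float)
    na, nl = values.shape
    flat = int(values.argmax())
    vmax = values.flat[flat]
    if vmax - values.min() <= 1e-15 * max(1.0, abs(vmax)):
        return 0.0, 0.0, FLAG_DEGENERATE
    if np.count_nonzero(values == vmax) > 1:
        (ia, il), (la, ll) = integer_argmax(values, lag_offset)
    else:
        ia, il = divmod(flat, nl)
        la, ll = ia + lag_offset[0], il + lag_offset[1]
    if vmax >= 1.0 - exact_peak_tol:
        return float(la), float(ll), FLAG_OK
    if ia in (0, na - 1) or il in (0, nl - 1):
        return float(la), float(ll), FLAG_BOUNDARY
    n_steps = int(round(span / refine_step))
    xa, wa = _refine_weights(na, ia, half_width, n_steps, refine_step)
    xl, wl = _refine_weights(nl, il, half_width, n_steps, refine_step)
    surf = wa @ values @ wl.T
    flatf = int(surf.argmax())
    fmax = surf.flat[flatf]
    if np.count_nonzero(surf == fmax) > 1:
        cand = np.argwhere(surf == fmax)
        off = np.stack([xa[cand[:, 0]] - ia, xl[cand[:, 1]] - il], axis=1)
        best = off[np.lexsort((off[:, 1], off[:, 0],
                               (off ** 2).sum(axis=1)))[0]]
    else:
        ka, kl = divmod(flatf, xl.size)
        best = (xa[ka] - ia, xl[kl] - il)
    return float(la + best[0]), float(ll + best[1]), FLAG_OK
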