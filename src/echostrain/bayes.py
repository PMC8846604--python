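"""Bayesian regularization of NCC similarity surfaces.

Each SMI is turned into a discrete probability density over integer lags;
a posterior is then formed per block by multiplying the prior with likelihood
terms built from neighboring PDFs.  Three schemes are provided:

* ``sbr_posterior``   — spatial-only: the four adjacent blocks (left, right,
  top, bottom) contribute likelihoods.
* ``stbr1_posterior`` — spatial then temporal: one SBR pass on each of the
  past/present/future PDF grids, then a second pass where the past and future
  stage-1 posteriors act as temporal neighbors of the present.
* ``stbr2_posterior`` — simultaneous spatiotemporal: the unregularized present
  prior is multiplied by the four spatial likelihoods and the two temporal
  likelihoods in a single pass.

The likelihood a neighbor with PDF :math:`p` assigns to candidate lag ``u``
is ``max over v, |v - u| <= 3 sigma per axis, of p(v) * exp(-|v - u|^2_sigma / 2)``:
the most probable neighbor displacement compatible with ``u`` under a
zero-mean anisotropic Gaussian on the displacement difference.  The Gaussian
width ``sigma`` (in lags) is coupled to the maximum expected strain via the
inter-block spacing: two adjacent blocks a spacing ``s`` apart differ by at
most ``strain * s`` samples of displacement.

Inside the multi-level tracker, each block's SMI is computed after the post
frame was aligned ("companded") by that block's own integer shift, so lag
coordinates differ between blocks by the integer difference of their
companding references.  The optional ``lag_ref`` arguments carry those
references; likelihood surfaces are shifted by the (exact, integer)
reference difference before entering a neighbor's posterior, so the
smoothness prior always acts on total displacement, never on the companding
staircase.

Products are accumulated in the log domain and every posterior is
renormalized to sum to one.  Updates are synchronous: all likelihoods within
an iteration are computed from the pre-iteration grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._interp import subsample_peak

_TINY = 1e-300


@dataclass
class RegularizationParams:
    """Tunables of the Bayesian regularizers.

    ``sigma_eps`` — (axial, lateral) strain-regularization widths (unitless
    strain): the maximum inter-frame strain the spatial smoothness model
    expects.  ``sigma_t`` — (axial, lateral) temporal widths; with
    ``coupling_mode='strain'`` (default) they are converted to lag units with
    the same block-spacing rule as ``sigma_eps``, with ``'lag'`` they are
    lags directly.  ``np.inf`` widths give flat likelihoods.

    The optimal ``sigma_t`` scales inversely with how finely the cardiac
    cycle is sampled: densely sampled cycles (hundreds of frames) justify
    strong temporal continuity (0.01), coarsely sampled ones need a looser
    width (0.1, appropriate for a few tens of frames per cycle, which
    matches the default phantom).  See docs/methods.md.
    """
    sigma_eps: tuple[float, float] = (0.05, 0.05)
    sigma_t: tuple[float, float] = (0.1, 0.1)
    n_iterations: int = 1
    likelihood_floor: float = 1e-12
    coupling_mode: str = "strain"

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma_eps) or any(s <= 0 for s in self.sigma_t):
            raise ValueError("regularization widths must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.coupling_mode not in ("strain", "lag"):
            raise ValueError("coupling_mode must be 'strain' or 'lag'")


@dataclass
class NeighborhoodSpec:
    """Optional availability masks for the regularization neighborhood.

    Spatial masks are boolean arrays over the block grid (True = that
    directional neighbor participates); ``None`` means every in-grid neighbor
    is available.  ``past``/``future`` gate the temporal neighbors.
    """
    top: Optional[np.ndarray] = None
    bottom: Optional[np.ndarray] = None
    left: Optional[np.ndarray] = None
    right: Optional[np.ndarray] = None
    past: bool = True
    future: bool = True

    @classmethod
    def empty(cls, shape) -> "NeighborhoodSpec":
        z = np.zeros(shape, dtype=bool)
        return cls(top=z, bottom=z, left=z, right=z, past=False, future=False)


def smi_to_pdf(values: np.ndarray) -> np.ndarray:
    """Map SMI values in [-1, 1] to a PDF: add one, normalize by the sum.

    Works on a single surface or batched over leading block axes.  A surface
    that is -1 everywhere (zero normalizer) becomes uniform.
    """
    values = np.asarray(values, dtype=float)
    if values.min() < -1.0 - 1e-9 or values.max() > 1.0 + 1e-9:
        raise ValueError("SMI values must lie in [-1, 1]")
    shifted = np.clip(values, -1.0, 1.0) + 1.0
    total = shifted.sum(axis=(-2, -1), keepdims=True)
    n = values.shape[-2] * values.shape[-1]
    uniform = np.full_like(shifted, 1.0 / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        pdf = np.where(total > 0, shifted / np.where(total > 0, total, 1.0), uniform)
    return pdf


def couple_sigma(sigma_eps, block_spacing) -> np.ndarray:
    """Strain width -> displacement-lag width: sigma_u = sigma_eps * spacing.

    ``block_spacing`` is the inter-block spacing (samples, lines) along each
    axis; the product is the displacement difference two adjacent blocks show
    at the maximum expected strain.
    """
    sigma_eps = np.asarray(sigma_eps, dtype=float)
    spacing = np.asarray(block_spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("block spacing must be positive (degenerate grid)")
    if np.any(sigma_eps <= 0):
        raise ValueError("sigma_eps must be positive")
    return sigma_eps * spacing


def _sigma_lags(params: RegularizationParams, block_spacing, temporal: bool) -> np.ndarray:
    base = params.sigma_t if temporal else params.sigma_eps
    if temporal and params.coupling_mode == "lag":
        return np.asarray(base, dtype=float)
    return couple_sigma(base, block_spacing)


def neighbor_likelihood(neighbor_pdf: np.ndarray, sigma_lags,
                        floor: float = 1e-12) -> np.ndarray:
    """Likelihood surface a neighbor PDF assigns to each candidate lag.

    ``L(u) = max over v with |v_a - u_a| <= 3 sigma_a and |v_l - u_l| <= 3 sigma_l
    of pdf(v) * exp(-((v_a - u_a)^2 / (2 sigma_a^2) + (v_l - u_l)^2 / (2 sigma_l^2)))``.
    Values are floored at ``floor`` so downstream log-products never hit -inf.
    Accepts batched PDFs over leading axes.
    """
    return _likelihood(np.asarray(neighbor_pdf, dtype=float),
                       np.asarray(sigma_lags, dtype=float), floor)


def _likelihood(pdfs: np.ndarray, sigma: np.ndarray, floor: float) -> np.ndarray:
    sa, sl = float(sigma[0]), float(sigma[1])
    if sa <= 0 or sl <= 0:
        raise ValueError("sigma must be positive")
    na, nl = pdfs.shape[-2:]
    wa = na - 1 if np.isinf(sa) else min(int(np.floor(3.0 * sa)), na - 1)
    wl = nl - 1 if np.isinf(sl) else min(int(np.floor(3.0 * sl)), nl - 1)
    out = np.zeros_like(pdfs)
    for da in range(-wa, wa + 1):
        ga = 0.0 if np.isinf(sa) else da * da / (2.0 * sa * sa)
        for dl in range(-wl, wl + 1):
            gl = 0.0 if np.isinf(sl) else dl * dl / (2.0 * sl * sl)
            g = np.exp(-(ga + gl))
            # candidate v = u + (da, dl); valid u range so v stays in-grid
            ua = slice(max(0, -da), min(na, na - da))
            ul = slice(max(0, -dl), min(nl, nl - dl))
            va = slice(max(0, da), min(na, na + da))
            vl = slice(max(0, dl), min(nl, nl + dl))
            region = out[..., ua, ul]
            np.maximum(region, pdfs[..., va, vl] * g, out=region)
    np.maximum(out, floor, out=out)
    return out


def _normalize(logpost: np.ndarray) -> np.ndarray:
    m = logpost.max(axis=(-2, -1), keepdims=True)
    p = np.exp(logpost - m)
    return p / p.sum(axis=(-2, -1), keepdims=True)


def _shift_lag_grid(g: np.ndarray, da: int, dl: int, fill: float) -> np.ndarray:
    """out[..., a, l] = g[..., a + da, l + dl] with ``fill`` outside."""
    out = np.full_like(g, fill)
    na, nl = g.shape[-2:]
    if abs(da) >= na or abs(dl) >= nl:
        return out
    oa = slice(max(0, -da), min(na, na - da))
    ol = slice(max(0, -dl), min(nl, nl - dl))
    ia = slice(max(0, da), min(na, na + da))
    il = slice(max(0, dl), min(nl, nl + dl))
    out[..., oa, ol] = g[..., ia, il]
    return out


def _align_to_refs(logl: np.ndarray, delta_a: np.ndarray, delta_l: np.ndarray,
                   log_floor: float) -> np.ndarray:
    """Shift each block's log-likelihood surface by its integer lag-reference
    difference (batched over the leading block axes)."""
    if not delta_a.any() and not delta_l.any():
        return logl
    out = np.empty_like(logl)
    for ua in np.unique(delta_a):
        for ul in np.unique(delta_l):
            m = (delta_a == ua) & (delta_l == ul)
            if not m.any():
                continue
            out[m] = _shift_lag_grid(logl[m], int(ua), int(ul), log_floor)
    return out


_DIRECTIONS = {"top": (-1, 0), "bottom": (1, 0), "left": (0, -1), "right": (0, 1)}


def _spatial_log_likelihood(like: np.ndarray, spec: Optional[NeighborhoodSpec],
                            lag_ref, log_floor: float) -> np.ndarray:
    """Sum of log spatial-neighbor likelihoods over available directions.

    ``like[i, j]`` is the likelihood surface computed *from* block (i, j)'s
    PDF; the neighbor in direction d of block b contributes ``like[b + d]``,
    re-indexed into b's lag coordinates when companding references differ.
    """
    nba, nbl = like.shape[:2]
    acc = np.zeros_like(like)
    loglike = np.log(like)
    log_floor_v = np.log(log_floor) if log_floor > 0 else -745.0
    for name, (oa, ol) in _DIRECTIONS.items():
        src_a = slice(max(0, oa), nba + min(0, oa))
        dst_a = slice(max(0, -oa), nba + min(0, -oa))
        src_l = slice(max(0, ol), nbl + min(0, ol))
        dst_l = slice(max(0, -ol), nbl + min(0, -ol))
        avail = np.zeros((nba, nbl), dtype=bool)
        avail[dst_a, dst_l] = True
        mask = getattr(spec, name) if spec is not None else None
        if mask is not None:
            avail &= np.asarray(mask, dtype=bool)
        neigh = loglike[src_a, src_l]
        if lag_ref is not None:
            ra, rl = lag_ref
            delta_a = np.asarray(ra)[dst_a, dst_l] - np.asarray(ra)[src_a, src_l]
            delta_l = np.asarray(rl)[dst_a, dst_l] - np.asarray(rl)[src_a, src_l]
            neigh = _align_to_refs(neigh, delta_a, delta_l, log_floor_v)
        contrib = np.zeros_like(like)
        contrib[dst_a, dst_l] = neigh
        acc += np.where(avail[..., None, None], contrib, 0.0)
    return acc


def sbr_posterior(pdf_grid: np.ndarray, params: RegularizationParams,
                  block_spacing, spec: Optional[NeighborhoodSpec] = None,
                  n_iterations: Optional[int] = None,
                  lag_ref=None) -> np.ndarray:
    """Spatial Bayesian regularization of a (rows, cols, lags_a, lags_l) PDF grid.

    Per block: posterior ∝ prior × product of the four adjacent neighbors'
    likelihoods; blocks only use the neighbors they have.  With all
    neighborhoods empty the posterior equals the prior.  ``lag_ref`` is an
    optional pair of integer arrays giving each block's companding reference
    (see module docstring).
    """
    pdfs = np.asarray(pdf_grid, dtype=float)
    if pdfs.ndim != 4:
        raise ValueError("pdf_grid must be (rows, cols, lags_a, lags_l)")
    sigma = _sigma_lags(params, block_spacing, temporal=False)
    iters = params.n_iterations if n_iterations is None else n_iterations
    cur = pdfs
    for _ in range(iters):
        like = _likelihood(cur, sigma, params.likelihood_floor)
        logpost = (np.log(np.maximum(cur, _TINY))
                   + _spatial_log_likelihood(like, spec, lag_ref,
                                             params.likelihood_floor))
        cur = _normalize(logpost)
    return cur


def _temporal_log_terms(center: np.ndarray, past, future,
                        params: RegularizationParams, block_spacing,
                        spec: Optional[NeighborhoodSpec],
                        lag_refs=None) -> np.ndarray:
    """Summed log temporal likelihoods; missing neighbors contribute nothing.

    ``lag_refs`` is an optional (past, present, future) triple of per-grid
    companding references; each temporal likelihood is re-indexed into the
    present grid's lag coordinates.
    """
    sigma_t = _sigma_lags(params, block_spacing, temporal=True)
    log_floor_v = np.log(params.likelihood_floor)
    log_t = np.zeros_like(center)
    ref_p = lag_refs[1] if lag_refs is not None else None
    for grid, ref_o, avail in ((past, lag_refs[0] if lag_refs else None,
                                spec is None or spec.past),
                               (future, lag_refs[2] if lag_refs else None,
                                spec is None or spec.future)):
        if grid is None or not avail:
            continue
        logl = np.log(_likelihood(np.asarray(grid, dtype=float), sigma_t,
                                  params.likelihood_floor))
        if ref_p is not None and ref_o is not None:
            delta_a = np.asarray(ref_p[0]) - np.asarray(ref_o[0])
            delta_l = np.asarray(ref_p[1]) - np.asarray(ref_o[1])
            logl = _align_to_refs(logl, delta_a, delta_l, log_floor_v)
        log_t += logl
    return log_t


def stbr1_posterior(pdf_past, pdf_present, pdf_future,
                    params: RegularizationParams, block_spacing,
                    spec: Optional[NeighborhoodSpec] = None,
                    lag_refs=None) -> np.ndarray:
    """Spatial-then-temporal regularization (two-stage).

    Stage 1 runs one SBR iteration independently on each time's grid;
    stage 2 multiplies the present stage-1 posterior by temporal likelihoods
    built from the past and future stage-1 posteriors.  A missing temporal
    neighbor degrades gracefully to the stage-1 result.
    """
    refs = lag_refs if lag_refs is not None else (None, None, None)
    s_present = sbr_posterior(np.asarray(pdf_present, dtype=float), params,
                              block_spacing, spec, n_iterations=1,
                              lag_ref=refs[1])
    s_past = None if pdf_past is None else sbr_posterior(
        np.asarray(pdf_past, dtype=float), params, block_spacing, spec,
        n_iterations=1, lag_ref=refs[0])
    s_future = None if pdf_future is None else sbr_posterior(
        np.asarray(pdf_future, dtype=float), params, block_spacing, spec,
        n_iterations=1, lag_ref=refs[2])
    log_t = _temporal_log_terms(s_present, s_past, s_future, params,
                                block_spacing, spec, lag_refs)
    return _normalize(np.log(np.maximum(s_present, _TINY)) + log_t)


def stbr2_posterior(pdf_past, pdf_present, pdf_future,
                    params: RegularizationParams, block_spacing,
                    spec: Optional[NeighborhoodSpec] = None,
                    lag_refs=None) -> np.ndarray:
    """Simultaneous spatiotemporal regularization (single-stage).

    Per block: posterior ∝ unregularized prior × four spatial likelihoods
    (present grid, strain-coupled sigma) × two temporal likelihoods (past /
    future grids, sigma_t).  With no temporal neighbors this is exactly SBR.
    Additional iterations reuse the original past/future priors and the
    updated present grid (synchronous within each pass).
    """
    cur = np.asarray(pdf_present, dtype=float)
    sigma_s = _sigma_lags(params, block_spacing, temporal=False)
    ref_present = lag_refs[1] if lag_refs is not None else None
    for _ in range(params.n_iterations):
        like_s = _likelihood(cur, sigma_s, params.likelihood_floor)
        log_s = _spatial_log_likelihood(like_s, spec, ref_present,
                                        params.likelihood_floor)
        log_t = _temporal_log_terms(cur, pdf_past, pdf_future, params,
                                    block_spacing, spec, lag_refs)
        cur = _normalize(np.log(np.maximum(cur, _TINY)) + log_s + log_t)
    return cur


def map_displacement(posterior: np.ndarray, lag_offset=(0, 0),
                     refine_step: float = 0.01):
    """MAP displacement of a posterior surface with sub-sample precision.

    Delegates to the same windowed-sinc peak refinement used for raw SMIs.
    Returns ``(axial, lateral, flags)``.
    """
    return subsample_peak(np.asarray(posterior, dtype=float), lag_offset,
                          refine_step=refine_step)
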