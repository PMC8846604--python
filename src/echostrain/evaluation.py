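"""Strain-estimation accuracy and precision statistics.

Accuracy against a known truth: strain bias (mean signed error), normalized
strain error (sum of absolute errors over sum of absolute truth) and the
total temporal relative error (TTR, the same ratio along a segmental strain
curve).  Precision without a truth: the elastographic signal-to-noise ratio
SNR_e = mu / sigma of strain in a local mesh window, summarized as a strain
filter — the conditional expectation E(SNR_e | strain) over binned
(strain, SNR_e) pairs.

All strain inputs are unitless fractions; percentages are returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _masked(true_map, est_map, mask):
    t = np.asarray(true_map, dtype=float).ravel()
    e = np.asarray(est_map, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError("true and estimated maps must be aligned")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        t, e = t[m], e[m]
    if t.size == 0:
        raise ValueError("empty mask")
    return t, e


def strain_bias(true_map, est_map, mask=None) -> float:
    """Mean signed strain error E[true - est], in percent strain."""
    t, e = _masked(true_map, est_map, mask)
    return float(np.mean(t - e) * 100.0)


def normalized_error(true_map, est_map, mask=None) -> float:
    """Normalized strain error: sum|true - est| / sum|true| x 100 (%)."""
    t, e = _masked(true_map, est_map, mask)
    denom = np.abs(t).sum()
    if denom == 0:
        raise ValueError("normalized error undefined for an all-zero true map")
    return float(np.abs(t - e).sum() / denom * 100.0)


def ttr(true_curve, est_curve) -> float:
    """Total temporal relative error between strain-vs-time curves (%)."""
    t = np.asarray(true_curve, dtype=float).ravel()
    e = np.asarray(est_curve, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError("curves must have equal length")
    denom = np.abs(t).sum()
    if denom == 0:
        raise ValueError("TTR undefined for an all-zero true curve")
    return float(np.abs(t - e).sum() / denom * 100.0)


def snr_e_map(strain_lattice, window=(5, 9), sigma_floor: float = 1e-12,
              ddof: int = 1):
    """Elastographic SNR per mesh point: mu / sigma of strain in a
    (transmural x arc) window centered at each lattice point.

    The lattice is edge-padded so the window can be centered everywhere.
    Points whose window standard deviation falls below ``sigma_floor`` are
    excluded (NaN) and flagged.  Returns ``(snr, flags)``.
    """
    a = np.asarray(strain_lattice, dtype=float)
    wa, wl = int(window[0]), int(window[1])
    if wa % 2 == 0 or wl % 2 == 0:
        raise ValueError("window dimensions must be odd")
    if wa > a.shape[0] + wa - 1 or wl > a.shape[1] + wl - 1:
        raise ValueError("window larger than mesh lattice")
    pad = np.pad(a, ((wa // 2, wa // 2), (wl // 2, wl // 2)), mode="edge")
    win = sliding_window_view(pad, (wa, wl)).reshape(a.shape + (-1,))
    mu = win.mean(axis=-1)
    sd = win.std(axis=-1, ddof=ddof)
    flags = sd <= sigma_floor
    snr = np.where(flags, np.nan, mu / np.where(flags, 1.0, sd))
    return snr, flags


@dataclass
class StrainFilter:
    """Strain filter: binned (strain, SNR_e) statistics.

    ``joint_hist`` is f(SNR_e, strain) counts (snr bins x strain bins);
    ``conditional`` columns sum to one over occupied strain bins;
    ``expected_snr`` is E(SNR_e | strain) per strain bin (NaN where empty).
    """
    strain_edges: np.ndarray
    snr_edges: np.ndarray
    joint_hist: np.ndarray
    strain_hist: np.ndarray
    conditional: np.ndarray
    expected_snr: np.ndarray

    @property
    def strain_centers(self):
        return 0.5 * (self.strain_edges[:-1] + self.strain_edges[1:])

    @property
    def snr_centers(self):
        return 0.5 * (self.snr_edges[:-1] + self.snr_edges[1:])


def strain_filter(strains, snrs, strain_bins=50, snr_bins=60,
                  snr_range=(0.0, 30.0),
                  strain_range: Optional[tuple] = None) -> StrainFilter:
    """Build the strain filter from (strain, SNR_e) pairs.

    The joint 2-D histogram is normalized per strain bin by the strain
    marginal, giving the conditional PDF f(SNR_e | strain); the expected SNR_e
    per strain bin is the bin-center average under that conditional.
    Non-finite pairs are dropped; pairs outside the SNR range are ignored.
    """
    s = np.asarray(strains, dtype=float).ravel()
    q = np.asarray(snrs, dtype=float).ravel()
    ok = np.isfinite(s) & np.isfinite(q)
    s, q = s[ok], q[ok]
    if s.size == 0:
        raise ValueError("no finite (strain, SNR_e) pairs")
    if strain_range is None:
        lo, hi = float(s.min()), float(s.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        strain_range = (lo, hi)
    if np.isscalar(strain_bins):
        strain_edges = np.linspace(strain_range[0], strain_range[1],
                                   int(strain_bins) + 1)
    else:
        strain_edges = np.asarray(strain_bins, dtype=float)
    if np.isscalar(snr_bins):
        snr_edges = np.linspace(snr_range[0], snr_range[1], int(snr_bins) + 1)
    else:
        snr_edges = np.asarray(snr_bins, dtype=float)
    if len(strain_edges) < 2 or len(snr_edges) < 2 or \
            np.any(np.diff(strain_edges) <= 0) or np.any(np.diff(snr_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    joint, _, _ = np.histogram2d(q, s, bins=(snr_edges, strain_edges))
    marginal = joint.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conditional = np.where(marginal > 0, joint / np.where(marginal > 0, marginal, 1.0),
                               np.nan)
    centers = 0.5 * (snr_edges[:-1] + snr_edges[1:])
    expected = np.where(marginal > 0,
                        np.nansum(conditional * centers[:, None], axis=0), np.nan)
    return StrainFilter(strain_edges, snr_edges, joint, marginal, conditional,
                        expected)
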