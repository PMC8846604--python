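"""Lagrangian myocardial strain from accumulated block-matching displacements.

A material mesh is seeded between the endocardial and epicardial contours at
end-diastole (the Lagrangian reference).  Inter-frame displacement fields are
median filtered, interpolated to the tracked point positions and integrated
over time; the Lagrangian strain tensor is then obtained per point by an
ordinary-least-squares fit of the accumulated displacement as an affine
function of the end-diastolic position, and rotated into wall coordinates to
give radial and longitudinal strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from ._interp import FLAG_DEGENERATE, FLAG_FROZEN, FLAG_OK  # noqa: F401 (re-exported flags)
from .blockmatch import DisplacementField


@dataclass
class CardiacMesh:
    """Tracked material points with wall-direction frames and segment labels.

    ``points`` are end-diastolic positions (N, 2) in mm (z, x); ``radial`` and
    ``longitudinal`` are per-point orthonormal unit vectors (transmural and
    along-wall); ``segment_labels`` partition the wall into six contiguous
    segments 1..6 (base -> apex -> base); ``lattice_shape`` is
    (n_transmural, n_arc) with points stored transmural-major.
    """
    points: np.ndarray
    radial: np.ndarray
    longitudinal: np.ndarray
    segment_labels: np.ndarray
    lattice_shape: tuple[int, int]
    trajectories: Optional[np.ndarray] = None  # (n_frames, N, 2) mm
    frozen: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.frozen is None:
            self.frozen = np.zeros(len(self.points), dtype=bool)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_lattice(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-point array to the (transmural, arc) lattice."""
        return np.asarray(values).reshape(self.lattice_shape)


@dataclass
class StrainRecord:
    """Lagrangian strain at one frame: 2x2 symmetric tensors per point plus
    derived radial/longitudinal strain (unitless fractions)."""
    frame_index: int
    E: np.ndarray
    e_r: Optional[np.ndarray] = None
    e_l: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(len(self.E), dtype=int)


def _resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    c = np.asarray(contour, dtype=float)
    seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("contour has zero length")
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.interp(t, s, c[:, k])
    return out


def _contours_cross(a: np.ndarray, b: np.ndarray) -> bool:
    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def seg_intersect(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)
    for i in range(len(a) - 1):
        for j in range(len(b) - 1):
            if seg_intersect(a[i], a[i + 1], b[j], b[j + 1]):
                return True
    return False


def _choose_arc_count(n_points: int) -> int:
    """Multiple of six that divides n_points, nearest to sqrt(2 n_points)."""
    target = np.sqrt(2.0 * n_points)
    cands = [k for k in range(6, n_points + 1, 6) if n_points % k == 0]
    if not cands:
        raise ValueError("n_points must be divisible by some multiple of 6 "
                         "(six equal arc segments)")
    return min(cands, key=lambda k: abs(k - target))


def build_mesh(endo_contour, epi_contour, n_points: int) -> CardiacMesh:
    """Seed a transmural x arc-length lattice between two wall contours.

    Radial unit vectors point endo -> epi (transmural), longitudinal vectors
    are the in-plane perpendicular oriented along the wall tangent; the arc is
    split into six equal segments labeled 1..6.
    """
    endo = np.atleast_2d(np.asarray(endo_contour, dtype=float))
    epi = np.atleast_2d(np.asarray(epi_contour, dtype=float))
    if len(endo) < 2 or len(epi) < 2:
        raise ValueError("contours need at least two points")
    if _contours_cross(endo, epi):
        raise ValueError("endocardial and epicardial contours intersect")
    n_arc = _choose_arc_count(n_points)
    n_trans = n_points // n_arc
    e = _resample_contour(endo, n_arc)
    p = _resample_contour(epi, n_arc)
    trans = p - e
    norms = np.linalg.norm(trans, axis=1)
    if np.any(norms <= 1e-12):
        raise ValueError("contours touch: zero wall thickness")
    radial_arc = trans / norms[:, None]
    mid = 0.5 * (e + p)
    tangent = np.gradient(mid, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1), 1e-12)[:, None]
    # exact orthogonality: longitudinal is radial rotated 90 deg, sign from tangent
    perp = np.stack([-radial_arc[:, 1], radial_arc[:, 0]], axis=1)
    sign = np.where(np.einsum("ij,ij->i", perp, tangent) < 0, -1.0, 1.0)
    longit_arc = perp * sign[:, None]
    fracs = (np.arange(n_trans) + 0.5) / n_trans
    points = (e[None, :, :] + fracs[:, None, None] * trans[None, :, :]).reshape(-1, 2)
    radial = np.tile(radial_arc, (n_trans, 1))
    longit = np.tile(longit_arc, (n_trans, 1))
    seg_of_arc = np.arange(n_arc) * 6 // n_arc + 1
    labels = np.tile(seg_of_arc, n_trans)
    return CardiacMesh(points, radial, longit, labels, (n_trans, n_arc))


def median_filter_field(fieldv: DisplacementField, kernel=(5, 5)) -> DisplacementField:
    """Component-wise 2-D median filter (edge replication) over the block grid;
    removes isolated false-peak outliers before Lagrangian accumulation."""
    ka, kl = int(kernel[0]), int(kernel[1])
    if ka % 2 == 0 or kl % 2 == 0:
        raise ValueError("median filter kernel dimensions must be odd")
    ax = ndimage.median_filter(fieldv.axial, size=(ka, kl), mode="nearest")
    la = ndimage.median_filter(fieldv.lateral, size=(ka, kl), mode="nearest")
    return DisplacementField(ax, la, fieldv.rows, fieldv.cols, fieldv.dz_mm,
                             fieldv.pitch_mm, fieldv.frame_pair,
                             fieldv.flags.copy())


def _field_interpolators(fieldv: DisplacementField):
    rows_mm = fieldv.rows_mm
    cols_mm = fieldv.cols_mm
    fz = RegularGridInterpolator((rows_mm, cols_mm), fieldv.axial_mm,
                                 bounds_error=False, fill_value=None)
    fx = RegularGridInterpolator((rows_mm, cols_mm), fieldv.lateral_mm,
                                 bounds_error=False, fill_value=None)
    bbox = (rows_mm[0], rows_mm[-1], cols_mm[0], cols_mm[-1])
    return fz, fx, bbox


def accumulate_lagrangian(mesh: CardiacMesh,
                          fields: Sequence[DisplacementField]) -> CardiacMesh:
    """Integrate inter-frame displacements along tracked material points
    starting at end-diastole: x(t+1) = x(t) + u_t(x(t)), with u_t bilinearly
    interpolated from the block grid.  Points leaving the grid are frozen at
    their last position and flagged."""
    n = mesh.n_points
    traj = np.empty((len(fields) + 1, n, 2))
    traj[0] = mesh.points
    frozen = np.zeros(n, dtype=bool)
    cur = mesh.points.copy()
    for t, f in enumerate(fields):
        fz, fx, bbox = _field_interpolators(f)
        inside = ((cur[:, 0] >= bbox[0]) & (cur[:, 0] <= bbox[1])
                  & (cur[:, 1] >= bbox[2]) & (cur[:, 1] <= bbox[3]))
        frozen |= ~inside
        step = np.zeros_like(cur)
        active = ~frozen
        if active.any():
            step[active, 0] = fz(cur[active])
            step[active, 1] = fx(cur[active])
        cur = cur + step
        traj[t + 1] = cur
    return CardiacMesh(mesh.points, mesh.radial, mesh.longitudinal,
                       mesh.segment_labels, mesh.lattice_shape,
                       trajectories=traj, frozen=frozen)


def ls_strain_tensor(mesh: CardiacMesh, frame_index: int,
                     kernel_mm=(0.5, 1.0), min_neighbors: int = 6,
                     finite: bool = False) -> StrainRecord:
    """Least-squares Lagrangian strain tensor at one frame.

    Per point, the accumulated displacement components of the neighbors inside
    an axial x lateral box (``kernel_mm``) are fit as affine functions of the
    end-diastolic position; E is the symmetric part of the fitted displacement
    gradient (infinitesimal strain; ``finite=True`` adds the quadratic
    Green-Lagrange term).  Points with fewer than ``min_neighbors`` usable
    neighbors, or rank-deficient neighborhoods, are flagged.
    """
    if mesh.trajectories is None:
        raise ValueError("mesh has no trajectories; run accumulate_lagrangian first")
    pts = mesh.points
    disp = mesh.trajectories[frame_index] - pts
    half = np.array([kernel_mm[0] / 2.0, kernel_mm[1] / 2.0])
    tree = cKDTree(pts / half)
    usable = ~mesh.frozen
    n = mesh.n_points
    E = np.zeros((n, 2, 2))
    flags = np.zeros(n, dtype=int)
    neighbor_lists = tree.query_ball_point(pts / half, r=1.0 + 1e-9, p=np.inf)
    for i in range(n):
        idx = np.asarray([j for j in neighbor_lists[i] if usable[j]])
        if idx.size < min_neighbors:
            flags[i] |= FLAG_DEGENERATE
            continue
        X = np.column_stack([np.ones(idx.size),
                             pts[idx, 0] - pts[i, 0],
                             pts[idx, 1] - pts[i, 1]])
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < 3:
            flags[i] |= FLAG_DEGENERATE
            continue
        coef = np.linalg.solve(XtX, X.T @ disp[idx])
        G = coef[1:, :].T  # G[a, b] = d u_a / d x_b
        Ei = 0.5 * (G + G.T)
        if finite:
            Ei = Ei + 0.5 * (G.T @ G)
        E[i] = Ei
    flags[mesh.frozen] |= FLAG_FROZEN
    return StrainRecord(frame_index, E, flags=flags)


def transform_strain(record: StrainRecord, mesh: CardiacMesh) -> StrainRecord:
    """Rotate the strain tensor into wall coordinates: e_r = r^T E r,
    e_l = l^T E l, with per-point unit radial / longitudinal directions."""
    for v in (mesh.radial, mesh.longitudinal):
        if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-9):
            raise ValueError("wall direction frames must be unit vectors")
    record.e_r = np.einsum("ni,nij,nj->n", mesh.radial, record.E, mesh.radial)
    record.e_l = np.einsum("ni,nij,nj->n", mesh.longitudinal, record.E,
                           mesh.longitudinal)
    return record


def segment_strain_curves(records: Sequence[StrainRecord],
                          mesh: CardiacMesh) -> pd.DataFrame:
    """Mean radial/longitudinal strain per segment per frame (non-flagged
    points only).  Accumulation starts at end-diastole, so frame-0 curves are
    identically zero."""
    rows = []
    for rec in records:
        if rec.e_r is None:
            raise ValueError("records must be transformed to wall coordinates first")
        good = rec.flags == FLAG_OK
        for s in np.unique(mesh.segment_labels):
            m = good & (mesh.segment_labels == s)
            if not m.any():
                rows.append({"frame": rec.frame_index, "segment": int(s),
                             "e_r": np.nan, "e_l": np.nan, "flagged": True})
                continue
            rows.append({"frame": rec.frame_index, "segment": int(s),
                         "e_r": float(rec.e_r[m].mean()),
                         "e_l": float(rec.e_l[m].mean()), "flagged": False})
    return pd.DataFrame(rows)
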