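"""Synthetic RF phantom with known ground-truth motion and strain.

The generator emulates the statistical structure of simulated cardiac RF
data: fully developed speckle from randomly placed point scatterers, imaged
by a separable band-limited point-spread function (Gaussian-enveloped cosine
axially — the round-trip carrier — and Gaussian laterally), deformed frame to
frame by a prescribed analytic motion model, with additive white Gaussian
noise calibrated to a requested sonographic SNR relative to a reference ROI.

Coordinates are (axial z, lateral x) in mm; axis 0 of an RF frame is depth.
All randomness flows from explicit seeds; outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .blockmatch import RFFrame

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- types

@dataclass
class ScattererField:
    """Point scatterers: positions (N, 2) in mm (z, x), unit-variance normal
    amplitudes, and the bounding region (z0, z1, x0, x1) in mm."""
    positions: np.ndarray
    amplitudes: np.ndarray
    region: tuple[float, float, float, float]

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("scatterer amplitudes must be finite")


@dataclass
class ImagingConfig:
    """Linear-array imaging geometry and PSF model.

    ``center_frequency`` / ``sampling_frequency`` in MHz, ``pitch`` in mm,
    ``speed_of_sound`` in m/s, ``psf_bandwidth`` fractional (-6 dB two-sided),
    ``lateral_sigma`` in mm, ``depth`` in mm, ``lines`` A-lines.
    """
    center_frequency: float = 8.0
    sampling_frequency: float = 78.84
    pitch: float = 0.2
    speed_of_sound: float = 1540.0
    psf_bandwidth: float = 0.5
    lateral_sigma: float = 0.15
    lines: int = 60
    depth: float = 12.0

    def __post_init__(self):
        vals = (self.center_frequency, self.sampling_frequency, self.pitch,
                self.speed_of_sound, self.psf_bandwidth, self.lateral_sigma,
                self.lines, self.depth)
        if any(v <= 0 for v in vals):
            raise ValueError("imaging configuration values must be positive")
        if self.sampling_frequency <= 2.0 * self.center_frequency:
            raise ValueError("sampling frequency must exceed twice the center frequency")

    @property
    def dz(self) -> float:
        """Axial sample spacing in mm."""
        return (self.speed_of_sound * 1e-3) / (2.0 * self.sampling_frequency)

    @property
    def n_samples(self) -> int:
        return int(round(self.depth / self.dz)) + 1

    @property
    def axial_sigma(self) -> float:
        """Gaussian envelope sigma of the axial PSF, in mm of depth."""
        sigma_f = self.psf_bandwidth * self.center_frequency / 2.355  # FWHM -> sigma, MHz
        sigma_t = 1.0 / (2.0 * math.pi * sigma_f)                     # microseconds
        return (self.speed_of_sound * 1e-3) * sigma_t / 2.0

    @property
    def carrier_cycles_per_mm(self) -> float:
        """Round-trip carrier spatial frequency 2 f0 / c."""
        return 2.0 * self.center_frequency / (self.speed_of_sound * 1e-3)

    @property
    def resolution_cell_mm2(self) -> float:
        """FWHM ellipse area of the PSF envelope."""
        return math.pi * (1.1774 * self.axial_sigma) * (1.1774 * self.lateral_sigma)

    def region(self) -> tuple[float, float, float, float]:
        return (0.0, self.depth, 0.0, (self.lines - 1) * self.pitch)


@dataclass
class MotionModel:
    """Prescribed analytic motion: cumulative displacement from the reference
    (frame 0) configuration.

    Kinds: ``rigid_shift`` (constant per-frame shift), ``uniform_strain``
    (linear strain ramp about a center), ``cyclic_wall`` (annular wall that
    thickens radially and shortens along its arc with a half-sine time course,
    returning to identity at cycle end).
    """
    kind: str
    parameters: dict
    frame_rate: float = 100.0

    @classmethod
    def rigid_shift(cls, shift_mm: tuple[float, float], frame_rate: float = 100.0):
        return cls("rigid_shift", {"shift": tuple(float(s) for s in shift_mm)},
                   frame_rate)

    @classmethod
    def uniform_strain(cls, strain_per_frame: tuple[float, float],
                       center: tuple[float, float], frame_rate: float = 100.0):
        """Diagonal (axial, lateral) strain increment per frame about ``center``."""
        return cls("uniform_strain", {"strain": tuple(float(s) for s in strain_per_frame),
                                      "center": tuple(float(c) for c in center)},
                   frame_rate)

    @classmethod
    def cyclic_wall(cls, center: tuple[float, float], r_endo: float, r_epi: float,
                    theta_span: tuple[float, float] = (-0.9, 0.9),
                    peak_radial_strain: float = 0.15,
                    peak_longitudinal_strain: float = -0.10,
                    cycle_frames: int = 12, frame_rate: float = 100.0):
        """Annular wall section (angles in radians around the upward, -z,
        direction from ``center``); strains follow sin(pi f / T)."""
        if r_epi <= r_endo:
            raise ValueError("epicardial radius must exceed endocardial radius")
        return cls("cyclic_wall", {
            "center": tuple(float(c) for c in center),
            "r_endo": float(r_endo), "r_epi": float(r_epi),
            "theta_span": tuple(float(t) for t in theta_span),
            "peak_radial_strain": float(peak_radial_strain),
            "peak_longitudinal_strain": float(peak_longitudinal_strain),
            "cycle_frames": int(cycle_frames)}, frame_rate)

    # -- kinematics ---------------------------------------------------------

    def cumulative_displacement(self, positions: np.ndarray, frame_index: int) -> np.ndarray:
        """Displacement (mm) of material points from their frame-0 positions."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        f = float(frame_index)
        if self.kind == "rigid_shift":
            return np.broadcast_to(np.asarray(self.parameters["shift"]) * f,
                                   pos.shape).copy()
        if self.kind == "uniform_strain":
            ez, ex = self.parameters["strain"]
            cz, cx = self.parameters["center"]
            out = np.empty_like(pos)
            out[:, 0] = (pos[:, 0] - cz) * ez * f
            out[:, 1] = (pos[:, 1] - cx) * ex * f
            return out
        if self.kind == "cyclic_wall":
            p = self.parameters
            t = math.sin(math.pi * f / p["cycle_frames"])
            er = p["peak_radial_strain"] * t
            el = p["peak_longitudinal_strain"] * t
            cz, cx = p["center"]
            rm = 0.5 * (p["r_endo"] + p["r_epi"])
            thc = 0.5 * (p["theta_span"][0] + p["theta_span"][1])
            dz = pos[:, 0] - cz
            dx = pos[:, 1] - cx
            r = np.hypot(dz, dx)
            # angle about the upward (-z) direction, positive toward +x
            th = np.arctan2(dx, -dz)
            r2 = rm + (r - rm) * (1.0 + er)
            th2 = thc + (th - thc) * (1.0 + el)
            z2 = cz - r2 * np.cos(th2)
            x2 = cx + r2 * np.sin(th2)
            return np.stack([z2 - pos[:, 0], x2 - pos[:, 1]], axis=1)
        raise ValueError(f"unknown motion kind {self.kind!r}")

    def interframe_displacement(self, positions: np.ndarray, frame_index: int,
                                n_iter: int = 25) -> np.ndarray:
        """Eulerian inter-frame displacement at spatial positions occupied at
        ``frame_index``: solves for the material point there by fixed-point
        iteration, then differences consecutive cumulative displacements."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        ref = pos.copy()
        for _ in range(n_iter):
            ref = pos - self.cumulative_displacement(ref, frame_index)
        return (self.cumulative_displacement(ref, frame_index + 1)
                - self.cumulative_displacement(ref, frame_index))

    def strain_tensor(self, positions: np.ndarray, frame_index: int,
                      h: float = 5e-3) -> np.ndarray:
        """Infinitesimal strain E = sym(grad u) of the cumulative displacement
        at material (frame-0) positions, by central differences (h in mm)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        grads = np.empty((pos.shape[0], 2, 2))
        for axis in range(2):
            dp = np.zeros_like(pos)
            dp[:, axis] = h
            up = self.cumulative_displacement(pos + dp, frame_index)
            dn = self.cumulative_displacement(pos - dp, frame_index)
            grads[:, :, axis] = (up - dn) / (2.0 * h)
        return 0.5 * (grads + np.swapaxes(grads, 1, 2))

    def wall_contours(self, n_points: int = 80):
        """Endocardial and epicardial polylines of a cyclic wall (mm)."""
        if self.kind != "cyclic_wall":
            raise ValueError("wall contours are defined for cyclic_wall motion only")
        p = self.parameters
        cz, cx = p["center"]
        th = np.linspace(p["theta_span"][0], p["theta_span"][1], n_points)
        endo = np.stack([cz - p["r_endo"] * np.cos(th), cx + p["r_endo"] * np.sin(th)], axis=1)
        epi = np.stack([cz - p["r_epi"] * np.cos(th), cx + p["r_epi"] * np.sin(th)], axis=1)
        return endo, epi


@dataclass
class GroundTruth:
    """Ground-truth kinematics of a generated sequence.

    Displacement mappings, strain tensors and wall-direction strains are all
    derived from the scene's motion model; strain is the symmetric spatial
    gradient of the accumulated displacement (evaluated numerically), so the
    two are consistent by construction.
    """
    motion: MotionModel
    n_frames: int
    imaging: ImagingConfig

    def displacement(self, positions, frame_index):
        return self.motion.cumulative_displacement(positions, frame_index)

    def interframe_displacement(self, positions, frame_index):
        return self.motion.interframe_displacement(positions, frame_index)

    def strain_tensor(self, positions, frame_index):
        return self.motion.strain_tensor(positions, frame_index)

    def wall_strains(self, mesh, frame_index):
        """(e_r, e_l) at the mesh's material points for one frame."""
        E = self.strain_tensor(mesh.points, frame_index)
        e_r = np.einsum("ni,nij,nj->n", mesh.radial, E, mesh.radial)
        e_l = np.einsum("ni,nij,nj->n", mesh.longitudinal, E, mesh.longitudinal)
        return e_r, e_l

    def segment_curves(self, mesh):
        """Per-segment mean (e_r, e_l) versus frame as a DataFrame."""
        import pandas as pd
        rows = []
        for f in range(self.n_frames):
            e_r, e_l = self.wall_strains(mesh, f)
            for s in np.unique(mesh.segment_labels):
                m = mesh.segment_labels == s
                rows.append({"frame": f, "segment": int(s),
                             "e_r": float(e_r[m].mean()), "e_l": float(e_l[m].mean())})
        return pd.DataFrame(rows)


@dataclass
class RFSequence:
    frames: list
    imaging: ImagingConfig

    def __len__(self):
        return len(self.frames)


@dataclass
class SceneConfig:
    """Everything needed to generate one RF sequence.

    ``snr_db`` is a single sonographic SNR, or an (upper, lower) pair applied
    to the upper/lower halves of the frame to mimic the anterior/posterior
    attenuation split; ``None`` / inf means noiseless.  ``noise_roi`` is the
    (z0, z1, x0, x1) reference ROI in samples/lines; by default a patch in the
    upper (anterior) half.
    """
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    motion: MotionModel = field(default_factory=lambda: MotionModel.rigid_shift((0.0, 0.0)))
    n_frames: int = 6
    scatterer_density: float = 220.0
    snr_db: object = None
    noise_roi: Optional[tuple[int, int, int, int]] = None
    seed: int = 0


# --------------------------------------------------------------------------- ops

def generate_scatterers(region, density_per_mm2: float, seed: int) -> ScattererField:
    """Uniformly scattered points with N(0, 1) reflectivities.

    The count is Poisson with mean density x area.  For fully developed
    speckle the density should put at least ~10 scatterers in a PSF
    resolution cell (``ImagingConfig.resolution_cell_mm2``); the default
    scene density satisfies this.
    """
    z0, z1, x0, x1 = (float(v) for v in region)
    area = (z1 - z0) * (x1 - x0)
    if density_per_mm2 <= 0:
        raise ValueError("scatterer density must be positive")
    if area <= 0:
        raise ValueError("degenerate scatterer region")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density_per_mm2 * area))
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(z0, z1, n)
    pos[:, 1] = rng.uniform(x0, x1, n)
    amp = rng.standard_normal(n)
    return ScattererField(pos, amp, (z0, z1, x0, x1))


def deform_scatterers(fieldv: ScattererField, motion: MotionModel, frame_index: int,
                      guard_mm: float = 1.0) -> ScattererField:
    """Map scatterers by the motion model's cumulative displacement at
    ``frame_index``; amplitudes are unchanged.  Scatterers landing outside the
    region extended by ``guard_mm`` are dropped (count logged)."""
    disp = motion.cumulative_displacement(fieldv.positions, frame_index)
    pos = fieldv.positions + disp
    z0, z1, x0, x1 = fieldv.region
    keep = ((pos[:, 0] >= z0 - guard_mm) & (pos[:, 0] <= z1 + guard_mm)
            & (pos[:, 1] >= x0 - guard_mm) & (pos[:, 1] <= x1 + guard_mm))
    dropped = int((~keep).sum())
    if dropped:
        log.info("deform_scatterers: dropped %d scatterers outside guard region", dropped)
    return ScattererField(pos[keep], fieldv.amplitudes[keep], fieldv.region)


@njit(cache=False)
def _accumulate_rf(out, zs, xs, amps, dz, pitch, sigma_z, sigma_x, kz,
                   half_z, half_x):  # pragma: no cover - numba kernel
    h, w = out.shape
    two_pi = 2.0 * math.pi
    for s in range(zs.shape[0]):
        ci = int(round(zs[s] / dz))
        cj = int(round(xs[s] / pitch))
        i0 = max(0, ci - half_z)
        i1 = min(h - 1, ci + half_z)
        j0 = max(0, cj - half_x)
        j1 = min(w - 1, cj + half_x)
        if i1 < i0 or j1 < j0:
            continue
        for i in range(i0, i1 + 1):
            d = i * dz - zs[s]
            az = math.exp(-d * d / (2.0 * sigma_z * sigma_z)) * math.cos(two_pi * kz * d)
            if az == 0.0:
                continue
            a = amps[s] * az
            for j in range(j0, j1 + 1):
                e = j * pitch - xs[s]
                out[i, j] += a * math.exp(-e * e / (2.0 * sigma_x * sigma_x))


def simulate_rf_frame(fieldv: ScattererField, cfg: ImagingConfig,
                      frame_index: int = 0) -> RFFrame:
    """Noiseless RF frame: superposition of one separable PSF per scatterer.

    RF(sample, line) = sum_s amplitude_s x [Gaussian envelope x cosine carrier]
    (axial offset) x Gaussian (lateral offset).  Deterministic given the
    scatterer field.
    """
    out = np.zeros((cfg.n_samples, cfg.lines))
    if fieldv.positions.size:
        half_z = int(math.ceil(4.0 * cfg.axial_sigma / cfg.dz))
        half_x = int(math.ceil(4.0 * cfg.lateral_sigma / cfg.pitch))
        _accumulate_rf(out, np.ascontiguousarray(fieldv.positions[:, 0]),
                       np.ascontiguousarray(fieldv.positions[:, 1]),
                       np.ascontiguousarray(fieldv.amplitudes),
                       cfg.dz, cfg.pitch, cfg.axial_sigma, cfg.lateral_sigma,
                       cfg.carrier_cycles_per_mm, half_z, half_x)
    return RFFrame(out, cfg.sampling_frequency, cfg.pitch, cfg.center_frequency,
                   cfg.speed_of_sound, frame_index)


def add_awgn(frame: RFFrame, snr_db: float, reference_roi, seed: int) -> RFFrame:
    """Superimpose white Gaussian noise so that the signal-to-noise power
    ratio of the *reference ROI's noiseless signal* equals ``snr_db``.

    ``reference_roi`` is (z0, z1, x0, x1) in samples/lines (half-open).
    ``snr_db = inf`` returns the frame unchanged.
    """
    z0, z1, x0, x1 = (int(v) for v in reference_roi)
    roi = frame.samples[z0:z1, x0:x1]
    if roi.size == 0:
        raise ValueError("empty reference ROI")
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return RFFrame(frame.samples.copy(), frame.axial_fs, frame.pitch,
                           frame.center_frequency, frame.sos, frame.frame_index)
        raise ValueError("snr_db must be finite or +inf")
    p_signal = float(np.mean(roi ** 2))
    if p_signal == 0:
        raise ValueError("reference ROI has zero signal power")
    var_noise = p_signal / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = frame.samples + rng.normal(0.0, math.sqrt(var_noise), frame.samples.shape)
    return RFFrame(noisy, frame.axial_fs, frame.pitch, frame.center_frequency,
                   frame.sos, frame.frame_index)


def _default_roi(cfg: ImagingConfig):
    h, w = cfg.n_samples, cfg.lines
    return (h // 8, 3 * h // 8, w // 4, 3 * w // 4)


def generate_sequence(scene: SceneConfig):
    """Generate an RF sequence plus its ground truth.

    Scatterers are drawn once, deformed per frame by the motion model, imaged,
    and (optionally) corrupted by AWGN at the prescribed sonographic SNR with
    per-frame derived seeds.  At least 4 frames are required — the minimum
    that yields the three temporal SMIs spatiotemporal regularization needs.
    """
    if scene.n_frames < 4:
        raise ValueError(
            "a sequence needs at least 4 frames: spatiotemporal regularization "
            "requires four consecutive frames (three SMIs per block)")
    cfg = scene.imaging
    cell = cfg.resolution_cell_mm2
    if scene.scatterer_density * cell < 10:
        log.warning("scatterer density %.1f/mm^2 gives %.1f per resolution cell "
                    "(<10): speckle may not be fully developed",
                    scene.scatterer_density, scene.scatterer_density * cell)
    guard = 2.0 * max(cfg.axial_sigma, cfg.lateral_sigma) * 2.355
    z0, z1, x0, x1 = cfg.region()
    region = (z0 - guard, z1 + guard, x0 - guard, x1 + guard)
    ss = np.random.SeedSequence(scene.seed)
    seeds = ss.generate_state(1 + scene.n_frames) % (2 ** 31)
    base = generate_scatterers(region, scene.scatterer_density, int(seeds[0]))

    roi = scene.noise_roi if scene.noise_roi is not None else _default_roi(cfg)
    snr = scene.snr_db
    frames = []
    for f in range(scene.n_frames):
        moved = deform_scatterers(base, scene.motion, f, guard_mm=guard)
        frame = simulate_rf_frame(moved, cfg, frame_index=f)
        if snr is not None:
            if np.isscalar(snr):
                frame = add_awgn(frame, float(snr), roi, int(seeds[1 + f]))
            else:
                frame = _banded_awgn(frame, tuple(snr), roi, int(seeds[1 + f]))
        frames.append(frame)
    gt = GroundTruth(scene.motion, scene.n_frames, cfg)
    return RFSequence(frames, cfg), gt


def _banded_awgn(frame: RFFrame, snr_pair, roi, seed: int) -> RFFrame:
    """Two-band noise: the requested SNRs apply to the upper and lower halves
    of the frame, both referenced to the (anterior) ROI signal power —
    mimicking depth-dependent attenuation."""
    up_db, low_db = (float(s) for s in snr_pair)
    z0, z1, x0, x1 = (int(v) for v in roi)
    p_signal = float(np.mean(frame.samples[z0:z1, x0:x1] ** 2))
    if p_signal == 0:
        raise ValueError("reference ROI has zero signal power")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(frame.samples.shape)
    h = frame.samples.shape[0]
    out = frame.samples.copy()
    for sl, db in ((slice(0, h // 2), up_db), (slice(h // 2, h), low_db)):
        if np.isfinite(db):
            out[sl] += noise[sl] * math.sqrt(p_signal / 10.0 ** (db / 10.0))
    return RFFrame(out, frame.axial_fs, frame.pitch, frame.center_frequency,
                   frame.sos, frame.frame_index)
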