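"""HDF5 / CSV persistence for RF sequences, displacement fields, strain and
meshes.  Round trips are bitwise for numeric data; every container carries a
format version attribute (mismatches warn and load best-effort; missing keys
raise a :class:`SchemaError` naming the key)."""

from __future__ import annotations

import json
import warnings
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .blockmatch import DisplacementField, RFFrame
from .phantom import GroundTruth, ImagingConfig, MotionModel, RFSequence
from .strain import CardiacMesh, StrainRecord

FORMAT_VERSION = "1"


class SchemaError(KeyError):
    """A required dataset or attribute is missing from a container."""


def _require(obj, key, kind="dataset"):
    if key not in obj:
        raise SchemaError(f"missing {kind} {key!r} in {getattr(obj, 'filename', obj)}")
    return obj[key]


def _check_version(g):
    v = g.attrs.get("format_version")
    if v is None:
        raise SchemaError("missing attribute 'format_version'")
    if str(v) != FORMAT_VERSION:
        warnings.warn(f"format version {v!r} != {FORMAT_VERSION!r}; "
                      "loading best-effort", stacklevel=3)


_IMAGING_ATTRS = ("center_frequency", "sampling_frequency", "pitch",
                  "speed_of_sound", "psf_bandwidth", "lateral_sigma",
                  "lines", "depth")


def save_sequence(path, seq: RFSequence, gt: Optional[GroundTruth] = None):
    """Write an RF sequence (frames x samples x lines) with imaging metadata;
    the motion model is stored as JSON so ground truth is reconstructable."""
    rf = np.stack([f.samples for f in seq.frames])
    with h5py.File(path, "w") as h:
        h.create_dataset("rf", data=rf)
        h.attrs["format_version"] = FORMAT_VERSION
        for k in _IMAGING_ATTRS:
            h.attrs[k] = getattr(seq.imaging, k)
        if gt is not None:
            h.attrs["motion"] = json.dumps({
                "kind": gt.motion.kind, "parameters": gt.motion.parameters,
                "frame_rate": gt.motion.frame_rate, "n_frames": gt.n_frames})


def load_sequence(path):
    """Read an RF sequence; returns ``(RFSequence, GroundTruth | None)``."""
    with h5py.File(path, "r") as h:
        _check_version(h)
        rf = np.array(_require(h, "rf"))
        kw = {}
        for k in _IMAGING_ATTRS:
            if k not in h.attrs:
                raise SchemaError(f"missing attribute {k!r}")
            kw[k] = h.attrs[k]
        kw["lines"] = int(kw["lines"])
        cfg = ImagingConfig(**kw)
        gt = None
        if "motion" in h.attrs:
            m = json.loads(h.attrs["motion"])
            motion = MotionModel(m["kind"],
                                 {k: tuple(v) if isinstance(v, list) else v
                                  for k, v in m["parameters"].items()},
                                 m["frame_rate"])
            gt = GroundTruth(motion, int(m["n_frames"]), cfg)
    frames = [RFFrame(rf[i], cfg.sampling_frequency, cfg.pitch,
                      cfg.center_frequency, cfg.speed_of_sound, i)
              for i in range(rf.shape[0])]
    return RFSequence(frames, cfg), gt


def save_fields(path, fields: Sequence[DisplacementField]):
    """Write displacement fields for consecutive frame pairs (shared grid)."""
    f0 = fields[0]
    with h5py.File(path, "w") as h:
        h.attrs["format_version"] = FORMAT_VERSION
        h.attrs["dz_mm"] = f0.dz_mm
        h.attrs["pitch_mm"] = f0.pitch_mm
        h.create_dataset("disp_axial", data=np.stack([f.axial for f in fields]))
        h.create_dataset("disp_lateral", data=np.stack([f.lateral for f in fields]))
        h.create_dataset("flags", data=np.stack([f.flags for f in fields]))
        h.create_dataset("rows", data=f0.rows)
        h.create_dataset("cols", data=f0.cols)
        h.create_dataset("frame_pairs",
                         data=np.array([f.frame_pair for f in fields]))


def load_fields(path) -> list[DisplacementField]:
    with h5py.File(path, "r") as h:
        _check_version(h)
        ax = np.array(_require(h, "disp_axial"))
        la = np.array(_require(h, "disp_lateral"))
        fl = np.array(_require(h, "flags"))
        rows = np.array(_require(h, "rows"))
        cols = np.array(_require(h, "cols"))
        pairs = np.array(_require(h, "frame_pairs"))
        dz = float(h.attrs["dz_mm"]) if "dz_mm" in h.attrs else _missing("dz_mm")
        pitch = float(h.attrs["pitch_mm"]) if "pitch_mm" in h.attrs else _missing("pitch_mm")
    return [DisplacementField(ax[i], la[i], rows, cols, dz, pitch,
                              (int(pairs[i][0]), int(pairs[i][1])), fl[i])
            for i in range(ax.shape[0])]


def _missing(key):
    raise SchemaError(f"missing attribute {key!r}")


def save_fields_csv(path, fields: Sequence[DisplacementField]):
    """Tidy CSV export of displacement fields (one row per block per pair)."""
    rows = []
    for f in fields:
        rr, cc = np.meshgrid(f.rows, f.cols, indexing="ij")
        rows.append(pd.DataFrame({
            "frame_pre": f.frame_pair[0], "frame_post": f.frame_pair[1],
            "row": rr.ravel(), "col": cc.ravel(),
            "axial_samples": f.axial.ravel(),
            "lateral_lines": f.lateral.ravel(),
            "axial_mm": f.axial_mm.ravel(),
            "lateral_mm": f.lateral_mm.ravel(),
            "flags": f.flags.ravel()}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def save_strain(path, records: Sequence[StrainRecord]):
    with h5py.File(path, "w") as h:
        h.attrs["format_version"] = FORMAT_VERSION
        h.create_dataset("E", data=np.stack([r.E for r in records]))
        h.create_dataset("e_r", data=np.stack([r.e_r for r in records]))
        h.create_dataset("e_l", data=np.stack([r.e_l for r in records]))
        h.create_dataset("flags", data=np.stack([r.flags for r in records]))
        h.create_dataset("frames", data=np.array([r.frame_index for r in records]))


def load_strain(path) -> list[StrainRecord]:
    with h5py.File(path, "r") as h:
        _check_version(h)
        E = np.array(_require(h, "E"))
        e_r = np.array(_require(h, "e_r"))
        e_l = np.array(_require(h, "e_l"))
        fl = np.array(_require(h, "flags"))
        frames = np.array(_require(h, "frames"))
    return [StrainRecord(int(frames[i]), E[i], e_r[i], e_l[i], fl[i])
            for i in range(E.shape[0])]


def save_mesh(path, mesh: CardiacMesh):
    """Mesh as a CSV point list (positions, wall frames, segment labels) with
    the lattice shape on a comment line."""
    df = pd.DataFrame({
        "z_mm": mesh.points[:, 0], "x_mm": mesh.points[:, 1],
        "radial_z": mesh.radial[:, 0], "radial_x": mesh.radial[:, 1],
        "longit_z": mesh.longitudinal[:, 0], "longit_x": mesh.longitudinal[:, 1],
        "segment": mesh.segment_labels})
    with open(path, "w") as fh:
        fh.write(f"# lattice {mesh.lattice_shape[0]} {mesh.lattice_shape[1]}\n")
        df.to_csv(fh, index=False)


def load_mesh(path) -> CardiacMesh:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# lattice"):
            raise SchemaError("mesh CSV must start with a '# lattice' line")
        _, _, nt, na = header.split()
        df = pd.read_csv(fh)
    for col in ("z_mm", "x_mm", "radial_z", "radial_x", "longit_z",
                "longit_x", "segment"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    return CardiacMesh(
        points=df[["z_mm", "x_mm"]].to_numpy(),
        radial=df[["radial_z", "radial_x"]].to_numpy(),
        longitudinal=df[["longit_z", "longit_x"]].to_numpy(),
        segment_labels=df["segment"].to_numpy(dtype=int),
        lattice_shape=(int(nt), int(na)))
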