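"""Pipeline configuration: one YAML document with per-stage sections.

All randomness flows from a single root seed; per-stage seeds are derived
from it, so a (config, seed) pair fully determines every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .bayes import RegularizationParams
from .blockmatch import BMConfig
from .phantom import ImagingConfig, MotionModel, SceneConfig


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    block_matching: BMConfig = field(default_factory=BMConfig)
    regularization: RegularizationParams = field(default_factory=RegularizationParams)
    regularizer: str = "ncc"
    mesh_points: int = 2400
    median_kernel: tuple[int, int] = (5, 5)
    ls_kernel_mm: tuple[float, float] = (0.5, 1.0)
    snr_window: tuple[int, int] = (5, 9)
    seed: int = 0
    write_rf: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.regularizer not in ("ncc", "none", "sbr", "stbr1", "stbr2"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.scene.n_frames < 4:
            raise ValueError("pipeline scenes need at least 4 frames "
                             "(spatiotemporal regularization minimum)")
        if any(k % 2 == 0 for k in self.median_kernel):
            raise ValueError("median kernel dimensions must be odd")
        bm = self.block_matching
        for lv in range(bm.n_levels):
            if bm.search_axial[lv] < 1 or bm.search_lateral[lv] < 1:
                raise ValueError("search half-ranges must be >= 1")

    # ---------------------------------------------------------------- (de)serialization

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "regularizer": self.regularizer,
            "mesh": {"n_points": self.mesh_points},
            "strain": {"median_kernel": list(self.median_kernel),
                       "ls_kernel_mm": list(self.ls_kernel_mm)},
            "evaluation": {"snr_window": list(self.snr_window)},
            "write_rf": self.write_rf,
            "scene": {
                "n_frames": self.scene.n_frames,
                "scatterer_density": self.scene.scatterer_density,
                "snr_db": self.scene.snr_db if self.scene.snr_db is None
                          or isinstance(self.scene.snr_db, (int, float))
                          else list(self.scene.snr_db),
                "noise_roi": None if self.scene.noise_roi is None
                             else list(self.scene.noise_roi),
                "seed": self.scene.seed,
                "imaging": asdict(self.scene.imaging),
                "motion": {"kind": self.scene.motion.kind,
                           "frame_rate": self.scene.motion.frame_rate,
                           "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                                          for k, v in self.scene.motion.parameters.items()}},
            },
            "block_matching": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                               for k, v in asdict(self.block_matching).items()},
            "regularization": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(self.regularization).items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sc = d.get("scene", {})
        motion_d = sc.get("motion", {"kind": "rigid_shift",
                                     "parameters": {"shift": (0.0, 0.0)}})
        motion = MotionModel(motion_d["kind"],
                             {k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in motion_d.get("parameters", {}).items()},
                             motion_d.get("frame_rate", 100.0))
        imaging = ImagingConfig(**sc.get("imaging", {}))
        snr = sc.get("snr_db")
        if isinstance(snr, list):
            snr = tuple(snr)
        roi = sc.get("noise_roi")
        scene = SceneConfig(imaging=imaging, motion=motion,
                            n_frames=sc.get("n_frames", 6),
                            scatterer_density=sc.get("scatterer_density", 220.0),
                            snr_db=snr,
                            noise_roi=None if roi is None else tuple(roi),
                            seed=sc.get("seed", 0))
        bm = BMConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in d.get("block_matching", {}).items()})
        reg = RegularizationParams(**{k: (tuple(v) if isinstance(v, list) else v)
                                      for k, v in d.get("regularization", {}).items()})
        mesh = d.get("mesh", {})
        st = d.get("strain", {})
        ev = d.get("evaluation", {})
        return cls(scene=scene, block_matching=bm, regularization=reg,
                   regularizer=d.get("regularizer", "ncc"),
                   mesh_points=mesh.get("n_points", 2400),
                   median_kernel=tuple(st.get("median_kernel", (5, 5))),
                   ls_kernel_mm=tuple(st.get("ls_kernel_mm", (0.5, 1.0))),
                   snr_window=tuple(ev.get("snr_window", (5, 9))),
                   seed=d.get("seed", 0),
                   write_rf=d.get("write_rf", False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def scene_from_yaml(path) -> SceneConfig:
    """Load just a scene section (for the phantom CLI)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "scene" in d:
        d = d["scene"]
    return PipelineConfig.from_dict({"scene": d}).scene
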