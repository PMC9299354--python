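"""Configuration, frame I/O, and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidInputError

VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}
IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass
class RunConfig:
    """All tunables of the analyze pipeline in one (YAML-loadable) place."""

    pattern_spec: str | None = None  # path to a pattern YAML; None = defaults
    fps_override: float | None = None
    tolerance_mm: float | None = None  # None = line half-width + dot radius
    max_gap_frames: int = 5
    max_missing_fraction: float = 0.10
    dwell_s: float = 0.5
    start_radius_mm: float = 15.0
    velocity_onset_mm_s: float = 10.0
    rectify_frames: int = 30
    detector_min_intensity: float = 150.0
    detector_min_redness: float = 40.0
    detector_min_area_px: int = 3
    detector_max_area_px: int = 500
    alpha: float = 0.05
    roc_cutoff: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.max_gap_frames < 0 or not 0 <= self.max_missing_fraction <= 1:
            raise InvalidInputError("gap/missing parameters out of range")
        if self.dwell_s < 0 or self.start_radius_mm <= 0:
            raise InvalidInputError("segmentation parameters out of range")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.pattern_spec is not None and not Path(cfg.pattern_spec).exists():
            raise InvalidInputError(f"pattern spec not found: {cfg.pattern_spec}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_frames(source) -> tuple[list[np.ndarray], float | None]:
    """Load frames from a directory of images, a video file, or pass through
    an in-memory frame list.  Returns (frames, fps or None).

    Image-sequence directories are the first-class input (sorted by name);
    container formats are decoded through imageio when a backend is present.
    """
    if isinstance(source, (list, tuple)):
        return [np.asarray(f) for f in source], None
    path = Path(source)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        )
        if not files:
            raise InvalidInputError(f"no image frames in directory {path}")
        return [iio.imread(p) for p in files], None
    if not path.exists():
        raise InvalidInputError(f"input not found: {path}")
    if path.suffix.lower() in VIDEO_SUFFIXES:
        try:
            frames = list(iio.imiter(path))
            meta = iio.immeta(path)
            return frames, float(meta.get("fps")) if meta.get("fps") else None
        except Exception as exc:  # backend-dependent
            raise InvalidInputError(
                f"cannot decode {path.name}: no video backend available ({exc}); "
                "use an image-sequence directory instead"
            ) from exc
    raise InvalidInputError(f"unsupported input type: {path}")


def write_frames(frames: list[np.ndarray], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        iio.imwrite(out / f"frame_{i:05d}.png", f)


def write_manifest(out_path: str | Path, config: RunConfig | dict,
                   seed: int | None = None, extra: dict | None = None) -> None:
    """Sidecar JSON recording everything needed to reproduce an output."""
    cfg = asdict(config) if isinstance(config, RunConfig) else dict(config)
    manifest = {
        "software": "cervitrace",
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    Path(out_path).write_text(json.dumps(manifest, indent=2, default=str))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise InvalidInputError(f"table not found: {path}")
    return pd.read_csv(path)
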