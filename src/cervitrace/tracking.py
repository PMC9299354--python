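"""Laser-dot detection and trajectory assembly.

Each video frame is searched for the laser dot (a small, bright, strongly red
blob); present detections are rectified into pattern millimetres and strung
into a fixed-rate trajectory.  Short detection dropouts are linearly
interpolated; the trial window is then segmented with a dwell-then-move rule
at the protocol start corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import InvalidInputError, UnsegmentableTrialError
from .pattern import (
    CORNER_LABELS,
    Rectification,
    TargetPattern,
    map_to_pattern_mm,
    point_to_centerline_distance,
)


@dataclass
class DotDetectorConfig:
    """Thresholds for laser-dot blob detection.

    The dot is found as the connected component maximising an
    intensity-times-redness score, which separates it from achromatic
    specular glare of similar brightness.
    """

    min_intensity: float = 150.0  # red-channel floor, 0-255
    min_redness: float = 40.0  # R - max(G, B) floor
    min_area_px: int = 3
    max_area_px: int = 500


@dataclass
class DotDetection:
    frame_index: int
    centroid_px: np.ndarray | None  # (x, y) or None when missing
    radius_px: float | None
    confidence: float

    def __post_init__(self):
        if (self.centroid_px is None) != (self.radius_px is None):
            raise InvalidInputError("centroid and radius must be present together")
        if self.centroid_px is None and self.confidence != 0.0:
            raise InvalidInputError("missing detection must have confidence 0")

    @property
    def missing(self) -> bool:
        return self.centroid_px is None


@dataclass
class DotTrack:
    """Time-stamped laser-dot trajectory at fixed frame rate.

    ``xy_mm`` rows are NaN where the dot was not detected (and not
    interpolated).  Pixel coordinates are retained for provenance/export.
    """

    fps: float
    t_s: np.ndarray
    xy_mm: np.ndarray
    interpolated: np.ndarray
    xy_px: np.ndarray | None = None
    dot_radius_mm: float | None = None

    def __post_init__(self):
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xy_mm = np.asarray(self.xy_mm, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if len(self.t_s) != len(self.xy_mm) or len(self.t_s) != len(self.interpolated):
            raise InvalidInputError("track arrays must have equal length")
        if len(self.t_s) > 1 and not (np.diff(self.t_s) > 0).all():
            raise InvalidInputError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.xy_mm).any(axis=1)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean()) if len(self) else 0.0

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) > 1 else 0.0

    def window_mask(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        return (self.t_s >= t_start_s) & (self.t_s <= t_end_s)

    def to_dataframe(
        self,
        pattern: TargetPattern | None = None,
        tolerance_mm: float | None = None,
    ) -> pd.DataFrame:
        """Trajectory table; adds ``on_target`` when pattern+tolerance given."""
        n = len(self)
        px = self.xy_px if self.xy_px is not None else np.full((n, 2), np.nan)
        df = pd.DataFrame(
            {
                "frame": np.round(self.t_s * self.fps).astype(int),
                "t_s": self.t_s,
                "x_px": px[:, 0],
                "y_px": px[:, 1],
                "x_mm": self.xy_mm[:, 0],
                "y_mm": self.xy_mm[:, 1],
                "interpolated": self.interpolated.astype(int),
            }
        )
        if pattern is not None and tolerance_mm is not None:
            on = np.full(n, np.nan)
            ok = ~self.missing
            if ok.any():
                d = point_to_centerline_distance(self.xy_mm[ok], pattern)
                on[ok] = (d <= tolerance_mm).astype(float)
            df["on_target"] = on
        return df


@dataclass
class TrialWindow:
    """Segmented trial interval plus the protocol corners it connects."""

    t_start_s: float
    t_end_s: float
    start_corner: str
    end_corner: str

    def __post_init__(self):
        if self.t_end_s <= self.t_start_s:
            raise InvalidInputError("trial window must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def detect_laser_dot(
    frame: np.ndarray,
    config: DotDetectorConfig | None = None,
    frame_index: int = 0,
    board_polygon_px: np.ndarray | None = None,
) -> DotDetection:
    """Detect the laser dot in one colour frame.

    A missing dot is a value (``centroid_px is None``, confidence 0), never an
    error: dropouts are normal when the dot crosses the dark target line.
    """
    cfg = config or DotDetectorConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise InvalidInputError("expected an (H, W, 3) colour frame")
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    redness = r - np.maximum(g, b)
    mask = (r >= cfg.min_intensity) & (redness >= cfg.min_redness)
    if board_polygon_px is not None:
        poly = np.asarray(board_polygon_px)
        if poly.dtype == bool:  # precomputed region mask
            mask &= poly
        else:
            mask &= polygon2mask(frame.shape[:2], poly[:, ::-1].astype(float))
    if not mask.any():
        return DotDetection(frame_index, None, None, 0.0)

    lab = cc_label(mask)
    best, best_score = None, -np.inf
    for p in regionprops(lab):
        if not (cfg.min_area_px <= p.area <= cfg.max_area_px):
            continue
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        score = float((r[rows, cols] * redness[rows, cols]).sum())
        if score > best_score:
            best, best_score = p, score
    if best is None:
        return DotDetection(frame_index, None, None, 0.0)

    rows, cols = best.coords[:, 0], best.coords[:, 1]
    w = r[rows, cols]
    cx = float((cols * w).sum() / w.sum())
    cy = float((rows * w).sum() / w.sum())
    radius = math.sqrt(best.area / math.pi)
    confidence = float(np.clip(w.max() / 255.0, 0.0, 1.0))
    return DotDetection(frame_index, np.array([cx, cy]), radius, confidence)


def build_trajectory(
    detections: list[DotDetection],
    fps: float,
    rectification: Rectification,
) -> DotTrack:
    """Assemble per-frame detections into a rectified mm trajectory.

    Missing detections become NaN rows; the median detected blob radius is
    converted to mm and retained for the on-line tolerance policy.
    """
    if fps <= 0:
        raise InvalidInputError("fps must be positive")
    n = len(detections)
    t = np.array([d.frame_index for d in detections], dtype=float) / fps
    xy_px = np.full((n, 2), np.nan)
    radii = []
    for i, d in enumerate(detections):
        if not d.missing:
            xy_px[i] = d.centroid_px
            radii.append(d.radius_px)
    xy_mm = np.full((n, 2), np.nan)
    ok = ~np.isnan(xy_px).any(axis=1)
    if ok.any():
        xy_mm[ok] = map_to_pattern_mm(xy_px[ok], rectification)
    dot_radius_mm = (
        float(np.median(radii)) * rectification.scale_mm_per_px() if radii else None
    )
    return DotTrack(
        fps=fps,
        t_s=t,
        xy_mm=xy_mm,
        interpolated=np.zeros(n, dtype=bool),
        xy_px=xy_px,
        dot_radius_mm=dot_radius_mm,
    )


def fill_gaps(track: DotTrack, max_gap_frames: int = 5) -> DotTrack:
    """Linearly interpolate detection gaps of at most ``max_gap_frames``.

    Longer gaps (and gaps touching either end of the track) are left missing.
    Non-missing samples are never altered; the operation is idempotent.
    """
    missing = track.missing
    xy = track.xy_mm.copy()
    interp = track.interpolated.copy()
    n = len(track)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        gap = j - i
        if 0 < i and j < n and gap <= max_gap_frames:
            t0, t1 = track.t_s[i - 1], track.t_s[j]
            for k in range(i, j):
                a = (track.t_s[k] - t0) / (t1 - t0)
                xy[k] = (1 - a) * track.xy_mm[i - 1] + a * track.xy_mm[j]
                interp[k] = True
        i = j
    return DotTrack(
        fps=track.fps,
        t_s=track.t_s.copy(),
        xy_mm=xy,
        interpolated=interp,
        xy_px=None if track.xy_px is None else track.xy_px.copy(),
        dot_radius_mm=track.dot_radius_mm,
    )


def segment_trial(
    track: DotTrack,
    pattern: TargetPattern,
    start_corner: str | None = None,
    dwell_s: float = 0.5,
    start_radius_mm: float = 15.0,
    velocity_onset_mm_s: float = 10.0,
) -> TrialWindow:
    """Find the trial window with a dwell-then-move start rule.

    The trial starts at the first sample where the dot, having dwelt at least
    ``dwell_s`` within ``start_radius_mm`` of the start vertex, exceeds
    ``velocity_onset_mm_s``; it ends when the dot first enters the same
    radius around the far end of the traced path.

    Raises
    ------
    UnsegmentableTrialError
        If the dot never dwells at the start, never starts moving, or never
        reaches the end vertex; diagnostics carry what was observed.
    """
    corner = start_corner or pattern.start_corner
    start_v = pattern.endpoint_near_corner(corner)
    ends = np.stack([pattern.centerline[0], pattern.centerline[-1]])
    end_v = ends[np.argmax(np.linalg.norm(ends - start_v, axis=1))]
    end_corner = CORNER_LABELS[
        int(np.argmin(np.linalg.norm(pattern.corners_mm - end_v, axis=1)))
    ]

    xy = track.xy_mm
    ok = ~track.missing
    d_start = np.full(len(track), np.inf)
    d_end = np.full(len(track), np.inf)
    d_start[ok] = np.linalg.norm(xy[ok] - start_v, axis=1)
    d_end[ok] = np.linalg.norm(xy[ok] - end_v, axis=1)

    need = max(1, math.ceil(dwell_s * track.fps))
    speed = np.zeros(len(track))
    delta = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed[:-1] = delta * track.fps  # forward difference; NaN where either end missing

    run = 0
    start_idx = None
    for i in range(len(track)):
        run = run + 1 if d_start[i] <= start_radius_mm else 0
        if run >= need and np.isfinite(speed[i]) and speed[i] > velocity_onset_mm_s:
            start_idx = i
            break
    if start_idx is None:
        raise UnsegmentableTrialError(
            "dot never dwelt at the start vertex and started moving",
            diagnostics={
                "min_dist_to_start_mm": float(np.min(d_start)),
                "max_dwell_frames": int(run),
                "required_dwell_frames": need,
            },
        )
    later = np.where(d_end[start_idx + 1 :] <= start_radius_mm)[0]
    if len(later) == 0:
        raise UnsegmentableTrialError(
            "dot never reached the end vertex after trial start",
            diagnostics={
                "t_start_s": float(track.t_s[start_idx]),
                "min_dist_to_end_mm": float(np.min(d_end[start_idx + 1 :], initial=np.inf)),
            },
        )
    # entering the radius marks approach; the trial ends when the dot stops
    # closing on the end vertex (first local minimum of the distance, with a
    # small hysteresis against jitter), not at radius entry, which would
    # systematically truncate the trial by start_radius / speed seconds.
    enter_idx = start_idx + 1 + int(later[0])
    end_idx = enter_idx
    best = d_end[enter_idx]
    hysteresis_mm = 2.0
    for j in range(enter_idx + 1, len(track)):
        if d_end[j] < best:
            best = d_end[j]
            end_idx = j
        elif np.isfinite(d_end[j]) and d_end[j] > best + hysteresis_mm:
            break
    return TrialWindow(
        t_start_s=float(track.t_s[start_idx]),
        t_end_s=float(track.t_s[end_idx]),
        start_corner=corner,
        end_corner=end_corner,
    )
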