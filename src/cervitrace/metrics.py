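"""Per-trial outcome variables and per-subject pooling.

Four outcomes per trial:

* **Acuity** — percentage of trial samples with the dot on the target line
  (distance to the centerline within a tolerance band).
* **Speed** — mean movement speed, traversed path length / trial time, mm/s.
* **Time** — seconds from trial start to completion.
* **NormAcuity** — Acuity / Time (arbitrary units, % / s), which absorbs the
  speed-accuracy trade-off: a slow careful trace and a fast sloppy one can
  have equal Acuity but very different NormAcuity.

Subject scores pool the 12 protocol trials (3 trials x 4 directions) by
arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidWindowError,
    PoolingError,
    UncomputableMetricError,
)
from .pattern import TargetPattern, point_to_centerline_distance
from .tracking import DotTrack, TrialWindow

DIRECTIONS = ("LR", "RL", "UD", "DU")

OUTCOME_FIELDS = ("acuity_pct", "speed_mm_s", "time_s", "norm_acuity_au")


@dataclass
class TrialResult:
    direction: str
    acuity_pct: float
    speed_mm_s: float
    time_s: float
    norm_acuity_au: float
    qc_pass: bool = True
    missing_fraction: float = 0.0

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise InvalidInputError(f"direction must be one of {DIRECTIONS}")


@dataclass
class SubjectOutcome:
    """Pooled outcomes for one subject at one test occasion."""

    subject_id: str
    group: str  # CON | INP | TNP
    occasion: int  # 1 | 2
    acuity_pct: float
    speed_mm_s: float
    time_s: float
    norm_acuity_au: float
    ndi_pct: float | None = None
    nrs_pain: float | None = None


def default_tolerance_mm(pattern: TargetPattern, dot_radius_mm: float | None) -> float:
    """On-line tolerance: dot-edge overlaps the printed line.

    The printed line has physical width and the laser dot physical extent, so
    "on the line" is an overlap criterion: centre-to-centerline distance at
    most line half-width plus dot radius.  Falls back to a 3 mm dot radius
    when no radius was measured.
    """
    radius = dot_radius_mm if dot_radius_mm is not None else 3.0
    return pattern.line_width_mm / 2.0 + radius


def compute_time(window: TrialWindow) -> float:
    """Trial duration in seconds."""
    dur = window.t_end_s - window.t_start_s
    if dur <= 0:
        raise InvalidWindowError("trial window has non-positive duration")
    return float(dur)


def compute_acuity(
    track: DotTrack,
    pattern: TargetPattern,
    window: TrialWindow,
    tolerance_mm: float,
) -> float:
    """Percentage of in-window samples on the target line.

    Interpolated samples count like detected ones; missing samples are
    excluded from numerator and denominator (sampling is uniform in time, so
    the surviving sample fraction still estimates time-on-line).
    """
    if tolerance_mm <= 0:
        raise InvalidInputError("tolerance_mm must be positive")
    mask = track.window_mask(window.t_start_s, window.t_end_s) & ~track.missing
    n = int(mask.sum())
    if n == 0:
        raise UncomputableMetricError("no usable samples in trial window")
    d = point_to_centerline_distance(track.xy_mm[mask], pattern)
    return float(100.0 * np.mean(d <= tolerance_mm))


def compute_speed(track: DotTrack, window: TrialWindow) -> float:
    """Average movement speed in mm/s: path length traced / window duration."""
    mask = track.window_mask(window.t_start_s, window.t_end_s) & ~track.missing
    if mask.sum() < 2:
        raise UncomputableMetricError("fewer than 2 usable samples in trial window")
    xy = track.xy_mm[mask]
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    return path / compute_time(window)


def compute_norm_acuity(acuity_pct: float, time_s: float) -> float:
    """Acuity normalised by movement time (arbitrary units)."""
    if time_s <= 0:
        raise InvalidInputError("time_s must be positive")
    return acuity_pct / time_s


def score_trial(
    track: DotTrack,
    pattern: TargetPattern,
    window: TrialWindow,
    direction: str,
    tolerance_mm: float | None = None,
    max_missing_fraction: float = 0.10,
) -> TrialResult:
    """Compute all four outcomes for one segmented trial with a QC flag.

    QC fails (flagged, never dropped here) when more than
    ``max_missing_fraction`` of in-window samples are missing after gap
    filling.
    """
    tol = (
        tolerance_mm
        if tolerance_mm is not None
        else default_tolerance_mm(pattern, track.dot_radius_mm)
    )
    time_s = compute_time(window)
    acuity = compute_acuity(track, pattern, window, tol)
    speed = compute_speed(track, window)
    in_win = track.window_mask(window.t_start_s, window.t_end_s)
    miss = float(track.missing[in_win].mean()) if in_win.any() else 1.0
    return TrialResult(
        direction=direction,
        acuity_pct=acuity,
        speed_mm_s=speed,
        time_s=time_s,
        norm_acuity_au=compute_norm_acuity(acuity, time_s),
        qc_pass=miss <= max_missing_fraction,
        missing_fraction=miss,
    )


def pool_trials(trial_results: list[TrialResult]) -> dict[str, float]:
    """Grand mean of each outcome over all QC-passing trials.

    With the balanced protocol (3 trials in each of 4 directions) the grand
    mean equals the mean of direction means.  NormAcuity is pooled from the
    per-trial values, not recomputed from pooled Acuity and Time.

    Raises
    ------
    PoolingError
        If any direction present in the input has zero QC-passing trials.
    """
    if not trial_results:
        raise PoolingError("no trials to pool")
    directions = {t.direction for t in trial_results}
    bad = sorted(
        d for d in directions if not any(t.qc_pass for t in trial_results if t.direction == d)
    )
    if bad:
        raise PoolingError(
            f"directions with no QC-passing trials: {bad}", directions=bad
        )
    good = [t for t in trial_results if t.qc_pass]
    return {f: float(np.mean([getattr(t, f) for t in good])) for f in OUTCOME_FIELDS}


def direction_means(trial_results: list[TrialResult]) -> dict[str, dict[str, float]]:
    """Per-direction outcome means over QC-passing trials (diagnostics)."""
    out: dict[str, dict[str, float]] = {}
    for d in DIRECTIONS:
        sub = [t for t in trial_results if t.direction == d and t.qc_pass]
        if sub:
            out[d] = {f: float(np.mean([getattr(t, f) for t in sub])) for f in OUTCOME_FIELDS}
    return out
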