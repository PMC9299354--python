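"""End-to-end orchestration: frames in, trial/pooled outcome tables out.

This is the programmatic surface the CLI wraps: a trial video (or frame
stack) is rectified from the corner fiducials, the dot is tracked, the trial
window segmented, and the four outcomes scored; pooled per-subject tables
feed the psychometric reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CervitraceError, CornerDetectionError, InvalidInputError
from .io import RunConfig, read_frames
from .metrics import TrialResult, pool_trials, score_trial
from .pattern import (
    Rectification,
    TargetPattern,
    build_zigzag_pattern,
    detect_board_corners,
    estimate_rectification,
    load_pattern_spec,
)
from .stats import reliability_report, validity_report
from .tracking import (
    DotDetectorConfig,
    build_trajectory,
    detect_laser_dot,
    fill_gaps,
    segment_trial,
)

log = logging.getLogger("cervitrace")

DEFAULT_FPS = 25.0


def pattern_from_config(config: RunConfig) -> TargetPattern:
    if config.pattern_spec:
        return load_pattern_spec(config.pattern_spec)
    return build_zigzag_pattern()


def rectification_from_frames(
    frames: list[np.ndarray],
    pattern: TargetPattern,
    n_frames: int = 30,
) -> Rectification:
    """Median corner positions over the first frames -> one static homography.

    Camera and board do not move during a trial, so estimating once from the
    per-frame median is robust to detection jitter in any single frame.
    """
    found = []
    for i, frame in enumerate(frames[:n_frames]):
        try:
            corners, _ = detect_board_corners(frame, frame_index=i)
            found.append(corners)
        except CornerDetectionError:
            continue
    if not found:
        raise CornerDetectionError(
            f"no frame of the first {min(n_frames, len(frames))} yielded 4 corners"
        )
    median = np.median(np.stack(found), axis=0)
    return estimate_rectification(median, pattern)


@dataclass
class TrialAnalysis:
    """One trial's outcomes plus pipeline provenance for the log."""

    result: TrialResult
    residual_px: float
    detection_rate: float
    tolerance_mm: float
    t_start_s: float
    t_end_s: float


def analyze_trial(
    source,
    pattern: TargetPattern,
    config: RunConfig | None = None,
    direction: str = "LR",
    fps: float | None = None,
) -> TrialAnalysis:
    """Score a single trial recording (frame dir, video file, or frame list)."""
    config = config or RunConfig()
    frames, src_fps = read_frames(source)
    if not frames:
        raise InvalidInputError("no frames in input")
    fps = config.fps_override or fps or src_fps or DEFAULT_FPS

    rect = rectification_from_frames(frames, pattern, config.rectify_frames)
    from skimage.draw import polygon2mask

    board_mask = polygon2mask(
        frames[0].shape[:2], rect.source_corners_px[:, ::-1]
    )
    det_cfg = DotDetectorConfig(
        min_intensity=config.detector_min_intensity,
        min_redness=config.detector_min_redness,
        min_area_px=config.detector_min_area_px,
        max_area_px=config.detector_max_area_px,
    )
    detections = [
        detect_laser_dot(f, det_cfg, frame_index=i, board_polygon_px=board_mask)
        for i, f in enumerate(frames)
    ]
    detection_rate = float(np.mean([not d.missing for d in detections]))
    track = build_trajectory(detections, fps, rect)
    track = fill_gaps(track, config.max_gap_frames)
    start_corner = {"LR": "TL", "RL": "TR", "UD": "TL", "DU": "BL"}.get(direction)
    window = segment_trial(
        track,
        pattern,
        start_corner=start_corner,
        dwell_s=config.dwell_s,
        start_radius_mm=config.start_radius_mm,
        velocity_onset_mm_s=config.velocity_onset_mm_s,
    )
    result = score_trial(
        track,
        pattern,
        window,
        direction=direction,
        tolerance_mm=config.tolerance_mm,
        max_missing_fraction=config.max_missing_fraction,
    )
    from .metrics import default_tolerance_mm

    tol = (
        config.tolerance_mm
        if config.tolerance_mm is not None
        else default_tolerance_mm(pattern, track.dot_radius_mm)
    )
    log.info(
        "trial %s: acuity=%.1f%% speed=%.1f mm/s time=%.2f s qc=%s "
        "(detection %.0f%%, residual %.2f px)",
        direction, result.acuity_pct, result.speed_mm_s, result.time_s,
        result.qc_pass, 100 * detection_rate, rect.residual_px,
    )
    return TrialAnalysis(
        result=result,
        residual_px=rect.residual_px,
        detection_rate=detection_rate,
        tolerance_mm=tol,
        t_start_s=window.t_start_s,
        t_end_s=window.t_end_s,
    )


def analyze_batch(
    trial_specs: list[dict],
    pattern: TargetPattern,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Analyze many trial recordings and pool per subject x occasion.

    Each spec dict needs ``source`` plus optional ``subject_id``, ``occasion``,
    ``direction``, ``trial_no``.  Returns (trial table, pooled table, error
    records); failures never abort the batch.
    """
    config = config or RunConfig()
    rows, errors = [], []
    for spec in trial_specs:
        base = {
            "subject_id": spec.get("subject_id", "S0001"),
            "occasion": int(spec.get("occasion", 1)),
            "direction": spec.get("direction", "LR"),
            "trial_no": int(spec.get("trial_no", 1)),
        }
        try:
            ana = analyze_trial(
                spec["source"], pattern, config,
                direction=base["direction"], fps=spec.get("fps"),
            )
        except CervitraceError as exc:
            errors.append({**base, "source": str(spec["source"]), "error": str(exc)})
            log.error("trial failed (%s): %s", spec["source"], exc)
            continue
        r = ana.result
        rows.append(
            {**base,
             "acuity_pct": r.acuity_pct, "speed_mm_s": r.speed_mm_s,
             "time_s": r.time_s, "norm_acuity_au": r.norm_acuity_au,
             "qc_pass": r.qc_pass, "missing_fraction": r.missing_fraction,
             "detection_rate": ana.detection_rate,
             "residual_px": ana.residual_px}
        )
    trials = pd.DataFrame(rows)
    pooled_rows = []
    if not trials.empty:
        for (sid, occ), sub in trials.groupby(["subject_id", "occasion"]):
            results = [
                TrialResult(
                    direction=t.direction, acuity_pct=t.acuity_pct,
                    speed_mm_s=t.speed_mm_s, time_s=t.time_s,
                    norm_acuity_au=t.norm_acuity_au, qc_pass=bool(t.qc_pass),
                )
                for t in sub.itertuples()
            ]
            try:
                pooled = pool_trials(results)
            except CervitraceError as exc:
                errors.append({"subject_id": sid, "occasion": occ,
                               "error": str(exc)})
                continue
            pooled_rows.append({"subject_id": sid, "occasion": occ, **pooled})
    return trials, pd.DataFrame(pooled_rows), errors


def stats_workflow(
    pooled: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Psychometric battery over a pooled outcomes table.

    ``pooled`` needs subject_id, occasion and the four outcomes; ``metadata``
    (subject_id, group, optionally ndi_pct / nrs_pain) is merged in when the
    pooled table lacks those columns.  Validity runs on occasion 1;
    reliability needs subjects present at both occasions and is skipped with
    a warning otherwise.
    """
    config = config or RunConfig()
    df = pooled.copy()
    if metadata is not None:
        overlap = [c for c in metadata.columns if c != "subject_id" and c in df.columns]
        df = df.drop(columns=overlap).merge(metadata, on="subject_id", how="left")
    if "group" not in df.columns:
        raise InvalidInputError("outcomes need a 'group' column (CON/INP/TNP)")
    if "occasion" not in df.columns:
        df["occasion"] = 1
    occ1 = df[df["occasion"] == 1]
    reports = validity_report(
        occ1, alpha=config.alpha, roc_cutoff=config.roc_cutoff
    )
    occ2 = df[df["occasion"] == 2]
    both = set(occ1["subject_id"]) & set(occ2["subject_id"])
    if both:
        reports["reliability"] = reliability_report(
            occ1[occ1["subject_id"].isin(both)],
            occ2[occ2["subject_id"].isin(both)],
            alpha=config.alpha,
        )
    else:
        log.warning("single-occasion data: reliability analysis skipped")
    return reports


def reliability_interpretation(rel: pd.DataFrame) -> str:
    """Plain-text block applying the ICC interpretation bands."""
    lines = ["Test-retest reliability interpretation (ICC 2,k bands:",
             "<0.5 poor, 0.5-0.75 moderate, 0.75-0.90 good, >0.90 excellent):"]
    for row in rel.itertuples():
        lines.append(
            f"  {row.variable}: ICC = {row.icc:.3f} "
            f"(95% CI {row.icc_ci_low:.3f}-{row.icc_ci_high:.3f}) -> "
            f"{row.icc_label}; SEM = {row.sem:.2f}, MDC = {row.mdc:.2f}"
        )
    return "\n".join(lines)
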