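"""Synthetic ground truth at two levels.

1. **Scripted trajectories and rendered frames** — a dot moves along the
   zigzag centerline at a scripted speed profile with Gaussian lateral error,
   and frames showing board, fiducials, target line and laser dot are
   rendered under a known projective camera.  Because the script is the
   ground truth, every stage of the image pipeline (corner detection,
   rectification, dot tracking, metric extraction) can be checked against
   exact expected values.

2. **Simulated cohorts** — three-group (CON / INP / TNP), two-occasion
   outcome tables with known between-subject and within-subject variance
   components, group mean shifts, an occasion-2 learning effect, and an
   NDI score correlated with Acuity in the patient groups.  Default
   parameters follow the published group descriptives of the clinical
   study population this system targets.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import GeometryInfeasibleError, InvalidInputError
from .pattern import TargetPattern
from .tracking import DotTrack

# ------------------------------------------------------------- trajectories


@dataclass
class TrajectoryScript:
    """Recipe for one simulated trial trace."""

    pattern: TargetPattern
    duration_s: float = 20.0
    dwell_s: float = 1.0
    fps: float = 25.0
    speed_profile: str = "constant"  # constant | ramped
    lateral_error_sd_mm: float = 1.5
    ar1_coeff: float = 0.0  # 0 = i.i.d.; >0 adds tremor-like smoothness
    start_corner: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidInputError("traverse duration must be positive")
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        if self.lateral_error_sd_mm < 0:
            raise InvalidInputError("lateral error SD must be >= 0")
        if not -1 < self.ar1_coeff < 1:
            raise InvalidInputError("AR(1) coefficient must be in (-1, 1)")
        if self.speed_profile not in ("constant", "ramped"):
            raise InvalidInputError("speed_profile must be constant|ramped")


@dataclass
class GroundTruth:
    """What the script implies for the trial metrics."""

    time_s: float
    speed_mm_s: float
    lateral_error_sd_mm: float
    path_length_mm: float

    def expected_acuity_pct(self, tolerance_mm: float) -> float:
        """Closed-form expected acuity, 100 * (2 * Phi(tau/sigma) - 1).

        Exact when the distance to the centerline equals the absolute
        lateral offset, i.e. on straight segments; near zigzag vertices the
        measured distance can be smaller (the adjacent segment is closer),
        so on folded patterns the realised acuity sits slightly above this
        value.
        """
        if self.lateral_error_sd_mm == 0:
            return 100.0
        return float(100.0 * (2.0 * norm.cdf(tolerance_mm / self.lateral_error_sd_mm) - 1.0))


def _oriented_centerline(pattern: TargetPattern, start_corner: str | None) -> np.ndarray:
    """Centerline ordered so the trace starts at the protocol start corner."""
    corner = start_corner or pattern.start_corner
    start_v = pattern.endpoint_near_corner(corner)
    line = pattern.centerline
    if np.linalg.norm(line[-1] - start_v) < np.linalg.norm(line[0] - start_v):
        line = line[::-1]
    return line


def _arc_interp(line: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents at arc positions ``s`` along a polyline."""
    seg = np.diff(line, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.clip(s, 0.0, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] == 0, 1.0, seg_len[idx])
    pts = line[idx] + frac[:, None] * seg[idx]
    tangents = seg[idx] / np.where(seg_len[idx] == 0, 1.0, seg_len[idx])[:, None]
    return pts, tangents


def simulate_trajectory(script: TrajectoryScript) -> tuple[DotTrack, GroundTruth]:
    """Generate a mm-space dot trajectory following the scripted trace.

    The dot dwells at the start vertex for ``dwell_s``, then traverses the
    full centerline over ``duration_s`` (constant arc speed, or a cosine
    ramp that starts and ends at rest).  Lateral error of SD sigma is applied
    perpendicular to the local path direction, i.i.d. per sample or AR(1)
    when ``ar1_coeff`` > 0 (stationary marginal SD stays sigma).
    """
    rng = np.random.default_rng(script.seed)
    pattern = script.pattern
    line = _oriented_centerline(pattern, script.start_corner)
    total = pattern.path_length_mm

    n_dwell = int(round(script.dwell_s * script.fps))
    n_move = int(round(script.duration_s * script.fps)) + 1
    t_move = np.arange(n_move) / script.fps
    frac = t_move / script.duration_s
    if script.speed_profile == "constant":
        s = total * frac
    else:  # cosine ramp: rest -> peak -> rest
        s = total * (1 - np.cos(np.pi * frac)) / 2.0

    arc = np.concatenate([np.zeros(n_dwell), s])
    pts, tangents = _arc_interp(line, arc)

    sigma = script.lateral_error_sd_mm
    n = len(arc)
    if sigma > 0:
        if script.ar1_coeff:
            rho = script.ar1_coeff
            eps = rng.normal(0.0, sigma, n)
            off = np.empty(n)
            off[0] = eps[0]
            innov_scale = np.sqrt(1 - rho**2)
            for i in range(1, n):
                off[i] = rho * off[i - 1] + innov_scale * eps[i]
        else:
            off = rng.normal(0.0, sigma, n)
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        pts = pts + normals * off[:, None]

    track = DotTrack(
        fps=script.fps,
        t_s=np.arange(n) / script.fps,
        xy_mm=pts,
        interpolated=np.zeros(n, dtype=bool),
    )
    truth = GroundTruth(
        time_s=script.duration_s,
        speed_mm_s=total / script.duration_s,
        lateral_error_sd_mm=sigma,
        path_length_mm=total,
    )
    return track, truth


# ---------------------------------------------------------------- rendering


@dataclass
class CameraSpec:
    """Static projective camera viewing the whole board obliquely.

    The default mimics a tripod camera behind and above the subject's right
    shoulder: a 20 degree oblique pitch/yaw, 720p at 25 fps.
    """

    width: int = 1280
    height: int = 720
    fps: float = 25.0
    pitch_deg: float = 20.0
    yaw_deg: float = 20.0
    roll_deg: float = 0.0  # in-plane camera rotation
    distance_mm: float = 1500.0
    focal_mm: float = 1200.0
    margin_frac: float = 0.06

    def homography_mm_to_px(self, pattern: TargetPattern) -> np.ndarray:
        """3x3 homography mapping board mm to image pixels.

        Built from a rotated pinhole view of the board plane, then rescaled
        by an affinity so the projected board fills the image inside the
        margin — which guarantees the board is fully in view.
        """
        bw, bh = pattern.board_size_mm
        cx, cy = bw / 2.0, bh / 2.0
        p, yw = np.deg2rad(self.pitch_deg), np.deg2rad(self.yaw_deg)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]]
        )
        ry = np.array(
            [[np.cos(yw), 0, np.sin(yw)], [0, 1, 0], [-np.sin(yw), 0, np.cos(yw)]]
        )
        rot = ry @ rx
        # board plane z=0; homography columns from rotation + translation
        t = np.array([0.0, 0.0, self.distance_mm])
        k = np.array(
            [[self.focal_mm, 0, 0], [0, self.focal_mm, 0], [0, 0, 1.0]]
        )
        h_raw = k @ np.column_stack([rot[:, 0], rot[:, 1], t])
        # recentre mm origin at board centre before projecting
        shift = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
        h = h_raw @ shift
        if self.roll_deg:
            r = np.deg2rad(self.roll_deg)
            roll = np.array(
                [[np.cos(r), -np.sin(r), 0], [np.sin(r), np.cos(r), 0], [0, 0, 1.0]]
            )
            h = roll @ h
        corners = np.hstack([pattern.corners_mm, np.ones((4, 1))]) @ h.T
        px = corners[:, :2] / corners[:, 2:3]
        lo, hi = px.min(axis=0), px.max(axis=0)
        mx, my = self.margin_frac * self.width, self.margin_frac * self.height
        scale = min(
            (self.width - 2 * mx) / (hi[0] - lo[0]),
            (self.height - 2 * my) / (hi[1] - lo[1]),
        )
        span = (hi - lo) * scale
        off = np.array(
            [
                (self.width - span[0]) / 2.0 - lo[0] * scale,
                (self.height - span[1]) / 2.0 - lo[1] * scale,
            ]
        )
        fit = np.array([[scale, 0, off[0]], [0, scale, off[1]], [0, 0, 1.0]])
        return fit @ h


@dataclass
class RenderNoiseSpec:
    """Optional imaging nuisances for robustness testing."""

    sensor_noise_sd: float = 0.0  # additive Gaussian, intensity units
    n_glare_blobs: int = 0  # white specular blobs inside the board
    glare_radius_px: float = 6.0
    seed: int = 0


@dataclass
class RenderResult:
    frames: list[np.ndarray]  # uint8 (H, W, 3)
    fps: float
    corner_px: np.ndarray  # (4, 2) ground-truth fiducial centres, TL TR BR BL
    dot_px: np.ndarray  # (N, 2) ground-truth dot pixels (NaN where off-board)
    homography_mm_to_px: np.ndarray


def render_frames(
    pattern: TargetPattern,
    track: DotTrack,
    camera: CameraSpec | None = None,
    noise: RenderNoiseSpec | None = None,
    fiducial_mm: float = 12.0,
    dot_sigma_px: float = 3.0,
) -> RenderResult:
    """Render the board scene with the dot at each track sample.

    The static background (grey wall, white board, black target line, black
    corner fiducials) is rasterised once by mapping every pixel back to board
    mm through the inverse homography; per frame only the dot (and optional
    glare/sensor noise) is composited on a copy.  Ground-truth fiducial and
    dot pixel positions are returned for detector validation.
    """
    camera = camera or CameraSpec()
    noise = noise or RenderNoiseSpec()
    h_mm_px = camera.homography_mm_to_px(pattern)
    h_px_mm = np.linalg.inv(h_mm_px)
    bw, bh = pattern.board_size_mm

    corners_h = np.hstack([pattern.corners_mm, np.ones((4, 1))]) @ h_mm_px.T
    corner_px = corners_h[:, :2] / corners_h[:, 2:3]
    if (
        corner_px.min() < 0
        or corner_px[:, 0].max() > camera.width
        or corner_px[:, 1].max() > camera.height
    ):
        raise GeometryInfeasibleError("board not fully inside the camera view")

    # pixel grid -> mm (static camera: computed once)
    xs, ys = np.meshgrid(np.arange(camera.width), np.arange(camera.height))
    pix = np.stack([xs.ravel(), ys.ravel(), np.ones(xs.size)], axis=1)
    mm = pix @ h_px_mm.T
    mm = (mm[:, :2] / mm[:, 2:3]).reshape(camera.height, camera.width, 2)

    on_board = (
        (mm[..., 0] >= 0) & (mm[..., 0] <= bw) & (mm[..., 1] >= 0) & (mm[..., 1] <= bh)
    )
    bg = np.full((camera.height, camera.width), 90.0)  # wall grey
    bg[on_board] = 235.0  # board white

    # target line: distance of each on-board pixel to the centerline
    from .pattern import point_to_centerline_distance

    board_mm = mm[on_board]
    d = point_to_centerline_distance(board_mm, pattern)
    line_mask = np.zeros_like(on_board)
    line_mask[on_board] = d <= pattern.line_width_mm / 2.0
    bg[line_mask] = 20.0

    half = fiducial_mm / 2.0
    for cx, cy in pattern.corners_mm:
        fid = (np.abs(mm[..., 0] - cx) <= half) & (np.abs(mm[..., 1] - cy) <= half)
        bg[fid] = 15.0
    background = np.repeat(bg[..., None], 3, axis=2).astype(np.uint8)

    rng = np.random.default_rng(noise.seed)
    dot_h = np.hstack([track.xy_mm, np.ones((len(track), 1))]) @ h_mm_px.T
    with np.errstate(invalid="ignore"):
        dot_px = dot_h[:, :2] / dot_h[:, 2:3]

    frames = []
    rad = int(np.ceil(4 * dot_sigma_px))
    for i in range(len(track)):
        frame = background.copy()
        cx, cy = dot_px[i]
        if np.isfinite(cx):
            _splat(frame, cx, cy, dot_sigma_px, rad, np.array([255.0, 70.0, 70.0]))
        for _ in range(noise.n_glare_blobs):
            gm = pattern.corners_mm.mean(axis=0) + rng.uniform(-60, 60, 2)
            gh = h_mm_px @ np.array([gm[0], gm[1], 1.0])
            _splat(
                frame, gh[0] / gh[2], gh[1] / gh[2],
                noise.glare_radius_px / 2.0, int(2 * noise.glare_radius_px),
                np.array([250.0, 250.0, 250.0]),
            )
        if noise.sensor_noise_sd > 0:
            jitter = rng.normal(0.0, noise.sensor_noise_sd, frame.shape)
            frame = np.clip(frame.astype(float) + jitter, 0, 255).astype(np.uint8)
        frames.append(frame)
    return RenderResult(frames, camera.fps, corner_px, dot_px, h_mm_px)


def _splat(frame: np.ndarray, cx: float, cy: float, sigma: float, rad: int,
           color: np.ndarray) -> None:
    """Composite a Gaussian blob of a given colour onto a uint8 frame."""
    h, w = frame.shape[:2]
    x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
    y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    g = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    patch = frame[y0:y1, x0:x1].astype(float)
    blended = patch + g[..., None] * (color[None, None, :] - patch)
    frame[y0:y1, x0:x1] = np.clip(blended, 0, 255).astype(np.uint8)


# ------------------------------------------------------------------ cohorts


#: Group-level generating parameters: outcome means, between-subject SDs
#: (cross-sectional descriptives of the clinical population), within-subject
#: occasion-error SDs (test-retest SEMs), the occasion-2 learning shift, and
#: the NDI / NRS models for the patient groups.
DEFAULT_COHORT = {
    "groups": {
        "CON": {
            "n": 52,
            "mean": {"acuity_pct": 62.7, "speed_mm_s": 61.7, "time_s": 27.9,
                     "norm_acuity_au": 2.7},
            "between_sd": {"acuity_pct": 1.7, "speed_mm_s": 37.4, "time_s": 11.5,
                           "norm_acuity_au": 0.1},
        },
        "INP": {
            "n": 26,
            "mean": {"acuity_pct": 64.2, "speed_mm_s": 52.5, "time_s": 37.2,
                     "norm_acuity_au": 2.2},
            "between_sd": {"acuity_pct": 12.8, "speed_mm_s": 32.3, "time_s": 20.6,
                           "norm_acuity_au": 1.1},
            "ndi": {"mean": 29.9, "sd": 14.0, "acuity_r": -0.373},
            "nrs": {"mean": 4.4, "sd": 2.6},
        },
        "TNP": {
            "n": 28,
            "mean": {"acuity_pct": 66.7, "speed_mm_s": 46.0, "time_s": 36.5,
                     "norm_acuity_au": 2.1},
            "between_sd": {"acuity_pct": 13.7, "speed_mm_s": 22.9, "time_s": 13.3,
                           "norm_acuity_au": 0.6},
            "ndi": {"mean": 40.5, "sd": 14.7, "acuity_r": 0.389},
            "nrs": {"mean": 4.6, "sd": 2.5},
        },
    },
    "within_sd": {"acuity_pct": 4.5, "speed_mm_s": 17.3, "time_s": 4.4,
                  "norm_acuity_au": 0.4},
    "occasion2_shift": {"acuity_pct": 0.0, "speed_mm_s": 10.0, "time_s": -3.5,
                        "norm_acuity_au": 0.4},
}

OUTCOME_VARS = ("acuity_pct", "speed_mm_s", "time_s", "norm_acuity_au")


@dataclass
class CohortSpec:
    """Generating model for a two-occasion, three-group cohort.

    ``groups[g]`` carries n, per-outcome means and between-subject SDs and,
    for patient groups, NDI/NRS models; ``within_sd`` the per-outcome
    occasion-error SD; ``occasion2_shift`` the systematic learning effect.
    """

    groups: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COHORT["groups"])
    )
    within_sd: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COHORT["within_sd"])
    )
    occasion2_shift: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COHORT["occasion2_shift"])
    )
    seed: int = 0

    def __post_init__(self):
        for g, cfg in self.groups.items():
            if cfg["n"] < 2:
                raise InvalidInputError(f"group {g!r} needs n >= 2")
            if any(sd < 0 for sd in cfg["between_sd"].values()):
                raise InvalidInputError("between-subject SDs must be >= 0")
            ndi = cfg.get("ndi")
            if ndi is not None and abs(ndi.get("acuity_r", 0.0)) > 1:
                raise InvalidInputError("|NDI-Acuity correlation| must be <= 1")
        if any(sd < 0 for sd in self.within_sd.values()):
            raise InvalidInputError("within-subject SDs must be >= 0")


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a cohort; one row per subject per occasion.

    Subject true scores are Normal(group mean, between-SD) per outcome;
    observed scores add Normal(0, within-SD) occasion error and the
    occasion-2 shift.  NDI is drawn jointly with the Acuity true score as a
    bivariate normal at the specified correlation, then clipped to [0, 100].
    Outcomes are clipped to their physical ranges (acuity 0-100, speed and
    NormAcuity >= 0, time > 0).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, cfg in spec.groups.items():
        for _ in range(cfg["n"]):
            sid += 1
            true = {}
            ndi_val = nrs_val = None
            ndi_cfg = cfg.get("ndi")
            # acuity first (possibly jointly with NDI)
            mu_a = cfg["mean"]["acuity_pct"]
            sd_a = cfg["between_sd"]["acuity_pct"]
            if ndi_cfg is not None:
                r = float(ndi_cfg.get("acuity_r", 0.0))
                z = rng.multivariate_normal(
                    [0.0, 0.0], [[1.0, r], [r, 1.0]]
                )
                true["acuity_pct"] = mu_a + sd_a * z[0]
                ndi_val = float(
                    np.clip(ndi_cfg["mean"] + ndi_cfg["sd"] * z[1], 0.0, 100.0)
                )
                nrs_cfg = cfg.get("nrs", {"mean": 5.0, "sd": 2.0})
                nrs_val = float(
                    np.clip(rng.normal(nrs_cfg["mean"], nrs_cfg["sd"]), 0.0, 10.0)
                )
            else:
                true["acuity_pct"] = rng.normal(mu_a, sd_a)
            for var in OUTCOME_VARS[1:]:
                true[var] = rng.normal(cfg["mean"][var], cfg["between_sd"][var])
            for occ in (1, 2):
                row = {"subject_id": f"S{sid:04d}", "group": group, "occasion": occ,
                       "ndi_pct": ndi_val, "nrs_pain": nrs_val}
                for var in OUTCOME_VARS:
                    v = true[var] + rng.normal(0.0, spec.within_sd[var])
                    if occ == 2:
                        v += spec.occasion2_shift.get(var, 0.0)
                    row[var] = _clip_outcome(var, v)
                rows.append(row)
    return pd.DataFrame(rows)


def _clip_outcome(var: str, v: float) -> float:
    if var == "acuity_pct":
        return float(np.clip(v, 0.0, 100.0))
    if var == "time_s":
        return float(max(v, 1e-3))
    return float(max(v, 0.0))
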