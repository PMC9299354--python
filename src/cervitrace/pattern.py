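"""Printed zigzag target: geometry, corner-fiducial detection, rectification.

The physical target is a 1 mm black line folded into a zigzag, total path
length 100 cm, printed on an A3 board with high-contrast corner fiducials.
Pattern coordinates are millimetres with the origin at the top-left board
corner, x to the right, y down.  A planar homography estimated from the four
fiducials maps camera pixels into this frame, which is what makes mm/s speeds
and mm distance tolerances possible from an oblique consumer-camera view.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from skimage.measure import label, regionprops
from skimage.transform import ProjectiveTransform

from .errors import (
    CornerDetectionError,
    DegenerateGeometryError,
    GeometryInfeasibleError,
    NumericDegeneracyError,
)

# A3 paper in mm
A3_LANDSCAPE = (420.0, 297.0)
A3_PORTRAIT = (297.0, 420.0)

CORNER_LABELS = ("TL", "TR", "BR", "BL")


@dataclass
class TargetPattern:
    """Zigzag target in pattern-mm coordinates.

    ``centerline`` is the ordered (N, 2) vertex array of the target line,
    ``corners_mm`` the four board corners in TL, TR, BR, BL order.
    """

    centerline: np.ndarray
    line_width_mm: float
    board_size_mm: tuple[float, float]
    corners_mm: np.ndarray
    orientation: str
    start_corner: str
    path_length_mm: float
    n_peaks: int = 5
    amplitude_mm: float = 0.0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.corners_mm = np.asarray(self.corners_mm, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise GeometryInfeasibleError("centerline must be an (N, 2) array")
        seg = np.diff(self.centerline, axis=0)
        length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        if not np.isclose(length, self.path_length_mm, rtol=1e-6, atol=1e-6):
            raise GeometryInfeasibleError(
                f"centerline length {length:.6f} != declared path_length_mm "
                f"{self.path_length_mm:.6f}"
            )
        w, h = self.board_size_mm
        eps = 1e-9
        x, y = self.centerline[:, 0], self.centerline[:, 1]
        if (x < -eps).any() or (x > w + eps).any() or (y < -eps).any() or (y > h + eps).any():
            raise GeometryInfeasibleError("centerline leaves the board rectangle")

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of the centerline segments."""
        return self.centerline[:-1], self.centerline[1:]

    def corner_mm(self, label: str) -> np.ndarray:
        """Board corner coordinates for a TL/TR/BR/BL label."""
        return self.corners_mm[CORNER_LABELS.index(label)]

    def endpoint_near_corner(self, corner: str) -> np.ndarray:
        """Centerline endpoint (first or last vertex) nearest a board corner.

        Trial protocol names the corner the trace starts from; the physical
        start point is the end of the printed line closest to that corner.
        """
        ref = self.corner_mm(corner)
        ends = np.stack([self.centerline[0], self.centerline[-1]])
        return ends[np.argmin(np.linalg.norm(ends - ref, axis=1))]

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "start_corner": self.start_corner,
            "n_peaks": self.n_peaks,
            "amplitude_mm": float(self.amplitude_mm),
            "board_size_mm": [float(v) for v in self.board_size_mm],
            "line_width_mm": float(self.line_width_mm),
            "path_length_mm": float(self.path_length_mm),
        }


def build_zigzag_pattern(
    orientation: str = "horizontal",
    start_corner: str = "TL",
    n_peaks: int = 5,
    amplitude_mm: float | None = None,
    board_size_mm: tuple[float, float] = A3_LANDSCAPE,
    path_length_mm: float = 1000.0,
    line_width_mm: float = 1.0,
    margin_mm: float = 20.0,
) -> TargetPattern:
    """Construct the zigzag target with an exact requested path length.

    The zigzag has ``2 * n_peaks`` straight segments spanning the board width
    (minus margins); when ``amplitude_mm`` is None the peak amplitude is
    solved so the segment lengths sum exactly to ``path_length_mm``.  When an
    amplitude is given, the horizontal span is solved instead.  A degenerate
    ``amplitude_mm=0`` gives a straight line of length ``path_length_mm``
    (useful for analytic checks; needs a long enough board).

    Vertical patterns are the 90-degree rotation of the horizontal one about
    the board centre, on the transposed board.

    Raises
    ------
    GeometryInfeasibleError
        If the requested path cannot fit on the board.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation must be horizontal|vertical, got {orientation!r}")
    if start_corner not in CORNER_LABELS:
        raise ValueError(f"start_corner must be one of {CORNER_LABELS}")
    if n_peaks < 1:
        raise GeometryInfeasibleError("n_peaks must be >= 1")
    if path_length_mm <= 0 or min(board_size_mm) <= 0:
        raise GeometryInfeasibleError("path length and board size must be positive")

    # build in the landscape frame, rotate at the end if vertical
    # (board_size_mm is always given as the landscape dimensions)
    bw, bh = board_size_mm
    m = 2 * n_peaks  # number of segments
    seg_len = path_length_mm / m

    if amplitude_mm is None:
        span = bw - 2 * margin_mm
        if span <= 0:
            raise GeometryInfeasibleError("margins exceed board width")
        dx = span / m
        if seg_len < dx:
            raise GeometryInfeasibleError(
                f"path length {path_length_mm} mm shorter than board span {span} mm"
            )
        half_amp = 0.5 * np.sqrt(seg_len**2 - dx**2)
    else:
        if amplitude_mm < 0:
            raise GeometryInfeasibleError("amplitude must be >= 0")
        half_amp = amplitude_mm / 2.0
        if seg_len < 2 * half_amp:
            raise GeometryInfeasibleError(
                "amplitude too large for the requested path length"
            )
        dx = np.sqrt(seg_len**2 - (2 * half_amp) ** 2)
        span = m * dx

    if span > bw - 2 * margin_mm + 1e-9:
        raise GeometryInfeasibleError(
            f"zigzag span {span:.1f} mm does not fit board width {bw} mm "
            f"with {margin_mm} mm margins"
        )
    if 2 * half_amp > bh - 2 * margin_mm:
        raise GeometryInfeasibleError(
            f"zigzag amplitude {2 * half_amp:.1f} mm does not fit board height {bh} mm"
        )

    x0 = (bw - span) / 2.0
    yc = bh / 2.0
    xs = x0 + np.arange(m + 1) * dx
    ys = np.where(np.arange(m + 1) % 2 == 0, yc - half_amp, yc + half_amp)
    centerline = np.stack([xs, ys], axis=1)

    if orientation == "vertical":
        # rotate +90 deg about the landscape board centre onto the portrait board
        c_land = np.array([bw / 2.0, bh / 2.0])
        c_port = np.array([bh / 2.0, bw / 2.0])
        rel = centerline - c_land
        centerline = np.stack([-rel[:, 1], rel[:, 0]], axis=1) + c_port
        bw, bh = bh, bw

    corners = np.array([[0.0, 0.0], [bw, 0.0], [bw, bh], [0.0, bh]])
    return TargetPattern(
        centerline=centerline,
        line_width_mm=line_width_mm,
        board_size_mm=(bw, bh),
        corners_mm=corners,
        orientation=orientation,
        start_corner=start_corner,
        path_length_mm=path_length_mm,
        n_peaks=n_peaks,
        amplitude_mm=2 * half_amp,
    )


@dataclass
class Rectification:
    """Planar projective pixel -> pattern-mm transform from the 4 fiducials."""

    matrix: np.ndarray  # 3x3, maps pixel homogeneous coords to mm
    residual_px: float
    source_corners_px: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateGeometryError("rectification matrix is singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def scale_mm_per_px(self) -> float:
        """Approximate isotropic scale at the board centre (mm per pixel)."""
        centre_px = self.source_corners_px.mean(axis=0)
        eps = 1.0
        probe = np.array([centre_px, centre_px + [eps, 0], centre_px + [0, eps]])
        mm = map_to_pattern_mm(probe, self)
        return float((np.linalg.norm(mm[1] - mm[0]) + np.linalg.norm(mm[2] - mm[0])) / 2)


def _order_corners(points: np.ndarray) -> np.ndarray:
    """Order 4 points TL, TR, BR, BL by angular position about their centroid."""
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    order = np.argsort(ang)  # clockwise in image coords (y down)
    pts = points[order]
    # rotate the cycle so TL (minimal x + y) leads; TL->TR->BR->BL follows
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def detect_board_corners(
    frame: np.ndarray,
    dark_threshold: int = 70,
    min_area_px: int = 20,
    max_area_frac: float = 0.01,
    min_extent: float = 0.45,
    frame_index: int | None = None,
) -> tuple[np.ndarray, float]:
    """Locate the four dark corner fiducials of the board in a colour frame.

    Fiducials are filled dark squares; candidate blobs are dark connected
    components that are compact (high extent = area / bounding-box area),
    which rejects the thin zigzag line even though it is equally dark.  The
    four largest candidates are returned in TL, TR, BR, BL order with a
    confidence score in [0, 1].

    Raises
    ------
    CornerDetectionError
        If fewer than four candidate fiducials are found.
    """
    frame = np.asarray(frame)
    gray = frame.mean(axis=2) if frame.ndim == 3 else frame.astype(float)
    mask = gray < dark_threshold
    lab = label(mask)
    max_area = max_area_frac * gray.size
    cands = [
        p
        for p in regionprops(lab)
        if min_area_px <= p.area <= max_area and p.extent >= min_extent
    ]
    if len(cands) < 4:
        raise CornerDetectionError(
            f"found {len(cands)} corner fiducial candidates, need 4",
            frame_index=frame_index,
        )
    cands.sort(key=lambda p: p.area, reverse=True)
    chosen = cands[:4]
    pts = np.array([(p.centroid[1], p.centroid[0]) for p in chosen])  # (x, y)
    confidence = float(np.clip(np.mean([p.extent for p in chosen]), 0.0, 1.0))
    return _order_corners(pts), confidence


def estimate_rectification(corners_px: np.ndarray, pattern: TargetPattern) -> Rectification:
    """Exact 4-point planar projective solve mapping pixels to pattern mm.

    Raises
    ------
    DegenerateGeometryError
        If any three of the four pixel corners are (near-)collinear.
    """
    corners_px = np.asarray(corners_px, dtype=float)
    if corners_px.shape != (4, 2):
        raise DegenerateGeometryError("need exactly 4 pixel corners")
    # collinearity check on every triple
    for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        a, b, c = corners_px[list(idx)]
        u, v = b - a, c - a
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 < 1e-6 * max(1.0, np.abs(corners_px).max() ** 2):
            raise DegenerateGeometryError("three of the four corners are collinear")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(corners_px, pattern.corners_mm)
        if not tf:  # FailedEstimation is falsy
            raise DegenerateGeometryError("projective solve failed")
    else:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        if not tf.estimate(corners_px, pattern.corners_mm):
            raise DegenerateGeometryError("projective solve failed")
    rect = Rectification(matrix=tf.params, residual_px=0.0, source_corners_px=corners_px)
    # reprojection residual in pixels: mm corners mapped back to pixel space
    back = _apply_homography(pattern.corners_mm, rect.inverse)
    rect.residual_px = float(np.max(np.linalg.norm(back - corners_px, axis=1)))
    return rect


def _apply_homography(points: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.hstack([pts, np.ones((len(pts), 1))]) @ matrix.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise NumericDegeneracyError("point maps to infinity under the homography")
    return hom[:, :2] / w[:, None]


def map_to_pattern_mm(point_px, rectification: Rectification) -> np.ndarray:
    """Map pixel point(s) to pattern mm via the rectification homography."""
    pts = np.asarray(point_px, dtype=float)
    single = pts.ndim == 1
    out = _apply_homography(pts, rectification.matrix)
    return out[0] if single else out


def point_to_centerline_distance(point_mm, pattern: TargetPattern):
    """Minimum Euclidean distance from point(s) to the centerline polyline.

    Distances are to the finite segments, not their infinite supporting
    lines.  Accepts a single (2,) point (returns float) or an (N, 2) array
    (returns (N,) array).
    """
    pts = np.atleast_2d(np.asarray(point_mm, dtype=float))
    a, b = pattern.segments
    ab = b - a  # (S, 2)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    # (N, S) projection parameter, clamped to the segment
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nsj,sj->ns", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - proj, axis=2).min(axis=1)
    return float(d[0]) if np.asarray(point_mm).ndim == 1 else d


def save_pattern_spec(pattern: TargetPattern, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(pattern.to_dict(), sort_keys=False))


def load_pattern_spec(path: str | Path) -> TargetPattern:
    """Rebuild a pattern from its YAML/JSON spec file."""
    spec = yaml.safe_load(Path(path).read_text())
    return build_zigzag_pattern(
        orientation=spec.get("orientation", "horizontal"),
        start_corner=spec.get("start_corner", "TL"),
        n_peaks=int(spec.get("n_peaks", 5)),
        amplitude_mm=spec.get("amplitude_mm"),
        board_size_mm=tuple(spec.get("board_size_mm", A3_LANDSCAPE)),
        path_length_mm=float(spec.get("path_length_mm", 1000.0)),
        line_width_mm=float(spec.get("line_width_mm", 1.0)),
    )


def pattern_to_svg(pattern: TargetPattern) -> str:
    """Printable vector rendering of the target (mm user units)."""
    w, h = pattern.board_size_mm
    pts = " ".join(f"{x:.3f},{y:.3f}" for x, y in pattern.centerline)
    fid = 12.0  # fiducial square side, mm
    squares = "".join(
        f'<rect x="{cx - fid / 2:.1f}" y="{cy - fid / 2:.1f}" width="{fid}" '
        f'height="{fid}" fill="black"/>'
        for cx, cy in pattern.corners_mm
    )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}mm" height="{h}mm" '
        f'viewBox="0 0 {w} {h}">'
        f'<rect width="{w}" height="{h}" fill="white"/>'
        f'<polyline points="{pts}" fill="none" stroke="black" '
        f'stroke-width="{pattern.line_width_mm}"/>'
        f"{squares}</svg>"
    )
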