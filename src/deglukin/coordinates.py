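"""Pixel-to-anatomical coordinate transformation.

The anatomical frame is anchored to the cervical spine: its origin is the
anteroinferior vertex of C4, its +y axis points along C4->C2, and its +x axis
points to the image-left of that axis (anteriorly in a standard lateral view).
The frame is recomputed in every video frame — it moves with the vertebral
bodies, so head motion is factored out of the structure trajectories.

Pixel coordinates (u, v) have v increasing downward; internally they are
v-flipped to (u, -v) so that rotations are ordinary proper rotations.  A global
scale factor s (mm/pixel) comes from a calibration object of known length
(default: a 24.0 mm coin marked as coin_a/coin_b across its diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import PixelPoint, Recording

__all__ = [
    "FramePose",
    "ScaleFactor",
    "AnatomicalPoint",
    "compute_scale_factor",
    "frame_pose",
    "to_anatomical",
    "transform_recording",
]

DEFAULT_REFERENCE_LENGTH_MM = 24.0
DEFAULT_CALIBRATION_FRAMES = 3


@dataclass(frozen=True)
class FramePose:
    """Rigid pose of the anatomical frame in v-flipped image coordinates.

    Columns of R are the unit x' and y axes of the local frame; p is the pixel
    position of the C4 anteroinferior vertex (the origin).
    """

    R: np.ndarray  # 2x2 proper rotation
    p: PixelPoint

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.shape != (2, 2):
            raise ValueError("R must be 2x2")
        if not np.allclose(R.T @ R, np.eye(2), atol=1e-12):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-12):
            raise ValueError("R must be a proper rotation (det +1)")
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class ScaleFactor:
    """mm-per-pixel ratio from the calibration object."""

    s: float
    reference_length_mm: float
    n_frames: int
    frames_used: tuple[int, ...] = ()

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError(f"scale factor must be positive, got {self.s}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class AnatomicalPoint:
    """Point in the anatomical frame, millimetres.

    x: positive toward image-left (anterior); y: positive along C4->C2.
    """

    x: float
    y: float


def compute_scale_factor(
    rec: Recording,
    reference_length_mm: float = DEFAULT_REFERENCE_LENGTH_MM,
    n_frames: int = DEFAULT_CALIBRATION_FRAMES,
) -> ScaleFactor:
    """Calibrate mm/pixel from the first *n_frames* frames with both coin markers.

    s = reference_length_mm / mean pixel distance ||coin_a - coin_b|| over the
    first n_frames qualifying frames (mean of distances, not distance of means).
    """
    if reference_length_mm <= 0:
        raise ValueError("reference_length_mm must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    used: list[int] = []
    dists: list[float] = []
    for ann in rec.frames:
        if "coin_a" in ann.markers and "coin_b" in ann.markers:
            a, b = ann.markers["coin_a"], ann.markers["coin_b"]
            d = float(np.hypot(a.u - b.u, a.v - b.v))
            if d == 0.0:
                raise ValueError(
                    f"degenerate calibration: coin markers coincide in frame {ann.frame}"
                )
            used.append(ann.frame)
            dists.append(d)
            if len(used) == n_frames:
                break
    if len(used) < n_frames:
        raise ValueError(
            f"calibration needs {n_frames} frames with both coin markers, found {len(used)}"
        )
    s = reference_length_mm / float(np.mean(dists))
    return ScaleFactor(
        s=s,
        reference_length_mm=reference_length_mm,
        n_frames=n_frames,
        frames_used=tuple(used),
    )


def frame_pose(c2: PixelPoint, c4: PixelPoint) -> FramePose:
    """Anatomical-frame pose from the C2 and C4 anteroinferior vertices.

    In v-flipped coordinates, e_y points from C4 to C2 and e_x' is 90 degrees
    clockwise from e_y (to the right of the vertical axis).
    """
    dy = np.array([c2.u - c4.u, -(c2.v - c4.v)], dtype=float)
    norm = np.linalg.norm(dy)
    if norm == 0.0:
        raise ValueError("degenerate cervical axis: C2 and C4 coincide")
    e_y = dy / norm
    e_x = np.array([e_y[1], -e_y[0]])
    R = np.column_stack([e_x, e_y])
    return FramePose(R=R, p=c4)


def to_anatomical(q: PixelPoint, pose: FramePose, s: ScaleFactor) -> AnatomicalPoint:
    """Transform a pixel point into the anatomical frame (millimetres).

    With q' = (u_q, -v_q), p' = (u_p, -v_p):
    (x, y) = s * (-[R^T (q' - p')]_x, +[R^T (q' - p')]_y) — y is the scaled
    projection onto the C4->C2 axis, x onto the axis 90 degrees
    counter-clockwise from it (image-left positive).
    """
    qv = np.array([q.u, -q.v], dtype=float)
    pv = np.array([pose.p.u, -pose.p.v], dtype=float)
    local = pose.R.T @ (qv - pv)
    return AnatomicalPoint(x=float(-s.s * local[0]), y=float(s.s * local[1]))


def transform_recording(
    rec: Recording, s: ScaleFactor
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Transform every marker in *rec* into per-frame anatomical coordinates.

    A fresh pose is computed from each frame's C2/C4, so the frame moves with
    the cervical spine.  Returns (times, series) where times[i] = frame_i/fps
    and series maps each marker name present anywhere in the recording to an
    (n, 2) array of (x, y) mm, NaN where the marker is absent.

    Raises if any frame containing analysis markers lacks C2 or C4.
    """
    missing = [
        ann.frame
        for ann in rec.frames
        if any(m not in ("c2", "c4") for m in ann.markers)
        and ("c2" not in ann.markers or "c4" not in ann.markers)
    ]
    if missing:
        raise ValueError(
            f"frames missing c2/c4 but containing analysis markers: {missing}"
        )
    names = sorted({m for ann in rec.frames for m in ann.markers})
    n = len(rec.frames)
    times = np.array([ann.frame / rec.fps for ann in rec.frames])
    series = {name: np.full((n, 2), np.nan) for name in names}
    for i, ann in enumerate(rec.frames):
        if "c2" not in ann.markers or "c4" not in ann.markers:
            continue
        pose = frame_pose(ann.markers["c2"], ann.markers["c4"])
        for name, pt in ann.markers.items():
            ap = to_anatomical(pt, pose, s)
            series[name][i] = (ap.x, ap.y)
    return times, series
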