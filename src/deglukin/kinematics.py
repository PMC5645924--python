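"""Displacement, velocity, tilt-angle and opening-distance kinematics.

Each swallowing structure gets the kinematics appropriate to its motion:

* hyoid, larynx, arytenoid — linear displacement relative to a reference frame,
  split into vertical (along C4->C2), horizontal (anterior-posterior) and
  two-dimensional components, with the matching velocities;
* epiglottis — tilt angle of the base->tip direction, measured both from its
  initial orientation (signed) and from the +y axis (unsigned), plus angular
  velocity;
* upper esophageal sphincter — anterior-posterior opening distance;
* bolus head — planar speed.

Velocities are finite differences of the (smoothed) displacement series:
forward at the first sample, central at interior samples, backward at the
last.  Peaks are greatest-magnitude samples with the earliest-frame tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coordinates import ScaleFactor, transform_recording
from .smoothing import DEFAULT_SPEC, SmoothingSpec, smooth_series
from .trajectory_io import EventLog, Recording

__all__ = [
    "TrajectorySeries",
    "PeakRecord",
    "KinematicSummary",
    "AnalysisResult",
    "finite_difference_velocity",
    "displacement_components",
    "tilt_angle_series",
    "separation_distance_series",
    "peak_summary",
    "transit_time",
    "analyze_recording",
    "LINEAR_STRUCTURES",
]

#: Structures analysed with linear (vertical/horizontal/2D) kinematics.
LINEAR_STRUCTURES = ("hyoid", "larynx", "arytenoid")

VALID_UNITS = ("mm", "degree", "mm/s", "degree/s")


@dataclass
class TrajectorySeries:
    """Uniformly time-sampled scalar or planar series with declared units."""

    t: np.ndarray
    values: np.ndarray
    units: str
    structure: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if len(self.t) != len(self.values):
            raise ValueError("t and values must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - dt[0])) > 1e-9:
                raise ValueError("time base must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else math.nan


@dataclass(frozen=True)
class PeakRecord:
    parameter: str
    value: float
    units: str
    frame: int


@dataclass
class KinematicSummary:
    """Per-structure peak values with the frame index where each peak occurs."""

    peaks: list[PeakRecord] = field(default_factory=list)

    def get(self, parameter: str) -> PeakRecord:
        for rec in self.peaks:
            if rec.parameter == parameter:
                return rec
        raise KeyError(f"no peak record for {parameter!r}")

    def as_rows(self) -> list[tuple[str, float, str, int]]:
        return [(r.parameter, r.value, r.units, r.frame) for r in self.peaks]


@dataclass
class AnalysisResult:
    times: np.ndarray
    series: dict[str, TrajectorySeries]
    summary: KinematicSummary
    superimposed_vertical: dict[str, np.ndarray]
    animation: dict[str, np.ndarray]  # (n, 2) anatomical positions per marker


def finite_difference_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """Velocity by finite differences of the displacement sequence.

    v(t_0) = (x_1 - x_0)/dt, v(t_i) = (x_{i+1} - x_{i-1})/(2 dt) for interior i,
    v(t_n) = (x_n - x_{n-1})/dt.  Exact for affine x everywhere and for
    quadratic x at interior samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.isnan(x).any():
        raise ValueError("interior NAs must be handled upstream (split into runs)")
    v = np.empty_like(x)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    if x.size > 2:
        v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    return v


def _velocity_with_gaps(x: np.ndarray, dt: float) -> np.ndarray:
    """Apply the finite-difference stencil independently on each contiguous
    non-NA run; runs of length 1 stay NA (no velocity estimate)."""
    x = np.asarray(x, dtype=float)
    v = np.full_like(x, np.nan)
    mask = ~np.isnan(x)
    i = 0
    n = x.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i >= 2:
            v[i:j] = finite_difference_velocity(x[i:j], dt)
        i = j
    return v


def _first_valid(values: np.ndarray) -> int:
    mask = ~np.isnan(values if values.ndim == 1 else values[:, 0])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("all-NA trajectory")
    return int(idx[0])


def displacement_components(
    traj: np.ndarray, reference: int | None = None
) -> dict[str, np.ndarray]:
    """Vertical/horizontal/planar displacement of an (n, 2) anatomical series.

    reference: frame *position* (row index) of the zero-displacement sample;
    defaults to the first non-NA row.  vertical = y - y_ref, horizontal =
    x - x_ref, planar magnitude = hypot(vertical, horizontal).
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must be an (n, 2) array")
    ref = _first_valid(traj) if reference is None else int(reference)
    if np.isnan(traj[ref]).any():
        raise ValueError(f"reference row {ref} has no sample")
    horizontal = traj[:, 0] - traj[ref, 0]
    vertical = traj[:, 1] - traj[ref, 1]
    return {
        "vertical": vertical,
        "horizontal": horizontal,
        "planar_magnitude": np.hypot(vertical, horizontal),
    }


def _direction_angles(base: np.ndarray, tip: np.ndarray) -> np.ndarray:
    """Signed angle (degrees) of tip-base from the +y axis, positive toward
    the posterior (-x) direction; NaN where either endpoint is missing."""
    d = np.asarray(tip, dtype=float) - np.asarray(base, dtype=float)
    ang = np.full(d.shape[0], np.nan)
    for i, (dx, dy) in enumerate(d):
        if np.isnan(dx) or np.isnan(dy):
            continue
        if dx == 0.0 and dy == 0.0:
            raise ValueError(f"zero-length orientation vector at row {i}")
        ang[i] = math.degrees(math.atan2(-dx, dy))
    return ang


def tilt_angle_series(
    base: np.ndarray, tip: np.ndarray, mode: str = "from_initial"
) -> np.ndarray:
    """Tilt angle (degrees) of the base->tip orientation per frame.

    ``from_y_axis``: unsigned angle between the orientation and the +y axis,
    in [0, 180].  ``from_initial``: signed angle from the first non-NA
    orientation, positive when the tip rotates from upright toward the
    posterior-inferior direction, wrapped to (-180, 180].
    """
    ang = _direction_angles(base, tip)
    if mode == "from_y_axis":
        return np.abs(ang)
    if mode == "from_initial":
        ref = _first_valid(ang)
        rel = ang - ang[ref]
        # wrap to (-180, 180]
        rel = np.where(np.isnan(rel), rel, ((-rel + 180.0) % 360.0))
        return np.where(np.isnan(rel), rel, -(rel - 180.0))
    raise ValueError(f"mode must be 'from_initial' or 'from_y_axis', got {mode!r}")


def separation_distance_series(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distance between two planar series (mm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the time base")
    return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])


def peak_summary(series: np.ndarray, signed: bool = True) -> tuple[float, int]:
    """Peak of a scalar series: (value, index).

    signed: sample of greatest absolute value, sign preserved.  unsigned
    (magnitude series): the maximum.  Ties broken by the earliest index; NAs
    skipped.
    """
    y = np.asarray(series, dtype=float)
    mask = ~np.isnan(y)
    if not mask.any():
        raise ValueError("all-NA series has no peak")
    key = np.abs(y) if signed else y
    key = np.where(mask, key, -np.inf)
    idx = int(np.argmax(key))  # argmax returns the first maximum
    return float(y[idx]), idx


def transit_time(
    events: EventLog, start_name: str, end_name: str, fps: float
) -> tuple[float, bool]:
    """Elapsed seconds between two recorded events: (frame_end - frame_start)/fps.

    Returns (seconds, reversed_flag); negative values are returned as-is with
    the flag set when the events occur in reverse order.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    start = events.frame_of(start_name)
    end = events.frame_of(end_name)
    dt = (end - start) / fps
    return dt, dt < 0


def _smoothed(vals: np.ndarray, spec: SmoothingSpec, t: np.ndarray) -> np.ndarray:
    return smooth_series(vals, spec, t=t)


def analyze_recording(
    rec: Recording,
    s: ScaleFactor,
    smoothing: SmoothingSpec | dict[str, SmoothingSpec] | None = None,
    structures: list[str] | None = None,
    motion_start_event: str | None = None,
) -> AnalysisResult:
    """Full per-structure kinematic analysis of a recording.

    Pipeline per structure: transform to the moving anatomical frame, smooth
    the component series, derive displacement/angle/distance series, finite-
    difference velocities, and peak extraction.  *smoothing* is a single
    :class:`SmoothingSpec` for all structures or a per-structure mapping (key
    ``"default"`` for the fallback).  *motion_start_event*, if recorded in the
    event log, sets the zero-displacement reference frame; otherwise the first
    non-NA frame is used.
    """
    times, anat = transform_recording(rec, s)
    dt = 1.0 / rec.fps

    def spec_for(structure: str) -> SmoothingSpec:
        if smoothing is None:
            return DEFAULT_SPEC
        if isinstance(smoothing, SmoothingSpec):
            return smoothing
        return smoothing.get(structure, smoothing.get("default", DEFAULT_SPEC))

    frame_index = np.array(rec.frame_indices)

    def ref_row() -> int | None:
        if motion_start_event and motion_start_event in rec.events.entries:
            fr = rec.events.frame_of(motion_start_event)
            rows = np.flatnonzero(frame_index == fr)
            if rows.size:
                return int(rows[0])
        return None

    available = set(anat)
    if structures is None:
        structures = [st for st in LINEAR_STRUCTURES if st in available]
        if {"epiglottis_base", "epiglottis_tip"} <= available:
            structures.append("epiglottis")
        if {"ues_anterior", "ues_posterior"} <= available:
            structures.append("ues")
        if "bolus_head" in available:
            structures.append("bolus")

    series: dict[str, TrajectorySeries] = {}
    peaks: list[PeakRecord] = []
    superimposed: dict[str, np.ndarray] = {}

    def add_series(name: str, vals: np.ndarray, units: str, structure: str):
        series[name] = TrajectorySeries(t=times, values=vals, units=units, structure=structure)

    def add_peak(param: str, vals: np.ndarray, units: str, signed: bool = True):
        value, idx = peak_summary(vals, signed=signed)
        peaks.append(PeakRecord(param, value, units, int(frame_index[idx])))

    def smooth_planar(name: str, spec: SmoothingSpec) -> np.ndarray:
        raw = anat[name]
        out = np.column_stack(
            [_smoothed(raw[:, 0], spec, times), _smoothed(raw[:, 1], spec, times)]
        )
        return out

    for structure in structures:
        spec = spec_for(structure)
        try:
            if structure in LINEAR_STRUCTURES:
                if structure not in available:
                    raise ValueError(f"marker {structure!r} absent from recording")
                traj = smooth_planar(structure, spec)
                comps = displacement_components(traj, reference=ref_row())
                for comp, abbr in (("vertical", "vert"), ("horizontal", "horiz")):
                    disp = comps[comp]
                    vel = _velocity_with_gaps(disp, dt)
                    add_series(f"{structure}_disp_{abbr}_mm", disp, "mm", structure)
                    add_series(f"{structure}_vel_{abbr}_mmps", vel, "mm/s", structure)
                    add_peak(f"{structure} maximal displacement ({comp})", disp, "mm")
                    add_peak(f"{structure} maximal velocity ({comp})", vel, "mm/s")
                disp2d = comps["planar_magnitude"]
                vx = _velocity_with_gaps(comps["horizontal"], dt)
                vy = _velocity_with_gaps(comps["vertical"], dt)
                vel2d = np.hypot(vx, vy)
                add_series(f"{structure}_disp_2d_mm", disp2d, "mm", structure)
                add_series(f"{structure}_vel_2d_mmps", vel2d, "mm/s", structure)
                add_peak(f"{structure} maximal displacement (two dimensional)",
                         disp2d, "mm", signed=False)
                add_peak(f"{structure} maximal velocity (two dimensional)",
                         vel2d, "mm/s", signed=False)
                superimposed[structure] = comps["vertical"]
            elif structure == "epiglottis":
                base = smooth_planar("epiglottis_base", spec)
                tip = smooth_planar("epiglottis_tip", spec)
                ang_init = tilt_angle_series(base, tip, mode="from_initial")
                ang_y = tilt_angle_series(base, tip, mode="from_y_axis")
                angvel = _velocity_with_gaps(ang_init, dt)
                add_series("epiglottis_tilt_from_initial_deg", ang_init, "degree", structure)
                add_series("epiglottis_tilt_from_y_axis_deg", ang_y, "degree", structure)
                add_series("epiglottis_angvel_degps", angvel, "degree/s", structure)
                add_peak("epiglottis maximal tilt angle (from the initial position)",
                         ang_init, "degree")
                add_peak("epiglottis maximal tilt angle (from the y axis)",
                         ang_y, "degree", signed=False)
                add_peak("epiglottis maximal angular velocity", angvel, "degree/s")
            elif structure == "ues":
                a = smooth_planar("ues_anterior", spec)
                b = smooth_planar("ues_posterior", spec)
                dist = separation_distance_series(a, b)
                add_series("ues_opening_mm", dist, "mm", structure)
                add_peak("upper esophageal sphincter opening distance", dist,
                         "mm", signed=False)
            elif structure == "bolus":
                traj = smooth_planar("bolus_head", spec)
                vx = _velocity_with_gaps(traj[:, 0], dt)
                vy = _velocity_with_gaps(traj[:, 1], dt)
                speed = np.hypot(vx, vy)
                add_series("bolus_speed_mmps", speed, "mm/s", structure)
                add_peak("liquid bolus maximal velocity", speed, "mm/s", signed=False)
                superimposed[structure] = traj[:, 1] - traj[_first_valid(traj), 1]
            else:
                raise ValueError(f"unknown structure {structure!r}")
        except ValueError as exc:
            raise ValueError(f"structure {structure!r}: {exc}") from exc

    animation = {name: anat[name] for name in sorted(available) if name not in ("coin_a", "coin_b")}
    return AnalysisResult(
        times=times,
        series=series,
        summary=KinematicSummary(peaks=peaks),
        superimposed_vertical=superimposed,
        animation=animation,
    )
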