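"""Marker/event data model and the plain-text file formats.

A recording is a sequence of per-frame landmark annotations digitised from a
lateral videofluoroscopic swallowing study (or from the phantom simulator).
Marker tables are UTF-8 comma-separated files with header ``frame,marker,u,v``;
comment lines start with ``#`` and an optional ``# fps=<float>`` comment carries
the frame rate.  Event logs are two-column ``event,frame`` files.  Frame indices
are 0-based throughout.

Pixel coordinates follow image conventions: ``u`` increases rightward, ``v``
increases downward.  Fractional (sub-pixel) coordinates are allowed.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MARKER_NAMES",
    "DEFAULT_EVENT_CATALOGUE",
    "NA_TOKEN",
    "PixelPoint",
    "FrameAnnotation",
    "EventLog",
    "Recording",
    "RecordingParseError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "export_analysis_table",
]

#: Closed, case-sensitive set of marker tokens.  Two-point structures (coin,
#: epiglottis, UES) are represented as marker pairs so that lengths, opening
#: distances and orientations can be computed.
MARKER_NAMES: tuple[str, ...] = (
    "coin_a",
    "coin_b",
    "c2",
    "c4",
    "hyoid",
    "mandible",
    "maxilla",
    "larynx",
    "arytenoid",
    "epiglottis_base",
    "epiglottis_tip",
    "ues_anterior",
    "ues_posterior",
    "bolus_head",
)

#: Default 20-name event catalogue.  The first two are the swallow onset/offset
#: events used to compute the pharyngeal transit time; the remainder are
#: editable placeholders.
DEFAULT_EVENT_CATALOGUE: tuple[str, ...] = (
    "bolus cross the mandible angle",
    "bolus tail cross the UES",
) + tuple(f"event_{i:02d}" for i in range(3, 21))

NA_TOKEN = "NA"


class RecordingParseError(ValueError):
    """Raised on malformed marker/event files; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class PixelPoint:
    """Sub-pixel image location; u rightward, v downward."""

    u: float
    v: float

    def __post_init__(self):
        if not (math.isfinite(self.u) and math.isfinite(self.v)):
            raise ValueError(f"pixel coordinates must be finite, got ({self.u}, {self.v})")


@dataclass
class FrameAnnotation:
    """All marker positions digitised in one video frame."""

    frame: int
    markers: dict[str, PixelPoint] = field(default_factory=dict)

    def __post_init__(self):
        if self.frame < 0:
            raise ValueError(f"frame index must be non-negative, got {self.frame}")
        for name in self.markers:
            if name not in MARKER_NAMES:
                raise ValueError(f"unknown marker token {name!r}")


@dataclass
class EventLog:
    """Named swallow events, one frame index per event name."""

    entries: dict[str, int] = field(default_factory=dict)
    catalogue: tuple[str, ...] = DEFAULT_EVENT_CATALOGUE

    def __post_init__(self):
        for name in self.entries:
            if name not in self.catalogue:
                raise ValueError(
                    f"unknown event name {name!r}; catalogue: {list(self.catalogue)}"
                )

    def frame_of(self, name: str) -> int:
        if name not in self.entries:
            raise KeyError(f"event {name!r} not recorded")
        return self.entries[name]


@dataclass
class Recording:
    """A digitised recording: frame annotations, frame rate, events, metadata."""

    fps: float
    frames: list[FrameAnnotation]
    events: EventLog = field(default_factory=EventLog)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        idx = [f.frame for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if idx:
            lo, hi = idx[0], idx[-1]
            for name, fr in self.events.entries.items():
                if not (lo <= fr <= hi):
                    raise ValueError(
                        f"event {name!r} at frame {fr} outside recording range [{lo}, {hi}]"
                    )

    @property
    def frame_indices(self) -> list[int]:
        return [f.frame for f in self.frames]

    def marker_frames(self, name: str) -> list[int]:
        """Frame indices where *name* was marked."""
        return [f.frame for f in self.frames if name in f.markers]


def _fmt(x: float) -> str:
    """repr of a Python float round-trips at full precision."""
    return repr(float(x))


def read_recording(path: str | Path, fps: float | None = None) -> Recording:
    """Read a marker table CSV (``frame,marker,u,v``) into a :class:`Recording`.

    ``fps`` overrides any ``# fps=`` header comment; one of the two must be
    present.  Rows may appear in any order; they are grouped by frame and
    sorted.  Duplicate (frame, marker) pairs and unknown marker tokens are
    rejected with the offending line number.
    """
    path = Path(path)
    header_fps: float | None = None
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, str, float, float]] = []  # (lineno, frame, marker, u, v)
    with open(path, newline="", encoding="utf-8") as fh:
        saw_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "fps":
                        try:
                            header_fps = float(val)
                        except ValueError:
                            raise RecordingParseError(f"bad fps value {val!r}", lineno)
                    else:
                        meta[key] = val
                continue
            parts = next(csv.reader(io.StringIO(line)))
            if not saw_header:
                expected = ["frame", "marker", "u", "v"]
                if [p.strip() for p in parts] != expected:
                    raise RecordingParseError(
                        f"header must be {','.join(expected)!r}, got {line!r}", lineno
                    )
                saw_header = True
                continue
            if len(parts) != 4:
                raise RecordingParseError(f"expected 4 fields, got {len(parts)}", lineno)
            f_s, marker, u_s, v_s = (p.strip() for p in parts)
            try:
                frame = int(f_s)
            except ValueError:
                raise RecordingParseError(f"bad frame index {f_s!r}", lineno)
            if frame < 0:
                raise RecordingParseError(f"negative frame index {frame}", lineno)
            if marker not in MARKER_NAMES:
                raise RecordingParseError(f"unknown marker token {marker!r}", lineno)
            try:
                u, v = float(u_s), float(v_s)
            except ValueError:
                raise RecordingParseError(f"bad coordinates ({u_s!r}, {v_s!r})", lineno)
            rows.append((lineno, frame, marker, u, v))
    if not saw_header:
        raise RecordingParseError("no header row found")
    if not rows:
        raise RecordingParseError("no frames: data section is empty")

    by_frame: dict[int, dict[str, PixelPoint]] = {}
    seen: dict[tuple[int, str], int] = {}
    for lineno, frame, marker, u, v in rows:
        key = (frame, marker)
        if key in seen:
            raise RecordingParseError(
                f"duplicate marker {marker!r} for frame {frame} (first at line {seen[key]})",
                lineno,
            )
        seen[key] = lineno
        by_frame.setdefault(frame, {})[marker] = PixelPoint(u, v)

    eff_fps = fps if fps is not None else header_fps
    if eff_fps is None:
        raise RecordingParseError("no fps given (argument or '# fps=' header comment)")
    frames = [FrameAnnotation(i, by_frame[i]) for i in sorted(by_frame)]
    return Recording(fps=eff_fps, frames=frames, meta=meta)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write *rec* back to the marker-table schema; round-trips exactly."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# fps={_fmt(rec.fps)}\n")
        for key, val in rec.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("frame,marker,u,v\n")
        for ann in rec.frames:
            for name in MARKER_NAMES:  # stable marker order within a frame
                if name in ann.markers:
                    pt = ann.markers[name]
                    fh.write(f"{ann.frame},{name},{_fmt(pt.u)},{_fmt(pt.v)}\n")


def read_events(
    path: str | Path, catalogue: Iterable[str] = DEFAULT_EVENT_CATALOGUE
) -> EventLog:
    """Read an ``event,frame`` CSV into an :class:`EventLog`.

    Names are validated against *catalogue*; an unknown name raises an error
    listing the catalogue.  An empty file yields an empty log.
    """
    catalogue = tuple(catalogue)
    entries: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = next(csv.reader(io.StringIO(line)))
            if [p.strip() for p in parts] == ["event", "frame"]:
                continue  # optional header
            if len(parts) != 2:
                raise RecordingParseError(f"expected 2 fields, got {len(parts)}", lineno)
            name, f_s = parts[0].strip(), parts[1].strip()
            if name not in catalogue:
                raise RecordingParseError(
                    f"unknown event name {name!r}; catalogue: {list(catalogue)}", lineno
                )
            if name in entries:
                raise RecordingParseError(f"duplicate event name {name!r}", lineno)
            try:
                entries[name] = int(f_s)
            except ValueError:
                raise RecordingParseError(f"bad frame index {f_s!r}", lineno)
    return EventLog(entries=entries, catalogue=catalogue)


def write_events(log: EventLog, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("event,frame\n")
        writer = csv.writer(fh, lineterminator="\n")
        for name, frame in log.entries.items():
            writer.writerow([name, frame])


def export_analysis_table(
    times: Iterable[float],
    columns: Mapping[str, Iterable[float]],
    summary: Iterable[tuple[str, float, str, int]],
    path: str | Path,
    meta: Mapping[str, str] | None = None,
) -> None:
    """Export per-frame series plus a peak-summary block as a TSV file.

    *columns* maps unit-annotated column names (``hyoid_disp_vert_mm``) to
    per-frame values sharing the recording time base; NaNs render as ``NA``.
    *summary* rows are ``(parameter, peak value, units, frame index)``.
    """
    import numpy as np

    times = list(times)
    cols = {name: list(vals) for name, vals in columns.items()}
    for name, vals in cols.items():
        if len(vals) != len(times):
            raise ValueError(
                f"column {name!r} has {len(vals)} rows, time base has {len(times)}"
            )

    def cell(x: float) -> str:
        return NA_TOKEN if x is None or (isinstance(x, float) and np.isnan(x)) else repr(float(x))

    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        names = list(cols)
        fh.write("\t".join(["time_s"] + names) + "\n")
        for i, t in enumerate(times):
            fh.write("\t".join([repr(float(t))] + [cell(cols[n][i]) for n in names]) + "\n")
        fh.write("# summary\n")
        fh.write("# parameter\tpeak_value\tunits\tframe\n")
        for param, value, units, frame in summary:
            fh.write(f"# {param}\t{cell(value)}\t{units}\t{frame}\n")
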