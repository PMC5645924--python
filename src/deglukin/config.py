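"""Flat dotted-key configuration shared by the CLI subcommands.

Config files are plain text, one ``key = value`` per line, ``#`` comments.
Keys mirror the analysis knobs: ``calibration.reference_length_mm``,
``calibration.n_frames``, ``smoothing.method``, ``smoothing.span``,
``smoothing.degree`` (plus per-structure overrides such as
``smoothing.hyoid.method``), ``fps``, ``events.catalogue`` (comma-separated),
``analysis.motion_start_event`` and ``analysis.structures``.  CLI flags
override file values; the effective config is echoed into output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .coordinates import DEFAULT_CALIBRATION_FRAMES, DEFAULT_REFERENCE_LENGTH_MM
from .smoothing import SmoothingSpec
from .trajectory_io import DEFAULT_EVENT_CATALOGUE

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    reference_length_mm: float = DEFAULT_REFERENCE_LENGTH_MM
    calibration_n_frames: int = DEFAULT_CALIBRATION_FRAMES
    smoothing_method: str = "moving_average"
    smoothing_span: float = 5
    smoothing_degree: int = 2
    per_structure_smoothing: dict[str, dict[str, str]] = field(default_factory=dict)
    fps: float | None = None
    event_catalogue: tuple[str, ...] = DEFAULT_EVENT_CATALOGUE
    structures: list[str] | None = None
    motion_start_event: str | None = None
    seed: int = 0
    raw: dict[str, str] = field(default_factory=dict)

    def smoothing_spec(self, structure: str | None = None) -> SmoothingSpec:
        method, span, degree = self.smoothing_method, self.smoothing_span, self.smoothing_degree
        if structure and structure in self.per_structure_smoothing:
            over = self.per_structure_smoothing[structure]
            method = over.get("method", method)
            span = float(over.get("span", span))
            degree = int(over.get("degree", degree))
        return SmoothingSpec(method=method, span=span, degree=degree)

    def smoothing_map(self) -> dict[str, SmoothingSpec]:
        out = {"default": self.smoothing_spec()}
        for structure in self.per_structure_smoothing:
            out[structure] = self.smoothing_spec(structure)
        return out

    def as_meta(self) -> dict[str, str]:
        meta = {
            "calibration.reference_length_mm": repr(self.reference_length_mm),
            "calibration.n_frames": str(self.calibration_n_frames),
            "smoothing.method": self.smoothing_method,
            "smoothing.span": repr(self.smoothing_span),
            "smoothing.degree": str(self.smoothing_degree),
        }
        if self.fps is not None:
            meta["fps"] = repr(self.fps)
        if self.motion_start_event:
            meta["analysis.motion_start_event"] = self.motion_start_event
        return meta


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a flat key=value config file into a :class:`RunConfig`."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    cfg.raw = raw
    if "calibration.reference_length_mm" in raw:
        cfg.reference_length_mm = float(raw["calibration.reference_length_mm"])
    if "calibration.n_frames" in raw:
        cfg.calibration_n_frames = int(raw["calibration.n_frames"])
    if "smoothing.method" in raw:
        cfg.smoothing_method = raw["smoothing.method"]
    if "smoothing.span" in raw:
        cfg.smoothing_span = float(raw["smoothing.span"])
    if "smoothing.degree" in raw:
        cfg.smoothing_degree = int(raw["smoothing.degree"])
    if "fps" in raw:
        cfg.fps = float(raw["fps"])
    if "events.catalogue" in raw:
        names = tuple(n.strip() for n in raw["events.catalogue"].split(",") if n.strip())
        if names:
            cfg.event_catalogue = names
    if "analysis.structures" in raw:
        cfg.structures = [s.strip() for s in raw["analysis.structures"].split(",") if s.strip()]
    if "analysis.motion_start_event" in raw:
        cfg.motion_start_event = raw["analysis.motion_start_event"]
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    # per-structure smoothing overrides: smoothing.<structure>.<param>
    for key, val in raw.items():
        parts = key.split(".")
        if len(parts) == 3 and parts[0] == "smoothing" and parts[2] in ("method", "span", "degree"):
            cfg.per_structure_smoothing.setdefault(parts[1], {})[parts[2]] = val
    return cfg
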