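"""Core data containers shared across the pipeline.

All times are seconds from session start; all bins are half-open
``[b, b + width)``. Cell ids are opaque strings that are stable across
sessions (cross-session identity is assumed given, e.g. from concatenated
registration before segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceMatrix:
    """Fluorescence traces for one field of view (FOV).

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_frames)
        Fluorescence in arbitrary (or z-scored) units.
    fps : float
        Sampling rate in frames per second.
    cell_ids : list of str
        One opaque id per row.
    session : str
        Session label (e.g. ``"A1"``).
    """

    values: np.ndarray
    fps: float
    cell_ids: list[str]
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x frames)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match number of rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Session duration in seconds implied by the frame count."""
        return self.n_frames / self.fps

    def frame_times(self) -> np.ndarray:
        """Time of each frame centre, in seconds."""
        return (np.arange(self.n_frames) + 0.5) / self.fps


@dataclass
class EventTrain:
    """Detected (or simulated) Ca2+ transient peaks for one cell.

    ``times`` are peak times in seconds, sorted ascending; ``amplitudes``
    are peak heights in noise-s.d. (z) units.
    """

    cell_id: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.amplitudes = self.amplitudes[order]

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class SessionTimeline:
    """Labelled windows over one session of known duration.

    Windows are ``(start, end)`` tuples in seconds, half-open, and must lie
    inside ``[0, duration]``.
    """

    label: str
    duration: float
    shock_window: tuple[float, float] | None = None
    tone_windows: list[tuple[float, float]] = field(default_factory=list)
    opto_epochs: list[tuple[float, float]] = field(default_factory=list)
    freezing_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name, windows in (
            ("shock_window", [self.shock_window] if self.shock_window else []),
            ("tone_windows", self.tone_windows),
            ("opto_epochs", self.opto_epochs),
            ("freezing_intervals", self.freezing_intervals),
        ):
            for start, end in windows:
                if not (0 <= start < end <= self.duration):
                    raise ValueError(
                        f"{name} ({start}, {end}) outside [0, {self.duration}]"
                    )

    def merged_freezing(self) -> list[tuple[float, float]]:
        """Freezing intervals sorted and merged so they never overlap."""
        if not self.freezing_intervals:
            return []
        ivs = sorted(self.freezing_intervals)
        merged = [list(ivs[0])]
        for start, end in ivs[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return [(s, e) for s, e in merged]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "duration": self.duration,
            "shock_window": list(self.shock_window) if self.shock_window else None,
            "tone_windows": [list(w) for w in self.tone_windows],
            "opto_epochs": [list(w) for w in self.opto_epochs],
            "freezing_intervals": [list(w) for w in self.freezing_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionTimeline":
        return cls(
            label=d["label"],
            duration=float(d["duration"]),
            shock_window=tuple(d["shock_window"]) if d.get("shock_window") else None,
            tone_windows=[tuple(w) for w in d.get("tone_windows", [])],
            opto_epochs=[tuple(w) for w in d.get("opto_epochs", [])],
            freezing_intervals=[tuple(w) for w in d.get("freezing_intervals", [])],
        )


@dataclass
class BinnedRaster:
    """Binary cells x bins event raster at a fixed bin width (default 1 s)."""

    values: np.ndarray
    cell_ids: list[str]
    bin_width: float = 1.0
    session: str = ""
    bin_mask: np.ndarray | None = None  # mask already applied; kept for record

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match raster rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]
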