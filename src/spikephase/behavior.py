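"""Scoring of behavioral endpoints from event-level logs.

Three endpoints, each a direct arithmetic rule:

* prepulse inhibition (PPI) of the acoustic startle response,
  ``100 - mean(prepulse-trial startle) / mean(startle-only startle) * 100``;
* radial-arm-maze working memory, where every entry into an
  already-visited arm is one error;
* open-field jump time, the total duration of time bins with Z-axis
  beam breaks and no X/Y breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StartleSession",
    "MazeSession",
    "BeamBreakLog",
    "ppi_percent",
    "working_memory_errors",
    "maze_summary",
    "jump_time",
]

STARTLE_ONLY = "startle_only"


@dataclass
class StartleSession:
    """Per-trial startle amplitudes.  ``trial_type`` is ``startle_only``
    or a prepulse label such as ``prepulse_70`` / ``prepulse_74`` /
    ``prepulse_82`` (dB)."""

    trial_types: list
    amplitudes: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.trial_types) != self.amplitudes.size:
            raise ValueError("trial_types and amplitudes differ in length")
        if np.any(self.amplitudes < 0):
            raise ValueError("startle amplitudes must be >= 0")
        if STARTLE_ONLY not in self.trial_types:
            raise ValueError("a session needs >= 1 startle-only trial")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StartleSession":
        return cls(df["trial_type"].tolist(), df["amplitude"].to_numpy())

    def mean_amplitude(self, trial_type: str) -> float:
        amps = self.amplitudes[
            np.array([t == trial_type for t in self.trial_types])
        ]
        if amps.size == 0:
            raise ValueError(f"no trials of type {trial_type!r}")
        return float(np.mean(amps))


def ppi_percent(session: StartleSession, prepulse_level: str) -> float:
    """Percent prepulse inhibition for one prepulse intensity.

    PPI = 100 - (mean startle on prepulse trials /
    mean startle on startle-only trials) * 100.  Negative values
    (facilitation) are allowed; the value is undefined (ValueError) when
    the startle-only mean is zero.
    """
    startle = session.mean_amplitude(STARTLE_ONLY)
    prepulse = session.mean_amplitude(prepulse_level)
    if startle == 0:
        raise ValueError("startle-only mean is zero: PPI undefined")
    return 100.0 - prepulse / startle * 100.0


@dataclass
class MazeSession:
    """Ordered arm entries in an 8-arm radial maze.

    ``doors_open`` is the session start (same time units as the entry
    timestamps); ``session_cap`` the cut-off applied when the animal
    never visits all arms.
    """

    arms: list
    timestamps: np.ndarray
    doors_open: float = 0.0
    session_cap: float | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.arms) != self.timestamps.size:
            raise ValueError("arms and timestamps differ in length")
        if any(a not in range(1, 9) for a in self.arms):
            raise ValueError("arm ids must be in 1..8")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def debounced(self) -> tuple[list, np.ndarray]:
        """Collapse consecutive identical arm ids (sensor re-triggers
        within one visit are not separate entries)."""
        arms, times = [], []
        for a, t in zip(self.arms, self.timestamps):
            if not arms or a != arms[-1]:
                arms.append(a)
                times.append(t)
        return arms, np.asarray(times)


def working_memory_errors(session: MazeSession,
                          debounce: bool = True) -> tuple[int, float]:
    """(error count, completion time) for one maze session.

    Every entry into an already-visited arm is one error, so
    errors = entries - distinct arms visited.  With ``debounce`` (the
    default) consecutive identical arm ids are first collapsed — sensor
    re-triggers within one visit are not separate entries; with
    ``debounce=False`` every logged repeat counts as a re-entry.
    Completion time is the timestamp of the last first-visit minus the
    doors-open time; when not all 8 arms were visited it is the session
    cap (NaN if no cap).
    """
    if debounce:
        arms, times = session.debounced()
    else:
        arms, times = list(session.arms), session.timestamps
    if not arms:
        return 0, np.nan
    seen: set = set()
    errors = 0
    t_complete = np.nan
    for a, t in zip(arms, times):
        if a in seen:
            errors += 1
        else:
            seen.add(a)
            if len(seen) == 8:
                t_complete = t - session.doors_open
    if np.isnan(t_complete) and session.session_cap is not None:
        t_complete = session.session_cap - session.doors_open
    return errors, float(t_complete)


def maze_summary(sessions: list) -> pd.DataFrame:
    """Per-day errors/completion plus the multi-day average error count
    (one session per day, in day order)."""
    rows = []
    for day, s in enumerate(sessions, start=1):
        errs, t = working_memory_errors(s)
        rows.append({"day": day, "errors": errs, "completion_time": t})
    df = pd.DataFrame(rows)
    df.attrs["average_daily_errors"] = float(df["errors"].mean())
    return df


@dataclass
class BeamBreakLog:
    """Timestamped infrared beam-break events tagged by axis (X, Y, Z)."""

    timestamps: np.ndarray = field(default_factory=lambda: np.array([]))
    axes: list = field(default_factory=list)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size != len(self.axes):
            raise ValueError("timestamps and axes differ in length")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        bad = set(self.axes) - {"X", "Y", "Z"}
        if bad:
            raise ValueError(f"unknown axis tags {sorted(bad)}")


def jump_time(log: BeamBreakLog, bin_ms: float = 100.0) -> float:
    """Total jump duration in seconds.

    The event stream is binned at ``bin_ms``; a bin counts as jumping
    when it contains >= 1 Z-axis break and no X- or Y-axis break (the
    animal is airborne).  Returns bins * bin width.
    """
    if log.timestamps.size == 0:
        return 0.0
    n_bins = int(np.floor(log.timestamps.max() / bin_ms)) + 1
    z = np.zeros(n_bins, dtype=bool)
    xy = np.zeros(n_bins, dtype=bool)
    idx = np.minimum((log.timestamps // bin_ms).astype(int), n_bins - 1)
    for i, ax in zip(idx, log.axes):
        if ax == "Z":
            z[i] = True
        else:
            xy[i] = True
    return float(np.sum(z & ~xy) * bin_ms / 1000.0)
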