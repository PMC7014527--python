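"""Recording/annotation I/O and the shared time conventions.

All times inside the package are seconds relative to the recording start.
Sample index ``i`` maps to time ``i / fs``; conversions are exact for integer
sample counts.  Intervals are half-open ``[start, end)`` so that overlap sums
are additive without double counting boundary samples.

CSV is the canonical interchange format: recordings are one column per channel
(optional leading time column), annotations are ``start_s,end_s`` tables.
EDF is supported read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Malformed input file (ragged columns, undecodable content)."""


class ConfigError(ValueError):
    """Missing or inconsistent configuration (e.g. no sampling rate)."""


class ValidationError(ValueError):
    """Domain-invariant violation (negative times, overlapping events, ...)."""


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start <= self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start <= end"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlap(self, other: "Interval") -> float:
        """Positive overlap duration with ``other`` (0 if disjoint)."""
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class EMGRecording:
    """Multi-channel raw EMG samples with sampling rate and channel labels.

    ``samples`` has shape ``(n_channels, n_samples)`` in arbitrary amplitude
    units.  ``t0`` is the recording start time in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if samples.ndim != 2 or samples.shape[0] < 1:
            raise ValidationError("samples must be (n_channels, n_samples)")
        if len(self.channel_ids) != samples.shape[0]:
            raise ValidationError("one channel_id per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _check_sorted_disjoint(events: Sequence[Interval], what: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.start < a.start:
            raise ValidationError(f"{what} must be sorted by start time")
        if b.start < a.end:
            raise ValidationError(
                f"{what} must be non-overlapping: "
                f"[{a.start},{a.end}) overlaps [{b.start},{b.end})"
            )


@dataclass(frozen=True)
class EventReference:
    """Labelled eating-event intervals serving as ground truth."""

    events: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        _check_sorted_disjoint(self.events, "reference events")

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def starts(self) -> np.ndarray:
        return np.array([e.start for e in self.events], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([e.end for e in self.events], dtype=float)

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.events))


@dataclass(frozen=True)
class SegmentList:
    """Ordered, non-overlapping time intervals from one detection source."""

    segments: tuple[Interval, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        _check_sorted_disjoint(self.segments, f"segments of {self.source_id!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


def intervals_from_arrays(
    starts: Iterable[float], ends: Iterable[float]
) -> tuple[Interval, ...]:
    return tuple(Interval(float(s), float(e)) for s, e in zip(starts, ends))


# ---------------------------------------------------------------------------
# readers / writers


def _read_recording_csv(
    path: str, fs: float | None, channel_ids: Sequence[str] | None
) -> EMGRecording:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse recording CSV {path}: {exc}") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise FormatError(f"recording CSV {path} is empty")

    time_col = None
    for cand in ("t", "time", "time_s"):
        if cand in frame.columns:
            time_col = cand
            break
    if time_col is not None:
        t = frame.pop(time_col).to_numpy(dtype=float)
        if fs is None and len(t) > 1:
            steps = np.diff(t)
            fs = 1.0 / float(np.median(steps))
    if frame.shape[1] < 1:
        raise FormatError(f"recording CSV {path} has no channel columns")
    if frame.isna().any().any():
        raise FormatError(
            f"recording CSV {path} has unequal channel lengths (missing values)"
        )
    if fs is None:
        raise ConfigError(
            "sampling rate not given and not derivable from the CSV; pass fs="
        )
    ids = tuple(channel_ids) if channel_ids else tuple(str(c) for c in frame.columns)
    return EMGRecording(frame.to_numpy(dtype=float).T, float(fs), ids)


def _read_recording_edf(path: str) -> EMGRecording:
    import mne  # heavy import, only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    return EMGRecording(np.asarray(data, dtype=float), fs, tuple(raw.ch_names))


def read_recording(
    path: str,
    format: str | None = None,
    fs: float | None = None,
    channel_ids: Sequence[str] | None = None,
) -> EMGRecording:
    """Read a multi-channel recording from CSV or EDF.

    For CSV the sampling rate comes from ``fs`` (or a time column); for EDF it
    comes from the file header, as do the channel labels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "csv"
    if format == "csv":
        return _read_recording_csv(path, fs, channel_ids)
    if format == "edf":
        return _read_recording_edf(path)
    raise ConfigError(f"unknown recording format {format!r}")


def read_annotations(path: str) -> EventReference:
    """Read a ``start_s,end_s`` annotation CSV into a sorted EventReference."""
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        return EventReference(())
    for col in ("start_s", "end_s"):
        if col not in frame.columns:
            raise FormatError(f"annotation CSV {path} lacks column {col!r}")
    frame = frame.sort_values("start_s", kind="stable")
    events = intervals_from_arrays(frame["start_s"], frame["end_s"])
    return EventReference(events)


def write_events(events: Sequence[Interval], path: str) -> None:
    """Write intervals as a ``start_s,end_s`` CSV (microsecond precision)."""
    events = tuple(events)  # validates via Interval construction upstream
    frame = pd.DataFrame(
        {
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")


#: Fixed pipeline defaults; grid-searched parameters (w0, theta_0, w1, theta_1,
#: w2, gamma, nu) intentionally have no defaults here.
DEFAULT_CONFIG: dict = {
    "fs": 256.0,
    "fnf": 50.0,
    "fhpf": 20.0,
    "w": 100,
    "theta_P": 0.7,
    "t_interval": 1.0 / 3.0,
    "s1": 256,
    "t_gap": 300.0,
}


def load_config(path: str) -> dict:
    """Load a YAML parameter file, layered over :data:`DEFAULT_CONFIG`."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"config {path} must be a mapping")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg
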