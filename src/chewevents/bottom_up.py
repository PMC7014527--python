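"""Bottom-up eating-event detection: onset density -> segments -> events.

Eating shows up as a sustained run of chewing-cycle onsets at 0.94-2.17 Hz.
The detector slides a window of ``w0`` seconds from onset to onset and counts
the onsets it contains (the local chewing-cycle frequency ``f``).  A chewing
segment starts at the first onset whose count reaches ``theta_0`` and ends at
the onset ``C[j_end + theta_0 - 1]`` where ``f[j_end] == theta_0`` and
``f[j_end + theta_0 - 1] == 1`` — i.e. the closing onset is alone in its own
window, marking the tail of the run.  Source-specific segment lists are fused
by point-set union, and gaps shorter than ``t_gap`` (within-meal interrupts
such as conversations) are eliminated, yielding eating events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cycles import CycleDetectParams, OnsetList, detect_chewing_cycles
from .preprocessing import PreprocessParams, preprocess
from .signal_io import EMGRecording, Interval, SegmentList, ValidationError


@dataclass(frozen=True)
class SegmentParams:
    """Onset-density segmentation parameters.

    w0 : counting window length in seconds (grid-searched)
    theta_0 : minimum onset count per window, integer >= 2 (grid-searched)
    t_gap : merge threshold in seconds (default 300 s = 5 min)
    """

    w0: float
    theta_0: int
    t_gap: float = 300.0

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValidationError("w0 must be positive")
        if self.theta_0 < 2:
            raise ValidationError("theta_0 must be an integer >= 2")
        if self.t_gap < 0:
            raise ValidationError("t_gap must be non-negative")


def _window_counts(onsets: np.ndarray, w0_samples: int) -> np.ndarray:
    """Onset count in the closed window [C[j], C[j] + w0] for every j."""
    right = np.searchsorted(onsets, onsets + w0_samples, side="right")
    return right - np.arange(onsets.size)


def onset_frequency(C: OnsetList, j: int, w0: float, fs: float) -> int:
    """Number of onsets in the closed window [C[j], C[j] + w0] (>= 1)."""
    onsets = C.onsets
    if not 0 <= j < onsets.size:
        raise IndexError(f"onset index {j} out of range [0, {onsets.size})")
    w0_samples = int(round(w0 * fs))
    return int(
        np.searchsorted(onsets, onsets[j] + w0_samples, side="right") - j
    )


def detect_segments(C: OnsetList, p: SegmentParams, fs: float) -> SegmentList:
    """Onset-density segmentation of one onset list.

    Implements the declarative start/end rules described in the module
    docstring with an iterative scan.  Every returned segment boundary is an
    element of ``C`` (converted to seconds) and every segment contains at
    least ``theta_0`` onsets.  If the recording ends while a segment is open,
    the segment is closed at the last onset.
    """
    onsets = C.onsets
    n = onsets.size
    if n == 0:
        return SegmentList((), C.channel_id)
    w0_samples = int(round(p.w0 * fs))
    f = _window_counts(onsets, w0_samples)
    th = p.theta_0

    segments: list[Interval] = []
    j = 0
    while j < n:
        if f[j] < th:
            j += 1
            continue
        start_idx = j
        end_idx = None
        k = j
        while k < n:
            tail = k + th - 1
            if f[k] == th and tail < n and f[tail] == 1:
                end_idx = tail
                break
            k += 1
        if end_idx is None:  # recording ended with the segment still open
            end_idx = n - 1
        segments.append(
            Interval(onsets[start_idx] / fs, onsets[end_idx] / fs)
        )
        j = end_idx + 1
    return SegmentList(tuple(segments), C.channel_id)


def _coalesce(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort and merge overlapping or abutting half-open intervals."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return tuple(out)


def fuse_sources(lists: Sequence[SegmentList]) -> SegmentList:
    """Point-set union of the source-specific segment lists.

    Overlapping or abutting intervals are coalesced so the result is sorted
    and non-overlapping; the union is idempotent, commutative and
    associative over sources.
    """
    merged = _coalesce(iv for lst in lists for iv in lst)
    return SegmentList(merged, "fused")


def eliminate_gaps(T: SegmentList, t_gap: float) -> SegmentList:
    """Merge adjacent segments whose gap is strictly smaller than ``t_gap``.

    Never loses covered time and leaves all remaining gaps >= t_gap;
    idempotent.
    """
    out: list[Interval] = []
    for iv in T:
        if out and iv.start - out[-1].end < t_gap:
            out[-1] = Interval(out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return SegmentList(tuple(out), T.source_id)


@dataclass(frozen=True)
class BottomUpParams:
    """Full bottom-up pipeline parameterisation."""

    segment: SegmentParams
    cycle: CycleDetectParams = field(default_factory=CycleDetectParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)


def detect_eating_bottom_up(rec: EMGRecording, params: BottomUpParams) -> SegmentList:
    """Run the full pipeline on a recording and return eating events."""
    xp = preprocess(rec, params.preprocess)
    onset_lists = detect_chewing_cycles(xp, params.cycle)
    per_channel = [
        detect_segments(C, params.segment, rec.fs) for C in onset_lists
    ]
    fused = fuse_sources(per_channel)
    return eliminate_gaps(fused, params.segment.t_gap)
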