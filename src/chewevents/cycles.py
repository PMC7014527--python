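"""Chewing-cycle onset detection from rectified EMG.

Each chewing cycle (one open-close jaw movement) appears as a short burst of
temporalis-muscle activity.  Onsets are found with a windowed below/above
count in the style of classic EMG onset detectors: slide a window of ``w``
samples over the rectified signal and score each position with

    index = #{first half-window samples < theta_C}
          + #{second half-window samples > theta_C}

The score peaks (at most ``w``) when the contraction starts exactly at the
window centre: quiet baseline fills the first half, burst activity the
second.  Strict local maxima of the index series exceeding ``theta_P * w``
are accepted as onsets, subject to a refractory gap of ``t_interval`` so a
single burst is not counted twice; chewing-cycle rates lie in roughly
0.94-2.17 Hz, hence the 1/3 s default spacing.

The burst threshold ``theta_C = mu + 3 sigma`` is estimated from baseline
(non-eating) signal, whose rectified amplitude is modelled as half-normal
noise; three standard deviations put the threshold above nearly all baseline
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import PreprocessedSignal
from .signal_io import EventReference, ValidationError


@dataclass(frozen=True)
class BaselineStats:
    """Mean and standard deviation of baseline (non-eating) amplitude."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")

    @property
    def theta_c(self) -> float:
        return self.mu + 3.0 * self.sigma


@dataclass(frozen=True)
class CycleDetectParams:
    """Windowed onset-detector parameters.

    w : window length in samples (even; default 100 = 0.4 s at 256 Hz)
    theta_c : burst amplitude threshold, signal units (estimate from baseline)
    theta_p : peak threshold fraction of w, in [0, 1]
    t_interval : minimum onset spacing in seconds (refractory)
    """

    w: int = 100
    theta_c: float | None = None
    theta_p: float = 0.7
    t_interval: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.w < 2 or self.w % 2 != 0:
            raise ValidationError("w must be even and >= 2")
        if not 0.0 <= self.theta_p <= 1.0:
            raise ValidationError("theta_p must lie in [0, 1]")
        if self.t_interval <= 0:
            raise ValidationError("t_interval must be positive")


@dataclass(frozen=True)
class IndexSeries:
    """Below/above count per window position; values in [0, w]."""

    values: np.ndarray
    offset: int
    w: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class OnsetList:
    """Strictly increasing chewing-cycle onset sample indices of one channel."""

    onsets: np.ndarray
    channel_id: str = ""

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.int64)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def times(self, fs: float) -> np.ndarray:
        return self.onsets / fs


def estimate_burst_threshold(baseline: np.ndarray) -> float:
    """theta_C = mu + 3*sigma of the supplied baseline samples.

    Uses the population standard deviation; the baseline should be drawn from
    the non-eating portions of (pre-processed, rectified) training data.
    """
    arr = np.ravel(np.asarray(baseline, dtype=float))
    if arr.size == 0:
        raise ValidationError("baseline is empty")
    return float(arr.mean() + 3.0 * arr.std(ddof=0))


def baseline_samples(xp: PreprocessedSignal, ref: EventReference) -> np.ndarray:
    """All pre-processed samples outside the reference events, all channels."""
    n = xp.n_samples
    t = np.arange(n) / xp.fs
    eating = np.zeros(n, dtype=bool)
    for ev in ref.events:
        eating[(t >= ev.start) & (t < ev.end)] = True
    return xp.values[:, ~eating].ravel()


def compute_index_series(x: np.ndarray, w: int, theta_c: float) -> IndexSeries:
    """Index series over all window positions, running-sum updated.

    For the window starting at sample ``i0`` the value is the number of
    samples strictly below ``theta_c`` among the first ``w/2`` window samples
    plus the number strictly above among the last ``w/2``.  Computed with
    prefix sums (an exact incremental update), bit-identical to a per-window
    recount.
    """
    x = np.ravel(np.asarray(x, dtype=float))
    if w < 2 or w % 2 != 0:
        raise ValidationError("w must be even and >= 2")
    if x.size <= w:
        raise ValidationError(f"signal length {x.size} must exceed w={w}")
    h = w // 2
    below = np.concatenate(([0], np.cumsum(x < theta_c, dtype=np.int64)))
    above = np.concatenate(([0], np.cumsum(x > theta_c, dtype=np.int64)))
    starts = np.arange(x.size - w + 1)
    index1 = below[starts + h] - below[starts]
    index2 = above[starts + w] - above[starts + h]
    return IndexSeries(index1 + index2, offset=0, w=w)


def detect_onsets(
    I: IndexSeries,
    w: int,
    theta_p: float,
    t_interval: float,
    fs: float,
    channel_id: str = "",
) -> OnsetList:
    """Accept strict local maxima of the index series above ``theta_p * w``.

    After accepting an onset the scan skips ``round(t_interval * fs)``
    positions (refractory), so consecutive onsets are at least that far
    apart.  The onset sample is the peak window start plus ``w/2``: the index
    is maximal when the contraction begins at the window centre.
    """
    v = I.values
    skip = int(round(t_interval * fs))
    if v.size < 3:
        return OnsetList(np.empty(0, dtype=np.int64), channel_id)
    peak = (v[:-2] < v[1:-1]) & (v[1:-1] > v[2:]) & (v[1:-1] > theta_p * w)
    candidates = np.nonzero(peak)[0]  # peak located at candidate + 1
    accepted: list[int] = []
    next_allowed = 0
    for c in candidates:
        if c >= next_allowed:
            accepted.append(int(c) + 1)
            next_allowed = int(c) + skip + 1
    onsets = np.asarray(accepted, dtype=np.int64) + I.offset + w // 2
    return OnsetList(onsets, channel_id)


def detect_chewing_cycles(
    xp: PreprocessedSignal, p: CycleDetectParams
) -> list[OnsetList]:
    """Per-channel onset detection: index series + peak picking."""
    if p.theta_c is None:
        raise ValidationError(
            "theta_c is required; estimate it with estimate_burst_threshold"
        )
    out = []
    for c in range(xp.n_channels):
        series = compute_index_series(xp.values[c], p.w, p.theta_c)
        out.append(
            detect_onsets(series, p.w, p.theta_p, p.t_interval, xp.fs, str(c))
        )
    return out
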