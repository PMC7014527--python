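"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately dumb: per-window recounts, explicit loops
over the declarative predicates, sample-grid label intersection and
all-pairs minima.  None of it shares code with the package internals.
"""

from __future__ import annotations

import numpy as np

from chewevents.signal_io import EventReference, Interval, SegmentList


def index_series_bruteforce(x: np.ndarray, w: int, theta_c: float) -> np.ndarray:
    """Recount the below/above index for every window position."""
    x = np.asarray(x, dtype=float)
    h = w // 2
    out = np.empty(x.size - w + 1, dtype=np.int64)
    for i0 in range(out.size):
        first = x[i0 : i0 + h]
        second = x[i0 + h : i0 + w]
        out[i0] = int((first < theta_c).sum()) + int((second > theta_c).sum())
    return out


def count_in_window(onsets: np.ndarray, j: int, w0_samples: int) -> int:
    """Onset count in the closed window [C[j], C[j] + w0], by explicit loop."""
    c = 0
    for s in onsets:
        if onsets[j] <= s <= onsets[j] + w0_samples:
            c += 1
    return c


def segments_bruteforce(
    onsets: np.ndarray, w0_samples: int, theta_0: int
) -> list[tuple[int, int]]:
    """Direct scan of the declarative start/end predicates.

    Returns (start_index, end_index) pairs into ``onsets``.  A segment starts
    at the first onset (after the previous segment) whose window count
    reaches theta_0; it ends at index jend + theta_0 - 1 where the count at
    jend equals theta_0 exactly and the count at jend + theta_0 - 1 is 1.
    An open segment at the end of the list closes at the last onset.
    """
    onsets = np.asarray(onsets)
    n = len(onsets)
    segs: list[tuple[int, int]] = []
    j = 0
    while j < n:
        if count_in_window(onsets, j, w0_samples) < theta_0:
            j += 1
            continue
        start = j
        end = None
        k = j
        while k < n:
            tail = k + theta_0 - 1
            if (
                count_in_window(onsets, k, w0_samples) == theta_0
                and tail < n
                and count_in_window(onsets, tail, w0_samples) == 1
            ):
                end = tail
                break
            k += 1
        if end is None:
            end = n - 1
        segs.append((start, end))
        j = end + 1
    return segs


def threshold_segments_bruteforce(
    x: np.ndarray, w1: int, s1: int, theta_1: float
) -> list[tuple[int, int]]:
    """Recompute the EMG-work crossing detector window by window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    starts: list[int] = []
    ends: list[int] = []
    i = s1
    while i + p_next_end(w1, s1) <= n:
        f_prev = x[i - s1 : i + w1 - s1].sum()
        f_cur = x[i : i + w1].sum()
        f_next = x[i + s1 : i + w1 + s1].sum()
        if f_prev < theta_1 and f_cur > theta_1:
            starts.append(i)
        if f_cur > theta_1 and f_next < theta_1:
            ends.append(i + s1)
        i += s1
    events = sorted([(s, 0) for s in starts] + [(e, 1) for e in ends])
    pairs: list[tuple[int, int]] = []
    open_start = None
    last = i - s1 + s1  # one step past the final evaluated window
    for t, kind in events:
        if kind == 0 and open_start is None:
            open_start = t
        elif kind == 1 and open_start is not None and t > open_start:
            pairs.append((open_start, t))
            open_start = None
    if open_start is not None and last > open_start:
        pairs.append((open_start, last))
    return pairs


def p_next_end(w1: int, s1: int) -> int:
    # the F_next window must fit: last evaluated i satisfies i + w1 + s1 <= n
    return w1 + s1


def ttp_sample_grid(
    ref: EventReference, det: SegmentList, fs: float, n_samples: int
) -> float:
    """Overlap duration via boolean label intersection on the sample grid."""
    t = np.arange(n_samples) / fs
    ref_mask = np.zeros(n_samples, dtype=bool)
    for e in ref.events:
        ref_mask |= (t >= e.start) & (t < e.end)
    det_mask = np.zeros(n_samples, dtype=bool)
    for s in det:
        det_mask |= (t >= s.start) & (t < s.end)
    return float((ref_mask & det_mask).sum()) / fs


def timing_bruteforce(
    ref: EventReference, det: SegmentList
) -> tuple[list[float], list[float]]:
    """All-pairs minima of |detected - reference| boundary distances."""
    starts, ends = [], []
    for q in det:
        starts.append(min(abs(q.start - p.start) for p in ref.events))
        ends.append(min(abs(q.end - p.end) for p in ref.events))
    return starts, ends


# ---------------------------------------------------------------------------
# random structure generators (seeded by the caller)


def random_onset_list(rng: np.random.Generator, max_len: int = 60) -> np.ndarray:
    """Random strictly increasing onset sample indices, mixed regimes."""
    n = int(rng.integers(0, max_len))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    gaps = rng.integers(1, 400, size=n)
    return np.cumsum(gaps).astype(np.int64)


def bursty_onset_list(
    rng: np.random.Generator,
    n_bursts: int = 3,
    fs: float = 256.0,
) -> np.ndarray:
    """Quasi-periodic clusters separated by silence (chewing-like)."""
    onsets: list[int] = []
    t = 0.0
    for _ in range(n_bursts):
        t += rng.uniform(30.0, 120.0)
        rate = rng.uniform(0.94, 2.17)
        n = int(rng.integers(5, 40))
        for _k in range(n):
            onsets.append(int(round(t * fs)))
            t += (1.0 / rate) * (1.0 + 0.08 * rng.standard_normal())
    arr = np.unique(np.asarray(onsets, dtype=np.int64))
    return arr


def random_interval_list(
    rng: np.random.Generator,
    fs: float = 256.0,
    max_events: int = 6,
    horizon_s: float = 2000.0,
) -> tuple[Interval, ...]:
    """Sorted, non-overlapping intervals with sample-grid-aligned bounds."""
    n = int(rng.integers(0, max_events + 1))
    out = []
    t = 0.0
    for _ in range(n):
        t += rng.uniform(1.0, horizon_s / max(max_events, 1) / 2)
        d = rng.uniform(0.5, horizon_s / max(max_events, 1) / 2)
        a = round(t * fs) / fs
        b = round((t + d) * fs) / fs
        if b > a:
            out.append(Interval(a, b))
        t += d + 1.0
    return tuple(out)
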