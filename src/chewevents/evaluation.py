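"""Overlap-retrieval metrics, timing errors, grid search and LOPO.

Retrieval is duration-based: with reference events p = 1..P and detected
events q = 1..Q,

    T_gt  = sum_p duration(p)                      (ground-truth eating time)
    T_ret = sum_q duration(q)                      (retrieved eating time)
    T_tp  = sum_{p,q} positive overlap(p, q)       (true-positive time)

    recall = T_tp / T_gt,  precision = T_tp / T_ret,  F1 = harmonic mean.

Timing errors are event-based: each detected start (end) is charged the
absolute distance to the nearest reference start (end); means over the Q
detections give the average start/end timing errors.  All times are carried
in seconds at the recording's sample resolution.

Grid search evaluates a detector over a parameter grid on training data and
extracts three performance points: PX (maximal F1), PS (minimal mean start
error) and PE (minimal mean end error).  Leave-one-participant-out (LOPO)
cross-validation repeats the grid search with each participant held out and
averages the held-out results across folds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import bottom_up, cycles, top_down
from .preprocessing import PreprocessParams, preprocess
from .signal_io import (
    EMGRecording,
    EventReference,
    SegmentList,
    ValidationError,
)

POINT_NAMES = ("PX", "PS", "PE")


@dataclass(frozen=True)
class RetrievalMetrics:
    """Duration-based precision/recall/F1 for one reference/detection pair."""

    t_gt: float
    t_ret: float
    t_tp: float
    precision: float
    recall: float
    f1: float
    defined: bool = True  # False when a denominator was zero


@dataclass(frozen=True)
class TimingErrors:
    """Per-event absolute start/end errors and their summary statistics."""

    start_errors: np.ndarray
    end_errors: np.ndarray
    defined: bool = True

    @property
    def mean_start(self) -> float:
        return float(np.mean(self.start_errors)) if self.defined else math.nan

    @property
    def mean_end(self) -> float:
        return float(np.mean(self.end_errors)) if self.defined else math.nan

    @property
    def std_start(self) -> float:
        if not self.defined or self.start_errors.size < 2:
            return 0.0
        return float(np.std(self.start_errors, ddof=1))

    @property
    def std_end(self) -> float:
        if not self.defined or self.end_errors.size < 2:
            return 0.0
        return float(np.std(self.end_errors, ddof=1))


UNDEFINED_TIMING = TimingErrors(
    np.empty(0), np.empty(0), defined=False
)


def overlap_durations(
    ref: EventReference, det: SegmentList
) -> tuple[float, float, float]:
    """(T_gt, T_ret, T_tp): summed reference, detected and overlap durations."""
    t_gt = ref.total_duration
    t_ret = det.total_duration
    t_tp = 0.0
    for p in ref.events:
        for q in det:
            t_tp += p.overlap(q)
    return t_gt, t_ret, t_tp


def retrieval_metrics(ref: EventReference, det: SegmentList) -> RetrievalMetrics:
    """Precision, recall and F1 from summed durations (0-flagged if empty)."""
    t_gt, t_ret, t_tp = overlap_durations(ref, det)
    defined = t_gt > 0 and t_ret > 0
    precision = t_tp / t_ret if t_ret > 0 else 0.0
    recall = t_tp / t_gt if t_gt > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return RetrievalMetrics(t_gt, t_ret, t_tp, precision, recall, f1, defined)


def timing_errors(ref: EventReference, det: SegmentList) -> TimingErrors:
    """Nearest-reference absolute start/end errors per detected event.

    Every detected event contributes, even if it overlaps no reference event
    (the literal nearest-boundary minimum).  Undefined (flagged) when there
    are no detections or no reference events.
    """
    if len(det) == 0 or ref.count == 0:
        return UNDEFINED_TIMING
    ref_starts = ref.starts
    ref_ends = ref.ends
    det_starts = np.array([s.start for s in det])
    det_ends = np.array([s.end for s in det])
    start_err = np.min(
        np.abs(det_starts[:, None] - ref_starts[None, :]), axis=1
    )
    end_err = np.min(np.abs(det_ends[:, None] - ref_ends[None, :]), axis=1)
    return TimingErrors(start_err, end_err)


# ---------------------------------------------------------------------------
# grid search


@dataclass(frozen=True)
class Participant:
    """One labelled recording (identifier, signal, reference events)."""

    id: str
    recording: EMGRecording
    reference: EventReference


@dataclass
class GridRow:
    params: dict
    metrics: RetrievalMetrics
    timing: TimingErrors


@dataclass
class GridResult:
    """Grid-search table plus the three performance points."""

    rows: list[GridRow]
    points: dict  # name -> GridRow

    @property
    def px(self) -> GridRow:
        return self.points["PX"]

    @property
    def ps(self) -> GridRow:
        return self.points["PS"]

    @property
    def pe(self) -> GridRow:
        return self.points["PE"]


def _pooled_scores(
    pairs: Sequence[tuple[EventReference, SegmentList]]
) -> tuple[RetrievalMetrics, TimingErrors]:
    """Pool durations and per-event errors over several labelled recordings."""
    t_gt = t_ret = t_tp = 0.0
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for ref, det in pairs:
        g, r, tp = overlap_durations(ref, det)
        t_gt += g
        t_ret += r
        t_tp += tp
        te = timing_errors(ref, det)
        if te.defined:
            starts.append(te.start_errors)
            ends.append(te.end_errors)
    precision = t_tp / t_ret if t_ret > 0 else 0.0
    recall = t_tp / t_gt if t_gt > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    metrics = RetrievalMetrics(
        t_gt, t_ret, t_tp, precision, recall, f1, t_gt > 0 and t_ret > 0
    )
    if starts:
        timing = TimingErrors(np.concatenate(starts), np.concatenate(ends))
    else:
        timing = UNDEFINED_TIMING
    return metrics, timing


def _preprocess_all(
    participants: Sequence[Participant], fixed: Mapping
) -> dict:
    """Preprocess participants, honouring an optional shared ``xp_cache``."""
    cache = fixed.get("xp_cache")
    pp = fixed.get("preprocess", PreprocessParams())
    out = {}
    for p in participants:
        if cache is not None and p.id in cache:
            out[p.id] = cache[p.id]
        else:
            xp = preprocess(p.recording, pp)
            if cache is not None:
                cache[p.id] = xp
            out[p.id] = xp
    return out


class _BottomUpRunner:
    """Cached bottom-up detection over a labelled dataset.

    theta_C is estimated once from the pooled non-eating samples of the
    training participants (unless fixed); index series are cached per
    participant so the (w0, theta_0) grid is cheap.
    """

    algo = "bottom-up"
    grid_keys = ("w0", "theta_0", "theta_P")

    def __init__(self, train: Sequence[Participant], fixed: Mapping):
        self.fixed = dict(fixed)
        self.xps = _preprocess_all(train, self.fixed)
        self.fs = train[0].recording.fs
        theta_c = self.fixed.get("theta_C")
        if theta_c is None:
            pooled = np.concatenate(
                [
                    cycles.baseline_samples(self.xps[p.id], p.reference)
                    for p in train
                ]
            )
            theta_c = cycles.estimate_burst_threshold(pooled)
        self.theta_c = float(theta_c)
        self._onsets: dict = {}
        self._series: dict = {}

    def attach(self, extra: Sequence[Participant]) -> None:
        """Preprocess held-out participants so detect() can see them."""
        self.xps.update(_preprocess_all(extra, self.fixed))

    def _onset_lists(self, pid: str, w: int, theta_p: float, t_interval: float):
        key = (pid, w, theta_p, t_interval)
        if key not in self._onsets:
            xp = self.xps[pid]
            lists = []
            for c in range(xp.n_channels):
                skey = (pid, c, w)
                if skey not in self._series:
                    self._series[skey] = cycles.compute_index_series(
                        xp.values[c], w, self.theta_c
                    )
                lists.append(
                    cycles.detect_onsets(
                        self._series[skey], w, theta_p, t_interval, self.fs, str(c)
                    )
                )
            self._onsets[key] = lists
        return self._onsets[key]

    def detect(self, p: Participant, params: Mapping) -> SegmentList:
        w = int(self.fixed.get("w", 100))
        theta_p = float(params.get("theta_P", self.fixed.get("theta_P", 0.7)))
        t_interval = float(self.fixed.get("t_interval", 1.0 / 3.0))
        t_gap = float(self.fixed.get("t_gap", 300.0))
        sp = bottom_up.SegmentParams(
            w0=float(params["w0"]), theta_0=int(params["theta_0"]), t_gap=t_gap
        )
        lists = self._onset_lists(p.id, w, theta_p, t_interval)
        per_channel = [bottom_up.detect_segments(C, sp, self.fs) for C in lists]
        return bottom_up.eliminate_gaps(
            bottom_up.fuse_sources(per_channel), t_gap
        )


class _ThresholdRunner:
    """Cached threshold top-down detection (grid over w1, theta_1)."""

    algo = "threshold"
    grid_keys = ("w1", "theta_1")

    def __init__(self, train: Sequence[Participant], fixed: Mapping):
        self.fixed = dict(fixed)
        self.xps = _preprocess_all(train, self.fixed)

    def attach(self, extra: Sequence[Participant]) -> None:
        self.xps.update(_preprocess_all(extra, self.fixed))

    def detect(self, p: Participant, params: Mapping) -> SegmentList:
        tp = top_down.ThresholdParams(
            w1=int(params["w1"]),
            theta_1=float(params["theta_1"]),
            s1=int(self.fixed.get("s1", 256)),
        )
        t_gap = float(self.fixed.get("t_gap", 300.0))
        per_channel = top_down.detect_segments_threshold(self.xps[p.id], tp)
        return bottom_up.eliminate_gaps(
            bottom_up.fuse_sources(per_channel), t_gap
        )


class _OcsvmRunner:
    """Cached ocSVM top-down detection (grid over gamma, nu).

    The model is trained per parameter combination on eating-labelled
    windows pooled over the training participants; window features are
    cached per participant.
    """

    algo = "ocsvm"
    grid_keys = ("gamma", "nu")

    def __init__(self, train: Sequence[Participant], fixed: Mapping):
        self.fixed = dict(fixed)
        self.w2 = int(self.fixed.get("w2", 2560))
        self.xps = _preprocess_all(train, self.fixed)
        self.fs = train[0].recording.fs
        theta_c = self.fixed.get("theta_C")
        if theta_c is None:
            pooled = np.concatenate(
                [
                    cycles.baseline_samples(self.xps[p.id], p.reference)
                    for p in train
                ]
            )
            theta_c = cycles.estimate_burst_threshold(pooled)
        self.theta_c = float(theta_c)
        self._features: dict = {}
        train_feats = []
        for p in train:
            feats = self._channel_features(p.id)
            xp = self.xps[p.id]
            ex = top_down.WindowFeatureExtractor(self.w2, self.fs, self.theta_c)
            starts = ex.window_starts(xp.n_samples)
            mask = top_down.eating_window_mask(
                starts, self.w2, self.fs, p.reference
            )
            for f in feats:
                train_feats.append(f[mask])
        self.train_features = (
            np.vstack(train_feats) if train_feats else np.empty((0, 8))
        )
        self._models: dict = {}

    def attach(self, extra: Sequence[Participant]) -> None:
        self.xps.update(_preprocess_all(extra, self.fixed))

    def _channel_features(self, pid: str) -> list[np.ndarray]:
        if pid not in self._features:
            self._features[pid] = top_down.extract_window_features(
                self.xps[pid], self.w2, self.theta_c
            )
        return self._features[pid]

    def _model(self, params: Mapping) -> top_down.OcsvmModel:
        key = (float(params["gamma"]), float(params["nu"]))
        if key not in self._models:
            p = top_down.OcsvmParams(w2=self.w2, gamma=key[0], nu=key[1])
            if self.train_features.shape[0] < 10:
                raise ValidationError(
                    "not enough eating-labelled training windows for the ocSVM"
                )
            self._models[key] = top_down.train_ocsvm(
                self.train_features, p, self.theta_c
            )
        return self._models[key]

    def detect(self, p: Participant, params: Mapping) -> SegmentList:
        model = self._model(params)
        xp = self.xps[p.id]
        t_gap = float(self.fixed.get("t_gap", 300.0))
        ex = top_down.WindowFeatureExtractor(self.w2, self.fs, self.theta_c)
        starts = ex.window_starts(xp.n_samples)
        per_channel = []
        for c, feats in enumerate(self._channel_features(p.id)):
            inlier = model.predict_inlier(feats)
            intervals = []
            run_start = None
            for i, flag in enumerate(inlier):
                if flag and run_start is None:
                    run_start = int(starts[i])
                elif not flag and run_start is not None:
                    intervals.append(
                        bottom_up.Interval(
                            run_start / self.fs, int(starts[i]) / self.fs
                        )
                    )
                    run_start = None
            if run_start is not None:
                intervals.append(
                    bottom_up.Interval(
                        run_start / self.fs, (int(starts[-1]) + self.w2) / self.fs
                    )
                )
            per_channel.append(SegmentList(tuple(intervals), str(c)))
        return bottom_up.eliminate_gaps(
            bottom_up.fuse_sources(per_channel), t_gap
        )


_RUNNERS = {
    "bottom-up": _BottomUpRunner,
    "threshold": _ThresholdRunner,
    "ocsvm": _OcsvmRunner,
}


def make_runner(
    train: Sequence[Participant], algo: str, fixed: Mapping | None = None
):
    """Build a cached detector runner over a training set."""
    if algo not in _RUNNERS:
        raise ValidationError(f"unknown algorithm {algo!r}")
    return _RUNNERS[algo](train, fixed or {})


def _combinations(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid.keys())
    return [
        dict(zip(keys, values))
        for values in itertools.product(*(grid[k] for k in keys))
    ]


def grid_search(
    train: Sequence[Participant],
    grid: Mapping[str, Sequence],
    algo: str,
    fixed: Mapping | None = None,
    runner=None,
) -> GridResult:
    """Evaluate every parameter combination on the training participants.

    Metrics are pooled over participants (summed durations, concatenated
    per-event errors).  Ties at the performance points are broken by the
    first combination in grid iteration order (lexicographic in the given
    key/value order), making the search deterministic.
    """
    combos = _combinations(grid)
    if not combos:
        raise ValidationError("empty parameter grid")
    runner = runner or make_runner(train, algo, fixed)
    rows: list[GridRow] = []
    for params in combos:
        pairs = [(p.reference, runner.detect(p, params)) for p in train]
        metrics, timing = _pooled_scores(pairs)
        rows.append(GridRow(params, metrics, timing))

    def best(key, reverse):
        vals = [key(r) for r in rows]
        cleaned = [
            (-v if reverse else v, i)
            for i, v in enumerate(vals)
            if not math.isnan(v)
        ]
        if not cleaned:
            return rows[0]
        return rows[min(cleaned)[1]]

    points = {
        "PX": best(lambda r: r.metrics.f1, reverse=True),
        "PS": best(lambda r: r.timing.mean_start, reverse=False),
        "PE": best(lambda r: r.timing.mean_end, reverse=False),
    }
    return GridResult(rows, points)


# ---------------------------------------------------------------------------
# LOPO


@dataclass
class FoldResult:
    held_out: str
    flagged: bool
    results: dict = field(default_factory=dict)  # point -> GridRow (test scores)


@dataclass
class LopoResult:
    """Per-fold held-out results plus cross-fold summary statistics."""

    folds: list[FoldResult]

    def summary(self) -> dict:
        """Cross-fold mean/std of F1 and timing errors at each point."""
        out: dict = {}
        for point in POINT_NAMES:
            f1s, s_mean, e_mean = [], [], []
            for fold in self.folds:
                if fold.flagged:
                    continue
                row = fold.results[point]
                f1s.append(row.metrics.f1)
                if row.timing.defined:
                    s_mean.append(row.timing.mean_start)
                    e_mean.append(row.timing.mean_end)

            def agg(vals):
                if not vals:
                    return {"mean": math.nan, "std": math.nan}
                return {
                    "mean": float(np.mean(vals)),
                    "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }

            out[point] = {
                "f1": agg(f1s),
                "start_error_s": agg(s_mean),
                "end_error_s": agg(e_mean),
            }
        return out


def lopo_evaluate(
    dataset: Sequence[Participant],
    algo: str,
    grid: Mapping[str, Sequence],
    fixed: Mapping | None = None,
) -> LopoResult:
    """Leave-one-participant-out evaluation with per-fold grid search.

    Each fold trains (grid-searches) on all other participants, then applies
    the PX/PS/PE parameter combinations to the held-out participant.  Folds
    whose training union contains no eating events are flagged and excluded
    from the summary.
    """
    if len(dataset) < 2:
        raise ValidationError("LOPO needs at least 2 participants")
    fixed = dict(fixed or {})
    fixed.setdefault("xp_cache", {})  # share preprocessing across folds
    folds: list[FoldResult] = []
    for held in dataset:
        train = [p for p in dataset if p.id != held.id]
        if sum(p.reference.count for p in train) == 0:
            folds.append(FoldResult(held.id, flagged=True))
            continue
        runner = make_runner(train, algo, fixed)
        gres = grid_search(train, grid, algo, fixed, runner=runner)
        runner.attach([held])
        fold = FoldResult(held.id, flagged=False)
        for point in POINT_NAMES:
            params = gres.points[point].params
            det = runner.detect(held, params)
            metrics, timing = _pooled_scores([(held.reference, det)])
            fold.results[point] = GridRow(dict(params), metrics, timing)
        folds.append(fold)
    return LopoResult(folds)
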