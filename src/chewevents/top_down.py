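"""Top-down baselines: EMG-work thresholding and windowed one-class SVM.

Both baselines classify fixed signal windows as chewing/non-chewing and feed
the same fusion and gap-elimination stages as the bottom-up detector.

Threshold detector: slide a window of ``w1`` samples with step ``s1`` over
the rectified signal, compute the EMG work F (sum of rectified samples) and
report a segment start when F crosses above ``theta_1`` and an end when it
crosses back below.

ocSVM detector: cut the rectified signal into non-overlapping windows of
``w2`` samples, extract a feature vector per window, and train a one-class
SVM (RBF kernel) on eating-labelled windows only; windows predicted as
inliers are eating.  Because decisions are per window, detected boundaries
are quantised to multiples of ``w2`` — the structural reason this baseline
incurs larger timing errors than the onset-based bottom-up detector.

The feature set (mean, std, max, EMG work, rate above theta_C, spectral
centroid, band powers 20-60 and 60-120 Hz) is a declared package default and
is swappable via ``WindowFeatureExtractor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .signal_io import EventReference, Interval, SegmentList, ValidationError
from .preprocessing import PreprocessedSignal


@dataclass(frozen=True)
class ThresholdParams:
    """w1: window samples; s1: step samples; theta_1: EMG-work threshold."""

    w1: int
    theta_1: float
    s1: int = 256

    def __post_init__(self) -> None:
        if not self.w1 >= self.s1 >= 1:
            raise ValidationError("need w1 >= s1 >= 1")
        if self.theta_1 <= 0:
            raise ValidationError("theta_1 must be positive")


@dataclass(frozen=True)
class OcsvmParams:
    """w2: window samples; gamma: RBF width; nu: margin-error bound."""

    w2: int
    gamma: float
    nu: float

    def __post_init__(self) -> None:
        if self.w2 < 1:
            raise ValidationError("w2 must be >= 1")
        if self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if not 0 < self.nu <= 1:
            raise ValidationError("nu must lie in (0, 1]")


def emg_work(x: np.ndarray) -> float:
    """Sum of rectified EMG samples in the window (chewing intensity F)."""
    arr = np.ravel(np.asarray(x, dtype=float))
    if arr.size == 0:
        raise ValidationError("empty window")
    return float(arr.sum())


def detect_segments_threshold(
    xp: PreprocessedSignal, p: ThresholdParams
) -> list[SegmentList]:
    """Threshold-crossing segmentation of the per-window EMG work.

    At window position ``i`` (multiples of ``s1``) a start is recorded when
    the previous window's work is below ``theta_1`` and the current one is
    above; an end at ``i + s1`` when the current is above and the next below.
    Starts and ends are paired greedily in temporal order; an end with no
    open start is dropped and a start left open at the recording end is
    closed at the last evaluated window.
    """
    n = xp.n_samples
    if n < p.w1 + 2 * p.s1:
        raise ValidationError(
            f"signal length {n} too short for w1={p.w1}, s1={p.s1}"
        )
    out = []
    # window starts i such that the previous (i - s1) and next (i + s1)
    # windows also fit inside the signal
    positions = np.arange(p.s1, n - p.w1 - p.s1 + 1, p.s1)
    for c in range(xp.n_channels):
        x = xp.values[c]
        csum = np.concatenate(([0.0], np.cumsum(x)))
        work = lambda i0: csum[i0 + p.w1] - csum[i0]  # noqa: E731
        F_prev = work(positions - p.s1)
        F_cur = work(positions)
        F_next = work(positions + p.s1)
        starts = positions[(F_prev < p.theta_1) & (F_cur > p.theta_1)]
        ends = positions[(F_cur > p.theta_1) & (F_next < p.theta_1)] + p.s1
        events = sorted(
            [(int(s), 0) for s in starts] + [(int(e), 1) for e in ends]
        )
        intervals: list[Interval] = []
        open_start: int | None = None
        for t, kind in events:
            if kind == 0:
                if open_start is None:
                    open_start = t
            else:
                if open_start is not None and t > open_start:
                    intervals.append(Interval(open_start / xp.fs, t / xp.fs))
                    open_start = None
        if open_start is not None:
            last = int(positions[-1] + p.s1)
            if last > open_start:
                intervals.append(Interval(open_start / xp.fs, last / xp.fs))
        out.append(SegmentList(tuple(intervals), str(c)))
    return out


FEATURE_NAMES = (
    "mean",
    "std",
    "max",
    "work",
    "rate_above_theta_c",
    "spectral_centroid",
    "band_power_20_60",
    "band_power_60_120",
)


@dataclass(frozen=True)
class WindowFeatureExtractor:
    """Per-window feature extraction for the ocSVM baseline.

    Operates on one channel of rectified signal cut into non-overlapping
    windows of ``w2`` samples.  ``theta_c`` is the burst amplitude threshold
    (shared with the bottom-up detector) used for the activity-rate feature.
    """

    w2: int
    fs: float
    theta_c: float

    def window_starts(self, n_samples: int) -> np.ndarray:
        k = n_samples // self.w2
        return np.arange(k) * self.w2

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Raw (unstandardised) feature matrix, one row per window."""
        x = np.ravel(np.asarray(x, dtype=float))
        if x.size < self.w2:
            raise ValidationError(f"signal shorter than one window ({self.w2})")
        k = x.size // self.w2
        win = x[: k * self.w2].reshape(k, self.w2)

        freqs = np.fft.rfftfreq(self.w2, d=1.0 / self.fs)
        spec = np.abs(np.fft.rfft(win, axis=1)) ** 2
        power = spec.sum(axis=1)
        centroid = np.where(
            power > 0, (spec * freqs).sum(axis=1) / np.maximum(power, 1e-300), 0.0
        )
        lo = spec[:, (freqs >= 20) & (freqs < 60)].sum(axis=1) / self.w2
        hi = spec[:, (freqs >= 60) & (freqs <= 120)].sum(axis=1) / self.w2

        feats = np.column_stack(
            [
                win.mean(axis=1),
                win.std(axis=1),
                win.max(axis=1),
                win.sum(axis=1),
                (win > self.theta_c).mean(axis=1),
                centroid,
                lo,
                hi,
            ]
        )
        if not np.all(np.isfinite(feats)):
            raise ValidationError("non-finite window feature")
        return feats


def extract_window_features(
    xp: PreprocessedSignal, w2: int, theta_c: float
) -> list[np.ndarray]:
    """Per-channel raw feature matrices for non-overlapping ``w2`` windows."""
    ex = WindowFeatureExtractor(w2, xp.fs, theta_c)
    return [ex.transform(xp.values[c]) for c in range(xp.n_channels)]


@dataclass
class OcsvmModel:
    """Trained one-class model: standardiser + RBF one-class SVM.

    ``theta_c`` records the burst threshold used when the training features
    were extracted, so detection re-extracts comparable features.
    """

    scaler: StandardScaler
    svm: OneClassSVM
    params: OcsvmParams
    theta_c: float = 0.0

    def predict_inlier(self, features: np.ndarray) -> np.ndarray:
        """Boolean eating prediction per window (inlier = eating)."""
        return self.svm.predict(self.scaler.transform(features)) == 1


def train_ocsvm(
    features: np.ndarray, p: OcsvmParams, theta_c: float = 0.0
) -> OcsvmModel:
    """Fit the one-class SVM on eating-labelled training windows.

    Training uses eating windows only (one-class setting); at most about a
    ``nu`` fraction of them end up flagged as outliers.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 10:
        raise ValidationError("need a 2-D feature matrix with >= 10 windows")
    if np.any(features.std(axis=0) == 0):
        raise ValidationError("degenerate (constant) feature column")
    scaler = StandardScaler().fit(features)
    svm = OneClassSVM(kernel="rbf", gamma=p.gamma, nu=p.nu)
    svm.fit(scaler.transform(features))
    return OcsvmModel(scaler, svm, p, theta_c)


def eating_window_mask(
    starts: np.ndarray, w2: int, fs: float, ref: EventReference
) -> np.ndarray:
    """True for windows lying entirely inside a reference eating event."""
    t0 = starts / fs
    t1 = (starts + w2) / fs
    mask = np.zeros(starts.size, dtype=bool)
    for ev in ref.events:
        mask |= (t0 >= ev.start) & (t1 <= ev.end)
    return mask


def detect_segments_ocsvm(
    xp: PreprocessedSignal, model: OcsvmModel, w2: int | None = None
) -> list[SegmentList]:
    """Merge consecutive inlier-predicted windows into per-channel segments.

    All boundaries are multiples of ``w2`` samples by construction.
    """
    w2 = w2 or model.params.w2
    ex = WindowFeatureExtractor(w2, xp.fs, model.theta_c)
    out = []
    for c in range(xp.n_channels):
        feats = ex.transform(xp.values[c])
        inlier = model.predict_inlier(feats)
        starts = ex.window_starts(xp.n_samples)
        intervals: list[Interval] = []
        run_start: int | None = None
        for i, flag in enumerate(inlier):
            if flag and run_start is None:
                run_start = int(starts[i])
            elif not flag and run_start is not None:
                intervals.append(
                    Interval(run_start / xp.fs, int(starts[i]) / xp.fs)
                )
                run_start = None
        if run_start is not None:
            end = int(starts[-1]) + w2
            intervals.append(Interval(run_start / xp.fs, end / xp.fs))
        out.append(SegmentList(tuple(intervals), str(c)))
    return out
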