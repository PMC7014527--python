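"""Two-channel surrogate temporalis EMG with chew-accurate ground truth.

The generator emulates the structure of free-living bilateral temporalis
recordings so that every detector in the package can be exercised without
real data:

* Gaussian baseline noise (electrode/amplifier floor),
* one band-limited (20-120 Hz) Hann-enveloped activity burst of ~0.3 s per
  chewing cycle, recurring at a per-event rate drawn from 0.94-2.17 Hz,
* 50 Hz power-line hum and slow baseline wander,
* occasional teeth-grinding confounders in non-eating time: fewer than five
  consecutive activations at reduced amplitude with aperiodic spacing,
* optional within-meal pauses (conversation interrupts) shorter than the
  gap-elimination threshold.

Both channels share the chewing schedule (bilateral mastication) with small
(< 30 ms) inter-channel burst-time jitter and independent noise.  Ground
truth carries the chew-accurate event reference, the per-channel true chew
times, and coarse "activity journal" annotations jittered by up to ±60 s
(the resolution of a paper journal).

Event durations are drawn log-uniformly over 54 s - 35.8 min, the range
observed in the free-living corpus the generator emulates; the log-uniform
mean (~9.5 min) matches the corpus mean event duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import (
    EMGRecording,
    EventReference,
    Interval,
    ValidationError,
)
from .evaluation import Participant


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults give a 2 h, 3-event recording."""

    fs: float = 256.0
    duration: float = 7200.0
    n_channels: int = 2
    n_events: int = 3
    event_duration_range: tuple[float, float] = (54.0, 2148.0)
    min_event_gap: float = 360.0
    chew_rate_range: tuple[float, float] = (0.94, 2.17)
    chew_interval_cv: float = 0.08
    burst_duration: float = 0.3
    burst_band: tuple[float, float] = (20.0, 120.0)
    burst_snr: float = 15.0
    baseline_sigma: float = 1.0
    hum_amplitude: float = 0.5
    hum_freq: float = 50.0
    drift_amplitude: float = 2.0
    pause_prob: float = 0.3
    pause_duration_range: tuple[float, float] = (30.0, 120.0)
    grind_rate_per_hour: float = 1.0
    grind_activations: tuple[int, int] = (2, 4)
    grind_amplitude_frac: float = 0.2
    grind_spacing_range: tuple[float, float] = (0.7, 2.0)
    channel_jitter: float = 0.02
    annotation_jitter: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.event_duration_range
        if not (0 < lo <= hi):
            raise ValidationError("invalid event_duration_range")
        rlo, rhi = self.chew_rate_range
        if not (0 < rlo <= rhi):
            raise ValidationError("invalid chew_rate_range")
        if self.n_events < 0 or self.duration <= 0 or self.fs <= 0:
            raise ValidationError("invalid duration/fs/n_events")


@dataclass(frozen=True)
class GroundTruth:
    """Chew-accurate reference, true chew/grind times and journal entries."""

    reference: EventReference
    chew_times: np.ndarray  # shared schedule, seconds
    channel_onsets: tuple[np.ndarray, ...]  # per-channel jittered chew times
    grind_times: np.ndarray  # grind activation times (non-eating)
    journal: tuple[Interval, ...]  # coarse jittered annotations
    pauses: tuple[Interval, ...] = ()


def _event_layout(cfg: SynthConfig, rng: np.random.Generator) -> list[Interval]:
    """Place non-overlapping events separated by at least min_event_gap."""
    n = cfg.n_events
    if n == 0:
        return []
    lo, hi = cfg.event_duration_range
    durations = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    available = cfg.duration - (n + 1) * cfg.min_event_gap
    if available <= n * lo:
        raise ValidationError(
            f"cannot fit {n} events of >= {lo} s into {cfg.duration} s"
        )
    budget = 0.9 * available
    if durations.sum() > budget:
        durations *= budget / durations.sum()
        durations = np.maximum(durations, lo)
    leftover = cfg.duration - durations.sum() - (n + 1) * cfg.min_event_gap
    gaps = cfg.min_event_gap + leftover * rng.dirichlet(np.ones(n + 1))
    events = []
    t = 0.0
    for d, g in zip(durations, gaps[:-1]):
        t += g
        events.append(Interval(t, t + d))
        t += d
    return events


def _chew_times_for_event(
    ev: Interval, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, Interval | None]:
    """Quasi-periodic chew times inside one event, with an optional pause."""
    rate = rng.uniform(*cfg.chew_rate_range)
    mean_iv = 1.0 / rate
    pause = None
    if rng.random() < cfg.pause_prob and ev.duration > 4 * cfg.pause_duration_range[1]:
        p_dur = rng.uniform(*cfg.pause_duration_range)
        p_start = ev.start + rng.uniform(0.3, 0.6) * (ev.duration - p_dur)
        pause = Interval(p_start, p_start + p_dur)
    times = []
    t = ev.start
    end_limit = ev.end - cfg.burst_duration
    while t <= end_limit:
        times.append(t)
        iv = mean_iv * (1.0 + cfg.chew_interval_cv * rng.standard_normal())
        iv = max(iv, cfg.burst_duration + 0.06)
        t += iv
        if pause is not None and pause.start <= t < pause.end:
            t = pause.end
    return np.asarray(times), pause


def _grind_times(
    cfg: SynthConfig,
    events: Sequence[Interval],
    rng: np.random.Generator,
) -> np.ndarray:
    """Aperiodic short grinding activations placed only in non-eating time."""
    eating = sum(e.duration for e in events)
    hours = max(cfg.duration - eating, 0.0) / 3600.0
    n_episodes = rng.poisson(cfg.grind_rate_per_hour * hours)
    margin = 30.0
    times: list[float] = []
    for _ in range(n_episodes):
        for _attempt in range(50):
            t0 = rng.uniform(margin, cfg.duration - margin - 15.0)
            m = int(rng.integers(cfg.grind_activations[0], cfg.grind_activations[1] + 1))
            spacing = rng.uniform(*cfg.grind_spacing_range, size=m - 1)
            episode = t0 + np.concatenate(([0.0], np.cumsum(spacing)))
            clear = all(
                not (ev.start - margin <= t <= ev.end + margin)
                for ev in events
                for t in (episode[0], episode[-1])
            )
            if clear:
                times.extend(episode)
                break
    return np.sort(np.asarray(times))


def generate_schedule(cfg: SynthConfig) -> GroundTruth:
    """Deterministic (seeded) event/chew/grind schedule with journal entries."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    events = _event_layout(cfg, rng)
    all_chews: list[np.ndarray] = []
    adjusted: list[Interval] = []
    pauses: list[Interval] = []
    for ev in events:
        chews, pause = _chew_times_for_event(ev, cfg, rng)
        if chews.size < 2:
            continue
        all_chews.append(chews)
        # chew-accurate reference: first chew to last chew + burst duration
        adjusted.append(Interval(chews[0], chews[-1] + cfg.burst_duration))
        if pause is not None:
            pauses.append(pause)
    chew_times = (
        np.concatenate(all_chews) if all_chews else np.empty(0, dtype=float)
    )
    reference = EventReference(tuple(adjusted))
    grind = _grind_times(cfg, reference.events, rng)

    channel_onsets = tuple(
        np.sort(
            chew_times
            + rng.uniform(-cfg.channel_jitter, cfg.channel_jitter, chew_times.size)
        )
        for _ in range(cfg.n_channels)
    )

    # Journal entries mimic a paper activity log: jittered by the logging
    # imprecision, then rounded to the log's 1-minute resolution.  The jitter
    # margin leaves room for the rounding so entries stay within
    # annotation_jitter of the chew-accurate reference.
    margin = max(cfg.annotation_jitter - 30.0, 0.0)
    journal = []
    for ev in reference.events:
        js = ev.start + rng.uniform(-margin, margin)
        je = ev.end + rng.uniform(-margin, margin)
        js = min(max(js, 0.0), cfg.duration)
        je = min(max(je, js), cfg.duration)
        if cfg.annotation_jitter >= 30.0:
            js = 60.0 * round(js / 60.0)
            je = max(60.0 * round(je / 60.0), js)
        journal.append(Interval(js, je))
    return GroundTruth(
        reference=reference,
        chew_times=chew_times,
        channel_onsets=channel_onsets,
        grind_times=grind,
        journal=tuple(journal),
        pauses=tuple(pauses),
    )


def _burst_envelope(
    n: int, times: np.ndarray, amps: np.ndarray, cfg: SynthConfig
) -> np.ndarray:
    env = np.zeros(n)
    blen = max(int(round(cfg.burst_duration * cfg.fs)), 2)
    window = np.hanning(blen)
    for t, a in zip(times, amps):
        i0 = int(round(t * cfg.fs))
        i1 = min(i0 + blen, n)
        if i0 >= n or i1 <= i0:
            continue
        env[i0:i1] += a * window[: i1 - i0]
    return env


def render_signal(gt: GroundTruth, cfg: SynthConfig) -> EMGRecording:
    """Render the scheduled activity into a raw multi-channel recording.

    Per channel: baseline Gaussian noise + Hann-enveloped band-limited burst
    carrier at each chew/grind time + power-line hum + slow drift.  Noise and
    carrier are independent across channels; the schedule is shared.
    """
    cfg.validate()
    n = int(round(cfg.duration * cfg.fs))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE316]))
    lo, hi = cfg.burst_band
    hi = min(hi, 0.499 * cfg.fs)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=cfg.fs, output="sos")
    t = np.arange(n) / cfg.fs
    channels = []
    chew_amp = cfg.burst_snr * cfg.baseline_sigma
    grind_amp = cfg.grind_amplitude_frac * chew_amp
    for c in range(cfg.n_channels):
        noise = rng.normal(0.0, cfg.baseline_sigma, n)
        if chew_amp > 0:
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
            std = carrier.std()
            if std > 0:
                carrier /= std
        else:
            carrier = np.zeros(n)
        onsets = gt.channel_onsets[c] if c < len(gt.channel_onsets) else gt.chew_times
        times = np.concatenate([onsets, gt.grind_times])
        amps = np.concatenate(
            [np.full(onsets.size, chew_amp), np.full(gt.grind_times.size, grind_amp)]
        )
        env = _burst_envelope(n, times, amps, cfg)
        hum = cfg.hum_amplitude * np.sin(
            2 * np.pi * cfg.hum_freq * t + rng.uniform(0, 2 * np.pi)
        )
        f1, f2 = rng.uniform(0.02, 0.2, size=2)
        drift = cfg.drift_amplitude * (
            np.sin(2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi))
            + 0.5 * np.sin(2 * np.pi * f2 * t + rng.uniform(0, 2 * np.pi))
        )
        channels.append(noise + env * carrier + hum + drift)
    ids = tuple(f"emg{c}" for c in range(cfg.n_channels))
    return EMGRecording(np.vstack(channels), cfg.fs, ids)


def generate_recording(cfg: SynthConfig) -> tuple[EMGRecording, GroundTruth]:
    """Schedule + render in one call."""
    gt = generate_schedule(cfg)
    return render_signal(gt, cfg), gt


#: Template emulating the free-living corpus structure: ~12 h days with a
#: handful of meals/snacks and a ~5.8% eating fraction.
DATASET_TEMPLATE = SynthConfig(duration=43200.0, n_events=4)


def generate_dataset(
    n_participants: int,
    cfg: SynthConfig = DATASET_TEMPLATE,
    master_seed: int = 0,
    eating_fraction_bounds: tuple[float, float] | None = (0.04, 0.08),
    render: bool = True,
) -> tuple[list[Participant], list[GroundTruth]]:
    """Per-participant recordings and ground truth from derived seeds.

    Per-participant seeds are derived from ``master_seed`` so the dataset is
    reproducible and participants are independent.  When
    ``eating_fraction_bounds`` is set, each participant's schedule is
    re-drawn (with a fresh derived seed) until its eating fraction falls in
    the bounds.  With ``render=False`` only schedules are generated (cheap;
    the recordings of the returned participants are 1-sample placeholders).
    """
    if n_participants < 1:
        raise ValidationError("need n_participants >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(
        n_participants * 64
    ) % (2**31)
    participants: list[Participant] = []
    truths: list[GroundTruth] = []
    for i in range(n_participants):
        gt = None
        for attempt in range(50):
            seed = int(seeds[i * 64 + attempt % 64])
            pcfg = replace(cfg, seed=seed)
            cand = generate_schedule(pcfg)
            frac = cand.reference.total_duration / cfg.duration
            if eating_fraction_bounds is None or (
                eating_fraction_bounds[0] <= frac <= eating_fraction_bounds[1]
            ):
                gt = cand
                break
        if gt is None:
            raise ValidationError(
                "could not draw a schedule inside the eating-fraction bounds"
            )
        if render:
            rec = render_signal(gt, pcfg)
        else:
            rec = EMGRecording(
                np.zeros((cfg.n_channels, 1)),
                cfg.fs,
                tuple(f"emg{c}" for c in range(cfg.n_channels)),
            )
        participants.append(Participant(f"p{i:02d}", rec, gt.reference))
        truths.append(gt)
    return participants, truths
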