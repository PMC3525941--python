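"""Stimulus scheduling and audio synthesis for dichotic streaming trials.

One trial presents two competing periodic tone streams, one per ear: 8 tones
at 512 Hz to the left ear interleaved with 7 tones at 768 Hz to the right ear.
Three timing conditions are supported:

``FP``
    fixed phase — both streams share a 492.2 ms period and the right stream
    starts half a period (246.1 ms) after the left, so the relative phase of
    the streams is constant.
``DP``
    drifting phase — the right stream's period is 546.9 ms while the left
    stays at 492.2 ms, and the right stream starts 109.4 ms after the left;
    the cross-stream phase drifts by 54.7 ms per stimulus.
``FP500``
    fixed phase with round numbers — both periods exactly 500 ms, offset
    exactly 250 ms.

Each tone is a 150 ms sawtooth with 5 ms raised-cosine rise/fall ramps.
*Standard* tones are amplitude-modulated to 100% depth by a raised sine
(42.67 Hz on the left, 36.57 Hz on the right — one modulation period is
exactly 6 or 7 samples of a 256 Hz EEG recording); *target* tones, which
listeners count, are unmodulated. The first two tones of each stream are
always standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StreamParams",
    "ConditionSpec",
    "StimulusEvent",
    "TrialSchedule",
    "build_condition",
    "make_trial",
    "make_run",
    "synthesize_audio",
    "events_to_frame",
    "write_event_tsv",
]

CONDITION_NAMES = ("FP", "DP", "FP500")

#: indices 0 and 1 of each stream are always standards
N_LEADING_STANDARDS = 2

EVENT_COLUMNS = ["trial_id", "condition", "attended", "stream", "index", "onset_s", "kind"]


@dataclass(frozen=True)
class StreamParams:
    """Timing and tone parameters of one ear's stimulus stream."""

    ear: str  # "left" or "right"
    fundamental_hz: float
    soa_s: float
    first_onset_s: float
    n_stimuli: int
    am_hz: float
    tone_duration_s: float = 0.150
    ramp_s: float = 0.005

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {self.ear!r}")
        if not self.soa_s > self.tone_duration_s:
            raise ValueError("soa_s must exceed tone_duration_s")
        if self.n_stimuli < 3:
            raise ValueError("need at least 3 stimuli per stream")
        if not self.am_hz > 0:
            raise ValueError("am_hz must be positive")

    def onsets(self) -> np.ndarray:
        """Stimulus onset times in seconds from trial sound start."""
        return self.first_onset_s + self.soa_s * np.arange(self.n_stimuli)


@dataclass(frozen=True)
class ConditionSpec:
    """A named pair of left/right stream parameterizations."""

    name: str
    left: StreamParams
    right: StreamParams


@dataclass(frozen=True)
class StimulusEvent:
    stream: str  # "left" or "right"
    index: int  # 0-based position within its stream
    onset_s: float
    kind: str  # "standard" or "target"


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered, timed stimulus events for one cued-attention trial."""

    condition: str
    attended: str  # "left" or "right"
    events: tuple[StimulusEvent, ...]
    n_targets_left: int
    n_targets_right: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    def stream_events(self, stream: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.stream == stream)


def build_condition(name: str) -> ConditionSpec:
    """Return the stream parameters of a named stimulus condition.

    Left stream: 8 tones at 512 Hz, 42.67 Hz standard modulation.
    Right stream: 7 tones at 768 Hz, 36.57 Hz standard modulation.
    Timing (SOAs and cross-stream offset) depends on the condition; see the
    module docstring.
    """
    if name not in CONDITION_NAMES:
        raise ValueError(
            f"unknown condition {name!r}; valid names are {', '.join(CONDITION_NAMES)}"
        )
    # standard-tone AM periods are exactly 6 (left) and 7 (right) samples of a
    # 256 Hz EEG recording: 42.67 and 36.57 Hz to printed precision
    left = StreamParams(
        ear="left", fundamental_hz=512.0, soa_s=0.4922, first_onset_s=0.0,
        n_stimuli=8, am_hz=256.0 / 6,
    )
    right = StreamParams(
        ear="right", fundamental_hz=768.0, soa_s=0.4922, first_onset_s=0.2461,
        n_stimuli=7, am_hz=256.0 / 7,
    )
    if name == "DP":
        right = replace(right, soa_s=0.5469, first_onset_s=0.1094)
    elif name == "FP500":
        left = replace(left, soa_s=0.500)
        right = replace(right, soa_s=0.500, first_onset_s=0.250)
    return ConditionSpec(name=name, left=left, right=right)


def _draw_targets(n_stimuli: int, n_targets: int | None, rng: np.random.Generator) -> np.ndarray:
    eligible = np.arange(N_LEADING_STANDARDS, n_stimuli)
    if n_targets is None:
        n_targets = int(rng.integers(1, 4))
    if not 1 <= n_targets <= 3:
        raise ValueError(f"target count must be in 1..3, got {n_targets}")
    if n_targets > eligible.size:
        raise ValueError(
            f"requested {n_targets} targets but only {eligible.size} eligible positions"
        )
    return np.sort(rng.choice(eligible, size=n_targets, replace=False))


def make_trial(
    cond: ConditionSpec,
    attended: str,
    rng: np.random.Generator,
    n_targets_left: int | None = None,
    n_targets_right: int | None = None,
) -> TrialSchedule:
    """Build one trial: merge the two streams and assign target positions.

    Target counts, when not given, are drawn uniformly and independently from
    {1, 2, 3} per stream; target positions are drawn uniformly without
    replacement among indices >= 2 (the first two tones of each stream are
    always standards). Events are returned merged and sorted by onset.
    """
    if attended not in ("left", "right"):
        raise ValueError(f"attended must be 'left' or 'right', got {attended!r}")
    events: list[StimulusEvent] = []
    counts = {}
    for params, requested in ((cond.left, n_targets_left), (cond.right, n_targets_right)):
        targets = _draw_targets(params.n_stimuli, requested, rng)
        counts[params.ear] = targets.size
        for i, onset in enumerate(params.onsets()):
            kind = "target" if i in targets else "standard"
            events.append(StimulusEvent(stream=params.ear, index=i, onset_s=float(onset), kind=kind))
    events.sort(key=lambda e: (e.onset_s, e.stream))
    return TrialSchedule(
        condition=cond.name,
        attended=attended,
        events=tuple(events),
        n_targets_left=counts["left"],
        n_targets_right=counts["right"],
    )


def make_run(cond: ConditionSpec, n_trials: int, rng: np.random.Generator) -> list[TrialSchedule]:
    """Build a run of trials, half attend-left and half attend-right, in random order."""
    if n_trials % 2:
        raise ValueError(f"n_trials must be even, got {n_trials}")
    labels = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials // 2))
    rng.shuffle(labels)
    return [make_trial(cond, attended, rng) for attended in labels]


def _bandlimited_sawtooth(f0: float, t: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Additive-synthesis sawtooth with harmonics up to Nyquist, phase 0 at t=0.

    sawtooth(x) = -(2/pi) * sum_k sin(2 pi k f0 x) / k, unit peak for the
    ideal wave; truncating the series at Nyquist anti-aliases it.
    """
    n_harmonics = max(1, int(np.floor((sample_rate_hz / 2) / f0)))
    k = np.arange(1, n_harmonics + 1)
    # outer product kept small: len(t) ~ 6615 samples, <= ~43 harmonics
    return -(2 / np.pi) * (np.sin(2 * np.pi * f0 * np.outer(k, t)) / k[:, None]).sum(axis=0)


def _tone(params: StreamParams, kind: str, sample_rate_hz: float) -> np.ndarray:
    n = int(round(params.tone_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    wave = _bandlimited_sawtooth(params.fundamental_hz, t, sample_rate_hz)
    if kind == "standard":
        # raised-sine AM, 100% depth: envelope minimum is exactly 0
        wave = wave * 0.5 * (1.0 - np.cos(2 * np.pi * params.am_hz * t))
    ramp_n = int(round(params.ramp_s * sample_rate_hz))
    if ramp_n:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        wave[:ramp_n] *= ramp
        wave[-ramp_n:] *= ramp[::-1]
    return wave


def synthesize_audio(
    trial: TrialSchedule,
    sample_rate_hz: float = 44100.0,
    cond: ConditionSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a trial to a stereo waveform plus a per-sample event marker track.

    Returns ``(audio, markers)`` where ``audio`` has shape (n_samples, 2)
    (column 0 = left ear, column 1 = right ear) and ``markers`` is an integer
    vector, nonzero exactly at stimulus-onset samples (1 = left stream,
    2 = right stream).
    """
    if sample_rate_hz < 8000:
        raise ValueError("sample_rate_hz must be at least 8000")
    if cond is None:
        cond = build_condition(trial.condition)
    params = {"left": cond.left, "right": cond.right}
    tail = max(p.tone_duration_s for p in params.values())
    duration = max(e.onset_s for e in trial.events) + tail + 0.05
    n_samples = int(np.ceil(duration * sample_rate_hz))
    audio = np.zeros((n_samples, 2))
    markers = np.zeros(n_samples, dtype=np.int8)
    channel = {"left": 0, "right": 1}
    for ev in trial.events:
        start = int(round(ev.onset_s * sample_rate_hz))
        tone = _tone(params[ev.stream], ev.kind, sample_rate_hz)
        audio[start:start + tone.size, channel[ev.stream]] += tone
        markers[start] = 1 if ev.stream == "left" else 2
    return audio, markers


def events_to_frame(trials: list[TrialSchedule]) -> pd.DataFrame:
    """Flatten trial schedules to a tidy event table (one row per stimulus)."""
    rows = [
        (tid, tr.condition, tr.attended, e.stream, e.index, e.onset_s, e.kind)
        for tid, tr in enumerate(trials)
        for e in tr.events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_event_tsv(trials: list[TrialSchedule], path) -> None:
    """Write the event table as UTF-8 TSV with '.' decimal separator."""
    events_to_frame(trials).to_csv(path, sep="\t", index=False, encoding="utf-8")
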