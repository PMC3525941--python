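"""Synthetic EEG, ERP, and gaze generation for the streaming-attention task.

The generative model is deliberately minimal and mirrors the structure the
decoding chain assumes:

* every stimulus evokes the same biphasic response — a one-cycle wavelet with
  a negative peak at 100 ms and a positive peak at 300 ms — whose amplitude is
  a factor ``attended_gain`` (default 1.2, i.e. 20%) larger when the stimulus
  belongs to the attended stream;
* the single-source response is projected to the electrodes through a fixed
  per-channel gain vector (a fronto-central topography by default);
* additive pink (1/f power) noise, independent per channel, with a standard
  deviation ``sd_ratio`` (default 2.0) times that of the channel's noiseless
  signal;
* optionally, a horizontal gaze trace that drifts exponentially toward the
  attended side after the directional cue.

With ``n_channels=1`` and unit gain this reduces to the single-channel
simulation used to compare fixed-phase and drifting-phase stimulus designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import ConditionSpec, TrialSchedule, build_condition, make_run

__all__ = [
    "ERPModel",
    "NoiseModel",
    "GazeModel",
    "Recording",
    "SubjectData",
    "MONTAGE_16",
    "biphasic_wavelet",
    "pink_noise",
    "simulate_recording",
    "simulate_gaze",
    "simulate_cohort",
]

#: extended 10-20 positions of the 16-electrode cap
MONTAGE_16 = (
    "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CP4", "P3", "Pz", "P4", "PO7", "PO8", "Oz",
)

# fronto-central projection of the auditory source: strongest at Cz/Fz,
# fading toward posterior sites (arbitrary units)
_DEFAULT_GAINS_16 = np.array(
    [0.7, 0.9, 0.7, 0.4, 0.6, 1.0, 0.6, 0.4,
     0.5, 0.5, 0.35, 0.4, 0.35, 0.2, 0.2, 0.2]
)


@dataclass
class ERPModel:
    """Single-source biphasic ERP: shape, attention gain, channel projection."""

    wavelet_duration_s: float = 0.4
    neg_peak_s: float = 0.1
    pos_peak_s: float = 0.3
    attended_gain: float = 1.2
    channel_gains: np.ndarray | None = None  # None -> montage default / ones
    latency_jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.neg_peak_s < self.pos_peak_s < self.wavelet_duration_s:
            raise ValueError("need 0 < neg_peak_s < pos_peak_s < wavelet_duration_s")
        if self.attended_gain < 1:
            raise ValueError("attended_gain must be >= 1")


@dataclass
class NoiseModel:
    """Additive pink-noise model; ``sd_ratio`` = noise SD / noiseless-signal SD."""

    kind: str = "pink"
    sd_ratio: float = 2.0
    independent_per_channel: bool = True

    def __post_init__(self) -> None:
        if self.kind != "pink":
            raise ValueError(f"unsupported noise kind {self.kind!r}")
        if not self.sd_ratio >= 0:
            raise ValueError("sd_ratio must be nonnegative")


@dataclass
class GazeModel:
    """Horizontal gaze drift toward the attended side (screen units)."""

    drift_gain: float = 0.2
    time_constant_s: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not self.time_constant_s > 0:
            raise ValueError("time_constant_s must be positive")


@dataclass
class Recording:
    """A channels x samples EEG-like recording with stimulus events.

    ``events`` has one row per stimulus with columns ``trial_id``, ``stream``,
    ``index``, ``kind``, ``onset_sample``; ``attended`` holds one label per
    trial.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame
    attended: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if len(self.events) and int(self.events["onset_sample"].max()) >= self.data.shape[1]:
            raise ValueError("event sample index beyond end of recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def biphasic_wavelet(model: ERPModel, fs_hz: float) -> np.ndarray:
    """Sample the one-cycle biphasic wavelet at ``fs_hz``; unit peak amplitude.

    The default shape is w(t) = -sin(2*pi*t / 0.4) on t in [0, 0.4 s): one
    negative-then-positive sine cycle, extrema at 100 and 300 ms.  For other
    requested peak latencies the sine's phase is piecewise-linearly warped so
    the extrema land at ``neg_peak_s`` and ``pos_peak_s``.
    """
    n = int(round(model.wavelet_duration_s * fs_hz))
    if n < 8:
        raise ValueError("wavelet too short at this sampling rate (need >= 8 samples)")
    t = np.arange(n) / fs_hz
    knots_t = [0.0, model.neg_peak_s, model.pos_peak_s, model.wavelet_duration_s]
    knots_phase = [0.0, 0.5 * np.pi, 1.5 * np.pi, 2.0 * np.pi]
    phase = np.interp(t, knots_t, knots_phase)
    return -np.sin(phase)


def pink_noise(
    n_samples: int,
    target_sd: float,
    rng: np.random.Generator,
    fs_hz: float = 256.0,
    floor_hz: float | None = None,
) -> np.ndarray:
    """Pink (1/f power) noise, zero mean, SD rescaled exactly to ``target_sd``.

    Synthesized in the frequency domain: independent Gaussian spectral
    coefficients with amplitude proportional to 1/sqrt(f), flattened below
    ``floor_hz`` (default: the lowest nonzero frequency bin) and zero at DC.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    floor = freqs[1] if floor_hz is None else floor_hz
    amp = 1.0 / np.sqrt(np.maximum(freqs, floor))
    amp[0] = 0.0
    n_bins = freqs.size
    spectrum = amp * (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins))
    x = np.fft.irfft(spectrum, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0 and target_sd > 0:
        x *= target_sd / sd
    elif target_sd == 0:
        x[:] = 0.0
    return x


def _resolve_gains(erp: ERPModel, n_channels: int) -> np.ndarray:
    if erp.channel_gains is not None:
        gains = np.asarray(erp.channel_gains, dtype=float)
        if gains.size != n_channels:
            raise ValueError(
                f"channel_gains has length {gains.size}, expected {n_channels}"
            )
        return gains
    if n_channels == 16:
        return _DEFAULT_GAINS_16.copy()
    return np.ones(n_channels)


def _default_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels == 16:
        return MONTAGE_16
    return tuple(f"ch{i}" for i in range(n_channels))


def simulate_recording(
    trials: list[TrialSchedule],
    erp: ERPModel,
    noise: NoiseModel,
    fs_hz: float = 256.0,
    n_channels: int = 16,
    rng: np.random.Generator | None = None,
    pre_s: float = 0.5,
    post_s: float = 1.0,
) -> Recording:
    """Simulate one continuous multichannel recording of a trial sequence.

    Each trial contributes an impulse train (amplitude ``attended_gain`` at
    attended-stream onsets, 1.0 at unattended onsets) convolved with the
    biphasic wavelet; the source series is projected through the channel
    gains.  Pink noise is then added per channel with SD equal to
    ``noise.sd_ratio`` times that channel's noiseless-signal SD, measured over
    the stimulation interval (first stimulus onset to last wavelet offset of
    each trial).  Trials are laid out back to back with ``pre_s`` of lead-in
    and ``post_s`` of tail per trial.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if rng is None:
        rng = np.random.default_rng()
    gains = _resolve_gains(erp, n_channels)
    wavelet = biphasic_wavelet(erp, fs_hz)

    trial_span = max(
        max(e.onset_s for e in tr.events) for tr in trials
    ) + erp.wavelet_duration_s
    pre_n = int(round(pre_s * fs_hz))
    seg_n = pre_n + int(np.ceil((trial_span + post_s) * fs_hz))
    n_samples = seg_n * len(trials)

    source = np.zeros(n_samples)
    stim_mask = np.zeros(n_samples, dtype=bool)
    rows = []
    for tid, tr in enumerate(trials):
        t0 = tid * seg_n + pre_n
        first = last = None
        for ev in tr.events:
            onset = ev.onset_s
            if erp.latency_jitter_sd_s > 0:
                onset = onset + rng.normal(0.0, erp.latency_jitter_sd_s)
            s = t0 + int(round(onset * fs_hz))
            amp = erp.attended_gain if ev.stream == tr.attended else 1.0
            source[s] += amp
            rows.append((tid, ev.stream, ev.index, ev.kind, s))
            first = s if first is None else min(first, s)
            last = s if last is None else max(last, s)
        stim_mask[first:last + wavelet.size] = True
    source = np.convolve(source, wavelet)[:n_samples]

    clean = gains[:, None] * source[None, :]
    data = clean.copy()
    if noise.sd_ratio > 0:
        for c in range(n_channels):
            signal_sd = clean[c, stim_mask].std()
            data[c] += pink_noise(
                n_samples, noise.sd_ratio * signal_sd, rng, fs_hz=fs_hz
            )

    events = pd.DataFrame(
        rows, columns=["trial_id", "stream", "index", "kind", "onset_sample"]
    )
    return Recording(
        data=data,
        fs_hz=fs_hz,
        channel_labels=_default_labels(n_channels),
        events=events,
        attended=tuple(tr.attended for tr in trials),
    )


def simulate_gaze(
    trials: list[TrialSchedule],
    gaze: GazeModel,
    rng: np.random.Generator,
    fs_hz: float = 60.0,
    cue_s: float = 2.0,
    duration_s: float = 6.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial horizontal/vertical gaze traces from cue onset.

    Returns ``(times, horizontal, vertical)``: ``times`` runs from ``-cue_s``
    (cue presentation) to ``duration_s - cue_s`` with the sound starting at 0;
    ``horizontal``/``vertical`` have shape (n_trials, n_samples).  The
    horizontal trace approaches +/-``drift_gain`` (positive = attend-right)
    exponentially with the model's time constant; the vertical trace is pure
    noise around fixation.
    """
    n = int(round(duration_s * fs_hz))
    times = np.arange(n) / fs_hz - cue_s
    h = np.empty((len(trials), n))
    v = np.empty((len(trials), n))
    drift_shape = 1.0 - np.exp(-(times + cue_s) / gaze.time_constant_s)
    for i, tr in enumerate(trials):
        sign = 1.0 if tr.attended == "right" else -1.0
        h[i] = sign * gaze.drift_gain * drift_shape + gaze.noise_sd * rng.standard_normal(n)
        v[i] = gaze.noise_sd * rng.standard_normal(n)
    return times, h, v


@dataclass
class SubjectData:
    """One simulated subject: EEG runs per condition, gaze traces, parameters."""

    subject_id: int
    params: dict
    runs: dict  # condition -> list of (list[TrialSchedule], Recording)
    gaze: dict  # condition -> (times, horizontal, vertical) pooled over runs

    def labels(self, condition: str) -> list[str]:
        out: list[str] = []
        for trials, _rec in self.runs[condition]:
            out.extend(tr.attended for tr in trials)
        return out


def simulate_cohort(
    n_subjects: int,
    rng: np.random.Generator,
    conditions: tuple[str, ...] = ("FP", "DP"),
    n_runs: int = 6,
    trials_per_run: int = 20,
    attended_gain_range: tuple[float, float] = (1.1, 1.3),
    sd_ratio_range: tuple[float, float] = (1.5, 2.5),
    drift_gain_range: tuple[float, float] = (0.0, 0.3),
    fs_hz: float = 256.0,
    n_channels: int = 16,
    with_gaze: bool = False,
) -> list[SubjectData]:
    """Simulate a cohort: per-subject effect sizes drawn from stated ranges.

    Each subject gets ``n_runs`` runs of ``trials_per_run`` trials in every
    requested condition, with subject-specific attention gain, noise level,
    and (optionally) gaze drift drawn uniformly from the given ranges.
    """
    for lo, hi in (attended_gain_range, sd_ratio_range, drift_gain_range):
        if hi < lo:
            raise ValueError("parameter range upper bound below lower bound")
    cohort = []
    for sid in range(n_subjects):
        params = {
            "attended_gain": float(rng.uniform(*attended_gain_range)),
            "sd_ratio": float(rng.uniform(*sd_ratio_range)),
            "drift_gain": float(rng.uniform(*drift_gain_range)),
        }
        erp = ERPModel(attended_gain=params["attended_gain"])
        noise = NoiseModel(sd_ratio=params["sd_ratio"])
        runs: dict = {}
        gaze_out: dict = {}
        for cname in conditions:
            cond = build_condition(cname)
            run_list = []
            all_trials: list[TrialSchedule] = []
            for _ in range(n_runs):
                trials = make_run(cond, trials_per_run, rng)
                rec = simulate_recording(
                    trials, erp, noise, fs_hz=fs_hz, n_channels=n_channels, rng=rng
                )
                run_list.append((trials, rec))
                all_trials.extend(trials)
            runs[cname] = run_list
            if with_gaze:
                gm = GazeModel(drift_gain=params["drift_gain"])
                gaze_out[cname] = simulate_gaze(all_trials, gm, rng)
        cohort.append(SubjectData(subject_id=sid, params=params, runs=runs, gaze=gaze_out))
    return cohort
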