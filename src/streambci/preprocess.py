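"""Online signal-processing chain: band-pass filter, epoching, difference features.

The decoding chain band-pass filters the multichannel recording between 0.1
and 8 Hz (Butterworth, order 6, causal in online mode), discards the first
two stimuli of each stream, extracts overlapping 600 ms epochs starting at
every remaining stimulus onset, and maintains per-trial running averages of
the left-locked epochs (X_L) and right-locked epochs (X_R).  The classifier
feature is their difference X_delta = X_R - X_L, updated every time a new
epoch becomes available and read out at the end of the trial.

A zero-phase variant of the filter (0.1-45 Hz, forward-backward) is used for
visualization-style grand averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal

from .synthgen import Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "DifferenceFeature",
    "ONLINE_FILTER",
    "VISUALIZATION_FILTER",
    "bandpass",
    "common_average_reference",
    "extract_epochs",
    "running_difference",
    "batch_difference",
    "trial_features",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``causal=True`` applies a forward-only filter (introduces group delay, as
    in real-time operation); ``causal=False`` applies it forward-backward for
    zero phase distortion.
    """

    low_hz: float
    high_hz: float
    order: int = 6
    causal: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs_hz: float) -> np.ndarray:
        if self.high_hz >= fs_hz / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz not below Nyquist ({fs_hz / 2} Hz)"
            )
        sos = signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=fs_hz, output="sos",
        )
        # poles must sit inside the unit circle with a numerically usable
        # margin; extremely narrow bands produce poles so close to the circle
        # that the filter never settles in finite precision
        poles = np.concatenate([np.roots(sec[3:]) for sec in sos])
        if np.any(np.abs(poles) >= 1.0 - 1e-6):
            raise ValueError(
                f"unstable filter design: band [{self.low_hz}, {self.high_hz}] Hz "
                f"too narrow for order {self.order} at fs={fs_hz} Hz"
            )
        return sos


#: causal online decoding filter
ONLINE_FILTER = FilterSpec(low_hz=0.1, high_hz=8.0, order=6, causal=True)
#: zero-phase broadband filter for grand-average visualization
VISUALIZATION_FILTER = FilterSpec(low_hz=0.1, high_hz=45.0, order=6, causal=False)


def bandpass(recording: Recording, spec: FilterSpec = ONLINE_FILTER) -> Recording:
    """Band-pass filter every channel; filter state runs across the whole recording."""
    sos = spec.sos(recording.fs_hz)
    if spec.causal:
        data = signal.sosfilt(sos, recording.data, axis=1)
    else:
        data = signal.sosfiltfilt(sos, recording.data, axis=1)
    return _dc_replace(recording, data=np.asarray(data))


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the across-channel mean from every channel, per sample."""
    if recording.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return _dc_replace(recording, data=data)


@dataclass
class EpochSet:
    """Stimulus-locked windows: epochs (n, channels, samples) plus labels."""

    epochs: np.ndarray
    stream: np.ndarray  # per-epoch "left"/"right"
    trial_id: np.ndarray
    onset_sample: np.ndarray
    fs_hz: float
    window_s: float
    channel_labels: tuple[str, ...] = ()

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def for_trial(self, tid: int) -> "EpochSet":
        """Epochs of one trial, in stimulus-onset order."""
        mask = self.trial_id == tid
        order = np.argsort(self.onset_sample[mask], kind="stable")
        idx = np.flatnonzero(mask)[order]
        return EpochSet(
            epochs=self.epochs[idx], stream=self.stream[idx],
            trial_id=self.trial_id[idx], onset_sample=self.onset_sample[idx],
            fs_hz=self.fs_hz, window_s=self.window_s,
            channel_labels=self.channel_labels,
        )

    def trial_ids(self) -> np.ndarray:
        return np.unique(self.trial_id)


def extract_epochs(
    recording: Recording,
    window_s: float = 0.6,
    skip_per_stream: int = 2,
) -> EpochSet:
    """Cut stimulus-locked epochs, skipping the first stimuli of each stream.

    Each retained stimulus yields one epoch of ``floor(window_s * fs)``
    samples (153 at 256 Hz) starting exactly at its onset sample.  The first
    ``skip_per_stream`` stimuli of each stream in each trial are disregarded.
    """
    n_win = int(np.floor(window_s * recording.fs_hz))
    ev = recording.events
    keep = ev["index"] >= skip_per_stream
    kept = ev[keep]
    ends = kept["onset_sample"].to_numpy() + n_win
    bad = kept[ends > recording.n_samples]
    if len(bad):
        raise ValueError(
            "epochs extend past the end of the recording for events: "
            + ", ".join(
                f"(trial {r.trial_id}, {r.stream} idx {r.index})"
                for r in bad.itertuples()
            )
        )
    onsets = kept["onset_sample"].to_numpy()
    idx = onsets[:, None] + np.arange(n_win)[None, :]
    epochs = recording.data[:, idx].transpose(1, 0, 2)  # (n, channels, samples)
    return EpochSet(
        epochs=epochs,
        stream=kept["stream"].to_numpy(),
        trial_id=kept["trial_id"].to_numpy(),
        onset_sample=onsets,
        fs_hz=recording.fs_hz,
        window_s=window_s,
        channel_labels=recording.channel_labels,
    )


@dataclass
class DifferenceFeature:
    """X_delta = running mean of right-locked epochs minus left-locked, one trial."""

    x_delta: np.ndarray  # channels x samples
    n_left_epochs: int
    n_right_epochs: int


def running_difference(trial_epochs: EpochSet) -> list[DifferenceFeature]:
    """Running difference-of-averages snapshots for one trial.

    Epochs must belong to a single trial and be in onset order (use
    ``EpochSet.for_trial``).  One snapshot is emitted after every epoch; until
    a stream has contributed its first epoch its running mean is a zero
    matrix.  The final snapshot uses all retained epochs of the trial.
    """
    if trial_epochs.n_epochs == 0:
        raise ValueError("trial has no epochs")
    if np.unique(trial_epochs.trial_id).size > 1:
        raise ValueError("running_difference operates on a single trial")
    shape = trial_epochs.epochs.shape[1:]
    sums = {"left": np.zeros(shape), "right": np.zeros(shape)}
    counts = {"left": 0, "right": 0}
    out: list[DifferenceFeature] = []
    for ep, stream in zip(trial_epochs.epochs, trial_epochs.stream):
        sums[stream] += ep
        counts[stream] += 1
        mean_l = sums["left"] / counts["left"] if counts["left"] else np.zeros(shape)
        mean_r = sums["right"] / counts["right"] if counts["right"] else np.zeros(shape)
        out.append(
            DifferenceFeature(
                x_delta=mean_r - mean_l,
                n_left_epochs=counts["left"],
                n_right_epochs=counts["right"],
            )
        )
    return out


def batch_difference(trial_epochs: EpochSet) -> DifferenceFeature:
    """Batch X_delta of one trial: mean right-locked minus mean left-locked."""
    left = trial_epochs.epochs[trial_epochs.stream == "left"]
    right = trial_epochs.epochs[trial_epochs.stream == "right"]
    shape = trial_epochs.epochs.shape[1:]
    mean_l = left.mean(axis=0) if len(left) else np.zeros(shape)
    mean_r = right.mean(axis=0) if len(right) else np.zeros(shape)
    return DifferenceFeature(
        x_delta=mean_r - mean_l, n_left_epochs=len(left), n_right_epochs=len(right)
    )


def trial_features(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Final X_delta per trial, stacked: returns (features, trial_ids).

    ``features`` has shape (n_trials, channels, samples), ordered by trial id.
    """
    tids = epochs.trial_ids()
    feats = np.stack(
        [batch_difference(epochs.for_trial(t)).x_delta for t in tids]
    )
    return feats, tids
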