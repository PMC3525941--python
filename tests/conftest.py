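import numpy as np
import pytest

from streambci.schedule import build_condition, make_trial
from streambci.synthgen import ERPModel, NoiseModel, simulate_recording
from streambci.preprocess import ONLINE_FILTER, bandpass, extract_epochs, trial_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fp_condition():
    return build_condition("FP")


@pytest.fixture(scope="session")
def dp_condition():
    return build_condition("DP")


@pytest.fixture(scope="session")
def noiseless_fp_recording():
    """A small noiseless 2-channel FP recording (deterministic up to targets)."""
    rng = np.random.default_rng(7)
    cond = build_condition("FP")
    trials = [make_trial(cond, side, rng) for side in ("left", "right") * 3]
    erp = ERPModel(attended_gain=1.2, channel_gains=np.array([1.0, 0.5]))
    rec = simulate_recording(
        trials, erp, NoiseModel(sd_ratio=0.0), n_channels=2, rng=rng
    )
    return trials, rec


@pytest.fixture(scope="session")
def small_decoding_problem():
    """Preprocessed features for a modest 2-class FP problem with noise."""
    rng = np.random.default_rng(99)
    cond = build_condition("FP")
    trials = [make_trial(cond, side, rng) for side in ("left", "right") * 30]
    erp = ERPModel(attended_gain=1.2)
    rec = simulate_recording(
        trials, erp, NoiseModel(sd_ratio=1.0), n_channels=4, rng=rng
    )
    filtered = bandpass(rec, ONLINE_FILTER)
    epochs = extract_epochs(filtered)
    feats, tids = trial_features(epochs)
    labels = np.array([trials[t].attended for t in tids])
    return epochs, feats, labels
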