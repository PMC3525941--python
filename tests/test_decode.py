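"""Whitening, L2 logistic decoding, incremental protocol, control signal."""

import numpy as np
import pytest

from streambci.decode import (
    AttentionDecoder,
    ControlSignalSpec,
    classify_trial,
    control_signal,
    fit_whitener,
    incremental_protocol,
    train,
)
from streambci.preprocess import DifferenceFeature, trial_features


def _random_features(rng, n=40, ch=4, samp=20):
    feats = rng.standard_normal((n, ch, samp))
    labels = np.array(["left", "right"] * (n // 2))
    return feats, labels


class TestWhitener:
    def test_isotropic_covariance_closed_form(self, rng):
        # epochs built so the mean spatial covariance is exactly 4*I
        n_samp = 5001
        base = rng.standard_normal((3, n_samp))
        base -= base.mean(axis=1, keepdims=True)
        # orthonormalize rows then scale: covariance = 4*I exactly
        q, _ = np.linalg.qr(base.T)
        epoch = 2.0 * np.sqrt(n_samp - 1) * q.T[:3]
        w = fit_whitener(epoch[None, :, :], ridge=0.0)
        assert np.allclose(w.matrix, 0.5 * np.eye(3), atol=1e-9)

    def test_whitened_epochs_have_identity_mean_covariance(self, rng):
        from streambci.decode import _epoch_spatial_cov

        epochs = rng.standard_normal((50, 6, 30))
        w = fit_whitener(epochs, ridge=0.0)
        white = w.transform(epochs)
        sigma = np.mean([_epoch_spatial_cov(e) for e in white], axis=0)
        assert np.max(np.abs(sigma - np.eye(6))) < 1e-6

    def test_matrix_square_root_oracle(self, rng):
        # brute-force check: W @ W @ Sigma = I for random SPD Sigma
        a = rng.standard_normal((5, 5))
        sigma = a @ a.T + 0.5 * np.eye(5)
        epochs = rng.standard_normal((100, 5, 40))
        # construct epochs with exactly this covariance via coloring
        chol = np.linalg.cholesky(sigma)
        white = rng.standard_normal((1, 5, 5001))
        white -= white.mean(axis=2, keepdims=True)
        q, _ = np.linalg.qr(white[0].T)
        e = np.sqrt(5000) * (chol @ q.T[:5])
        w = fit_whitener(e[None], ridge=0.0)
        assert np.allclose(w.matrix @ w.matrix @ sigma, np.eye(5), atol=1e-8)
        assert np.allclose(w.matrix, w.matrix.T, atol=1e-12)

    def test_singular_covariance_advises_ridge(self):
        epochs = np.zeros((3, 4, 10))
        with pytest.raises(ValueError, match="ridge"):
            fit_whitener(epochs, ridge=0.0)


class TestTraining:
    def test_label_swap_negates_weights_and_bias(self, rng):
        feats, labels = _random_features(rng)
        r1 = AttentionDecoder(feats, labels).fit()
        r2 = AttentionDecoder(
            feats, np.where(labels == "left", "right", "left")
        ).fit()
        assert np.max(np.abs(r1.weights + r2.weights)) < 1e-6
        assert abs(r1.bias + r2.bias) < 1e-6

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        feats, labels = _random_features(rng, n=20, ch=2, samp=5)
        feats[labels == "right", 0, 0] += 10.0
        res = AttentionDecoder(feats, labels, lam=1e-4).fit()
        assert res.training_accuracy() == 1.0

    def test_huge_lambda_shrinks_weights_to_zero(self, rng):
        feats, labels = _random_features(rng)
        res = AttentionDecoder(feats, labels, lam=1e8).fit()
        assert np.max(np.abs(res.weights)) < 1e-4
        outs = [res.score(f) for f in feats]
        assert np.ptp(outs) < 1e-3  # outputs collapse to the bias

    def test_single_class_rejected(self, rng):
        feats, _ = _random_features(rng, n=10)
        with pytest.raises(ValueError):
            AttentionDecoder(feats, ["left"] * 10)

    def test_refit_is_deterministic(self, rng):
        feats, labels = _random_features(rng)
        model = AttentionDecoder(feats, labels)
        r1, r2 = model.fit(), model.fit()
        assert np.array_equal(r1.weights, r2.weights)
        assert r1.bias == r2.bias

    def test_channel_mixing_equivariance(self, rng):
        """An invertible channel mixing is absorbed by the whitener."""
        ch = 4
        epochs = rng.standard_normal((60, ch, 25))
        feats, labels = _random_features(rng, n=30, ch=ch, samp=25)
        mix = rng.standard_normal((ch, ch)) + 3 * np.eye(ch)
        r1 = AttentionDecoder(
            feats, labels, whitener=fit_whitener(epochs, ridge=0.0)
        ).fit()
        mixed_epochs = np.einsum("ij,njk->nik", mix, epochs)
        mixed_feats = np.einsum("ij,njk->nik", mix, feats)
        r2 = AttentionDecoder(
            mixed_feats, labels, whitener=fit_whitener(mixed_epochs, ridge=0.0)
        ).fit()
        s1 = np.array([r1.score(f) for f in feats])
        s2 = np.array([r2.score(f) for f in mixed_feats])
        assert np.max(np.abs(s1 - s2)) < 1e-4

    def test_cv_lambda_selection_runs(self, rng):
        feats, labels = _random_features(rng, n=30)
        res = AttentionDecoder(feats, labels, lam="cv").fit()
        assert res.lam in np.logspace(-2, 2, 9)

    def test_summary_mentions_key_quantities(self, rng):
        feats, labels = _random_features(rng)
        text = AttentionDecoder(feats, labels).fit().summary()
        assert "lambda" in text and "training accuracy" in text


class TestScoring:
    def test_zero_feature_scores_bias(self, rng):
        feats, labels = _random_features(rng)
        res = train(feats, labels)
        assert res.score(np.zeros_like(feats[0])) == pytest.approx(res.bias)

    def test_negation_linearity(self, rng):
        feats, labels = _random_features(rng)
        res = train(feats, labels)
        x = rng.standard_normal(feats[0].shape)
        assert res.score(-x) - res.bias == pytest.approx(-(res.score(x) - res.bias))

    def test_matches_elementwise_sum_oracle(self, rng):
        feats, labels = _random_features(rng)
        res = train(feats, labels)
        x = rng.standard_normal(feats[0].shape)
        oracle = float(np.sum(res.weights * (res.whitener.matrix @ x)) + res.bias)
        assert res.score(x) == pytest.approx(oracle, rel=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        feats, labels = _random_features(rng)
        res = train(feats, labels)
        with pytest.raises(ValueError):
            res.score(np.zeros((2, 2)))

    def test_classify_trial_outputs_and_flip(self, rng):
        feats, labels = _random_features(rng)
        res = train(feats, labels)
        snaps = [DifferenceFeature(rng.standard_normal(feats[0].shape), 1, 1)
                 for _ in range(11)]
        outs, label = res.classify_trial(snaps)
        assert outs.shape == (11,)
        flipped = [DifferenceFeature(-s.x_delta, 1, 1) for s in snaps]
        # negate the bias' effect by comparing sign of (out - bias)
        outs_f, _ = res.classify_trial(flipped)
        assert np.allclose(outs_f - res.bias, -(outs - res.bias), atol=1e-9)

    def test_high_snr_noiseless_trial_is_classified_correctly(
        self, small_decoding_problem
    ):
        epochs, feats, labels = small_decoding_problem
        res = AttentionDecoder(feats, labels, lam=1.0).fit()
        from streambci.preprocess import running_difference

        # end-to-end: running snapshots of a training trial end at its label
        correct = 0
        for tid in epochs.trial_ids()[:10]:
            snaps = running_difference(epochs.for_trial(tid))
            _outs, label = classify_trial(res, snaps)
            correct += label == labels[tid]
        assert correct >= 9


class TestIncrementalProtocol:
    def _runs(self, rng, n_runs=3, n_trials=8, effect=2.0):
        from streambci.preprocess import EpochSet

        runs = []
        for _ in range(n_runs):
            labels = {}
            epochs, streams, tids, onsets = [], [], [], []
            for t in range(n_trials):
                lab = "right" if t % 2 else "left"
                labels[t] = lab
                sign = 1.0 if lab == "right" else -1.0
                for k in range(4):
                    e = rng.standard_normal((2, 10))
                    stream = "right" if k % 2 else "left"
                    if stream == "right":
                        e += sign * effect / 2
                    else:
                        e -= sign * effect / 2
                    epochs.append(e)
                    streams.append(stream)
                    tids.append(t)
                    onsets.append(t * 100 + k * 10)
            runs.append((
                EpochSet(
                    epochs=np.array(epochs), stream=np.array(streams),
                    trial_id=np.array(tids), onset_sample=np.array(onsets),
                    fs_hz=256.0, window_s=0.6,
                ),
                labels,
            ))
        return runs

    def test_scored_trial_count(self, rng):
        runs = self._runs(rng, n_runs=6, n_trials=20)
        res = incremental_protocol(runs)
        assert res["n_scored_trials"] == 100
        assert len(res["per_run_accuracy"]) == 5

    def test_strong_effect_decodes_well(self, rng):
        res = incremental_protocol(self._runs(rng, effect=4.0))
        assert res["accuracy_pct"] > 90

    def test_deterministic(self):
        r1 = incremental_protocol(self._runs(np.random.default_rng(0)))
        r2 = incremental_protocol(self._runs(np.random.default_rng(0)))
        assert r1["accuracy_pct"] == r2["accuracy_pct"]

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError):
            incremental_protocol(self._runs(rng, n_runs=1))


class TestControlSignal:
    def test_ema_impulse_response(self):
        # 4 Hz cannot resolve a 3 Hz low-pass, so the EMA stage is isolated
        with pytest.warns(UserWarning):
            out = control_signal(
                np.array([1.0, 0, 0, 0]),
                ControlSignalSpec(lowpass_cutoff_hz=3.0), update_rate_hz=4.0,
            )
        assert np.allclose(out, [0.5, 0.25, 0.125, 0.0625])

    def test_bypass_warns(self):
        with pytest.warns(UserWarning, match="bypass"):
            control_signal(np.zeros(4), update_rate_hz=4.0)

    def test_zero_in_zero_out(self):
        out = control_signal(np.zeros(100), update_rate_hz=20.0)
        assert np.allclose(out, 0.0)

    def test_constant_steady_state_preserves_level(self):
        out = control_signal(np.full(2000, 3.0), update_rate_hz=20.0)
        assert out[-1] == pytest.approx(3.0, rel=1e-3)

    def test_gain_offset_affine(self):
        spec = ControlSignalSpec(gain=2.0, offset=1.0)
        out = control_signal(np.full(2000, 3.0), spec, update_rate_hz=20.0)
        assert out[-1] == pytest.approx(2.0 * 3.0 + 1.0, rel=1e-3)
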