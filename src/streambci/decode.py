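"""Whitened, L2-regularized logistic-regression decoding of auditory attention.

The classifier operates on the per-trial difference features X_delta
(channels x samples).  Training has three stages:

1. *Symmetric whitening.*  The spatial covariance (channels x channels,
   computed within each training epoch after removing its time mean) is
   averaged across all training epochs; the features are premultiplied by the
   inverse matrix square root W = Sigma^(-1/2), so that the whitened training
   epochs have identity mean spatial covariance.
2. *Scaling.*  Whitened features are divided by a single global RMS scale so
   that the regularization strength is comparable across datasets.  A scalar
   (rather than per-dimension) scale keeps the objective invariant to
   invertible channel mixings, which whitening absorbs up to a rotation.
3. *L2-penalized linear logistic regression* on the flattened features, with
   attend-right coded as the positive class.  The objective is convex, so
   retraining on the same data reproduces the same weights.

The trial-level BCI output is the weighted sum of the whitened feature
values plus a bias; it is updated after every new epoch (roughly four times
per second in the fixed-phase design) and the *sign of its final value* is
the predicted direction of attention (positive = right; an exact zero is
broken toward right).

In online operation the classifier was retrained at the end of every run on
all runs gathered so far in the same stimulus condition
(:func:`incremental_protocol`), and for continuous control the un-thresholded
output was smoothed by an exponential moving average (decay 0.5) and an
8th-order 3 Hz Butterworth low-pass (:func:`control_signal`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from sklearn.linear_model import LogisticRegression

from .preprocess import DifferenceFeature, EpochSet, trial_features

__all__ = [
    "Whitener",
    "ControlSignalSpec",
    "AttentionDecoder",
    "AttentionDecoderResults",
    "fit_whitener",
    "train",
    "score",
    "classify_trial",
    "incremental_protocol",
    "control_signal",
]

LABELS = ("left", "right")  # right is the positive class


@dataclass(frozen=True)
class Whitener:
    """Symmetric whitening transform W = (Sigma + ridge*I)^(-1/2)."""

    matrix: np.ndarray
    ridge: float

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Whiten channels of one (channels x samples) matrix or a stack."""
        if x.ndim == 2:
            return self.matrix @ x
        return np.einsum("ij,njk->nik", self.matrix, x)


def _epoch_spatial_cov(epoch: np.ndarray) -> np.ndarray:
    """Spatial covariance of one channels x samples epoch, time mean removed."""
    centered = epoch - epoch.mean(axis=1, keepdims=True)
    return centered @ centered.T / (epoch.shape[1] - 1)


def fit_whitener(epochs: EpochSet | np.ndarray, ridge: float | None = None) -> Whitener:
    """Fit W = Sigma^(-1/2) from the mean spatial covariance of training epochs.

    ``ridge`` is a diagonal loading added to Sigma before inversion; the
    default is 1e-6 * trace(Sigma)/n_channels.  Pass ``ridge=0`` to disable
    loading (raises if Sigma is then numerically singular).
    """
    arr = epochs.epochs if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if arr.ndim != 3:
        raise ValueError("expected epochs with shape (n, channels, samples)")
    sigma = np.mean([_epoch_spatial_cov(e) for e in arr], axis=0)
    n_ch = sigma.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(sigma) / n_ch
    sigma_r = sigma + ridge * np.eye(n_ch)
    evals, evecs = np.linalg.eigh(sigma_r)
    if evals.min() <= 0 or evals.min() / evals.max() < 1e-12:
        raise ValueError(
            "training covariance is singular; supply a positive ridge "
            f"(smallest eigenvalue {evals.min():.3g})"
        )
    w = (evecs * (evals ** -0.5)) @ evecs.T
    return Whitener(matrix=w, ridge=float(ridge))


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= set(LABELS):
        raise ValueError(f"labels must be in {LABELS}")
    return (labels == "right").astype(int)


class AttentionDecoder:
    """Model object: per-trial X_delta features + attend-left/right labels.

    Parameters
    ----------
    features : ndarray, shape (n_trials, n_channels, n_samples)
        Final difference-of-averages feature of each trial.
    labels : sequence of {"left", "right"}
    whitener : Whitener, optional
        Spatial whitening transform.  Usually fitted from the training
        *epochs* (not the features); see :meth:`from_epochs`.  If omitted it
        is fitted from the features themselves.
    lam : float or "cv"
        L2 penalty strength on the scaled whitened features (default 1.0), or
        ``"cv"`` for 5-fold cross-validated selection over a log grid.
    ridge : float, optional
        Covariance diagonal loading used when the whitener must be fitted
        here.
    """

    def __init__(self, features, labels, whitener: Whitener | None = None,
                 lam: float | str = 1.0, ridge: float | None = None):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 3:
            raise ValueError("features must have shape (n_trials, channels, samples)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        self.y = _encode_labels(labels)
        if self.y.size != self.features.shape[0]:
            raise ValueError("labels length must match number of trials")
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data must contain both classes")
        if whitener is None:
            whitener = fit_whitener(self.features, ridge=ridge)
        self.whitener = whitener
        self.lam = lam

    @classmethod
    def from_epochs(cls, epochs: EpochSet, labels_by_trial: dict,
                    lam: float | str = 1.0, ridge: float | None = None
                    ) -> "AttentionDecoder":
        """Build the model from an EpochSet: whitener from the epochs,
        features as the per-trial batch X_delta."""
        whitener = fit_whitener(epochs, ridge=ridge)
        feats, tids = trial_features(epochs)
        labels = [labels_by_trial[t] for t in tids]
        return cls(feats, labels, whitener=whitener, lam=lam)

    def fit(self) -> "AttentionDecoderResults":
        """Fit the convex L2-logistic objective; deterministic optimum."""
        white = self.whitener.transform(self.features)
        scale = float(np.sqrt(np.mean(white ** 2)))
        if scale == 0:
            raise ValueError("all-zero features cannot be fitted")
        x = white.reshape(len(white), -1) / scale
        if self.lam == "cv":
            lam = self._select_lambda(x)
        else:
            lam = float(self.lam)
        clf = LogisticRegression(
            C=1.0 / lam, solver="lbfgs",
            tol=1e-12, max_iter=20000, fit_intercept=True,
        )
        clf.fit(x, self.y)
        weights = clf.coef_.reshape(self.features.shape[1:]) / scale
        return AttentionDecoderResults(
            model=self, weights=weights, bias=float(clf.intercept_[0]),
            lam=lam, scale=scale,
        )

    def _select_lambda(self, x: np.ndarray) -> float:
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        grid = np.logspace(-2, 2, 9)
        n_splits = min(5, int(np.min(np.bincount(self.y))))
        cv = StratifiedKFold(n_splits=max(2, n_splits))
        scores = []
        for lam in grid:
            clf = LogisticRegression(C=1.0 / lam, solver="lbfgs",
                                     tol=1e-8, max_iter=5000)
            scores.append(cross_val_score(clf, x, self.y, cv=cv).mean())
        return float(grid[int(np.argmax(scores))])


@dataclass
class AttentionDecoderResults:
    """Fitted decoder: whitening transform + linear read-out weights."""

    model: AttentionDecoder
    weights: np.ndarray  # channels x samples, applied to whitened features
    bias: float
    lam: float
    scale: float

    @property
    def whitener(self) -> Whitener:
        return self.model.whitener

    def score(self, x_delta: np.ndarray | DifferenceFeature) -> float:
        """Un-thresholded output: <weights, W @ x_delta> + bias (positive = right)."""
        if isinstance(x_delta, DifferenceFeature):
            x_delta = x_delta.x_delta
        x_delta = np.asarray(x_delta)
        if x_delta.shape != self.weights.shape:
            raise ValueError(
                f"feature shape {x_delta.shape} does not match weights "
                f"{self.weights.shape}"
            )
        return float(np.sum(self.weights * self.whitener.transform(x_delta)) + self.bias)

    def classify_trial(
        self, snapshots: list[DifferenceFeature] | list[np.ndarray]
    ) -> tuple[np.ndarray, str]:
        """Score every running-X_delta snapshot; label = sign of the final output.

        Returns ``(outputs, label)``; an exact zero final output is broken
        toward "right".
        """
        if not snapshots:
            raise ValueError("need at least one snapshot")
        outputs = np.array([self.score(s) for s in snapshots])
        return outputs, ("right" if outputs[-1] >= 0 else "left")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict labels for a stack of final X_delta features."""
        out = [
            "right" if self.score(f) >= 0 else "left"
            for f in np.asarray(features)
        ]
        return np.array(out)

    def training_accuracy(self) -> float:
        pred = self.predict(self.model.features)
        return float(np.mean(_encode_labels(pred) == self.model.y))

    def summary(self) -> str:
        m = self.model
        n_ch, n_samp = self.weights.shape
        lines = [
            "Attention decoder (whitened L2 logistic regression)",
            "=" * 52,
            f"trials:            {len(m.y)}  "
            f"(left {int(np.sum(m.y == 0))} / right {int(np.sum(m.y == 1))})",
            f"feature shape:     {n_ch} channels x {n_samp} samples",
            f"lambda (L2):       {self.lam:g}",
            f"covariance ridge:  {self.whitener.ridge:.3g}",
            f"bias:              {self.bias:+.4f}",
            f"|weights|:         {np.linalg.norm(self.weights):.4f}",
            f"training accuracy: {100 * self.training_accuracy():.1f}%",
        ]
        return "\n".join(lines)


def train(features, labels, lam: float | str = 1.0,
          whitener: Whitener | None = None) -> AttentionDecoderResults:
    """Functional entry point: fit the decoder on per-trial features."""
    return AttentionDecoder(features, labels, whitener=whitener, lam=lam).fit()


def score(results: AttentionDecoderResults, x_delta) -> float:
    return results.score(x_delta)


def classify_trial(results: AttentionDecoderResults, snapshots):
    return results.classify_trial(snapshots)


def incremental_protocol(
    runs: list[tuple[EpochSet, dict]],
    lam: float | str = 1.0,
    ridge: float | None = None,
) -> dict:
    """Online-style evaluation: run k is scored by the model trained on runs 1..k-1.

    ``runs`` is a list of ``(epochs, labels_by_trial)`` pairs in chronological
    order.  The first run only seeds the training set (it ran without
    feedback); each later run is classified with the decoder retrained on all
    earlier runs pooled.  Returns per-run accuracies, pooled accuracy in
    percent over the scored trials, and per-trial predictions.
    """
    if len(runs) < 2:
        raise ValueError("need at least one training run and one scored run")
    per_run_acc: list[float] = []
    correct = total = 0
    predictions: list[tuple[int, str, str]] = []  # (run, predicted, true)
    for k in range(1, len(runs)):
        train_feats, train_labels = [], []
        train_epochs = []
        for epochs, labmap in runs[:k]:
            f, tids = trial_features(epochs)
            train_feats.append(f)
            train_labels.extend(labmap[t] for t in tids)
            train_epochs.append(epochs.epochs)
        whitener = fit_whitener(np.concatenate(train_epochs), ridge=ridge)
        results = AttentionDecoder(
            np.concatenate(train_feats), train_labels, whitener=whitener, lam=lam
        ).fit()
        epochs_k, labmap_k = runs[k]
        f_k, tids_k = trial_features(epochs_k)
        pred = results.predict(f_k)
        truth = np.array([labmap_k[t] for t in tids_k])
        per_run_acc.append(float(np.mean(pred == truth)))
        correct += int(np.sum(pred == truth))
        total += len(truth)
        predictions.extend(zip([k] * len(truth), pred, truth))
    return {
        "per_run_accuracy": per_run_acc,
        "accuracy_pct": 100.0 * correct / total,
        "n_scored_trials": total,
        "predictions": predictions,
    }


@dataclass(frozen=True)
class ControlSignalSpec:
    """Smoothing chain for continuous control: EMA + Butterworth low-pass."""

    ema_decay: float = 0.5
    lowpass_order: int = 8
    lowpass_cutoff_hz: float = 3.0
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.ema_decay < 1:
            raise ValueError("ema_decay must be in (0, 1)")


def control_signal(
    outputs: np.ndarray,
    spec: ControlSignalSpec = ControlSignalSpec(),
    update_rate_hz: float = 4.0,
) -> np.ndarray:
    """Smooth classifier outputs into a continuous control (velocity) signal.

    The exponential moving average is the unit-DC-gain recursion
    ``y_k = (1 - decay) * x_k + decay * y_{k-1}``, followed by a causal
    Butterworth low-pass and an affine gain/offset.  If the update rate does
    not resolve the low-pass cutoff (rate <= 2 * cutoff) that stage is
    bypassed with a warning.
    """
    x = np.asarray(outputs, dtype=float)
    d = spec.ema_decay
    y = _sig.lfilter([1.0 - d], [1.0, -d], x)
    if update_rate_hz > 2 * spec.lowpass_cutoff_hz:
        sos = _sig.butter(spec.lowpass_order, spec.lowpass_cutoff_hz,
                          btype="lowpass", fs=update_rate_hz, output="sos")
        y = _sig.sosfilt(sos, y)
    else:
        warnings.warn(
            f"update rate {update_rate_hz} Hz cannot resolve a "
            f"{spec.lowpass_cutoff_hz} Hz low-pass; stage bypassed",
            stacklevel=2,
        )
    return spec.gain * y + spec.offset
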