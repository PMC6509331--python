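"""Lagged-sample features, shrinkage LDA, and sliding-window cross-validation.

Features are the raw microvolt samples of all good EEG channels on a lag grid
(200 ms spacing by default) inside a feature-extraction window, either centred
on the evaluation time (offline, non-causal) or trailing it (online, causal).
The classifier is a multiclass linear discriminant with a shrunk pooled
covariance

    Sigma_tilde = (1 - lambda) * Sigma_hat + lambda * nu * I,
    nu = mean diagonal of Sigma_hat,

with the shrinkage intensity lambda estimated analytically (Ledoit-Wolf) from
the within-class-centred data. Discriminant scores are passed through a
softmax to yield class probabilities. Accuracy curves come from repeated
stratified trial-based k-fold cross-validation (10 x 10 by default) of the
window slid along the trial in 1/16 s steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold

from .data import EpochSet

__all__ = [
    "FeatureWindowConfig",
    "SLDAModel",
    "AccuracyCurve",
    "extract_features",
    "fit_slda",
    "predict_proba",
    "sliding_accuracy",
    "confusion_at",
]


@dataclass(frozen=True)
class FeatureWindowConfig:
    """Feature-extraction window: length, lag spacing, alignment, slide step.

    ``length`` 0 means a single sample per channel. The lag count is
    ``floor(length / spacing) + 1``. ``alignment="center"`` places the lags
    symmetrically about the evaluation time (non-causal, offline);
    ``"causal"`` places every lag at or before it (online).
    """

    length: float = 1.4
    lag_spacing: float = 0.2
    alignment: str = "center"
    step: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("window length must be >= 0")
        if self.lag_spacing <= 0:
            raise ValueError("lag spacing must be > 0")
        if self.alignment not in ("center", "causal"):
            raise ValueError("alignment must be 'center' or 'causal'")

    @property
    def n_lags(self) -> int:
        return int(np.floor(self.length / self.lag_spacing + 1e-9)) + 1

    def lag_offsets(self) -> np.ndarray:
        """Lag times (s) relative to the evaluation time."""
        lags = np.arange(self.n_lags) * self.lag_spacing
        if self.alignment == "center":
            return lags - self.length / 2.0
        return lags - self.length


def extract_features(
    epochs: EpochSet, t_ref: float, cfg: FeatureWindowConfig
) -> np.ndarray:
    """Trials x features matrix of raw uV samples at the lag grid.

    Features are ordered channel-major: all lags of the first good EEG
    channel, then the second, etc. EOG and bad channels are excluded.
    """
    eeg = epochs.channel_indices(kind="EEG", good_only=True)
    offsets = cfg.lag_offsets()
    cols = []
    for off in offsets:
        t = t_ref + off
        try:
            cols.append(epochs.sample_at(t))
        except ValueError as exc:
            raise ValueError(
                f"lag {off:+.3f} s (t = {t:.3f} s) outside the epoch window"
            ) from exc
    # (trials, channels, lags) -> channel-major flat
    block = epochs.data[:, eeg, :][:, :, cols]
    return block.reshape(epochs.n_trials, len(eeg) * len(cols))


@dataclass
class SLDAModel:
    """Fitted shrinkage-LDA: class means, shrunk covariance, linear scores."""

    classes: np.ndarray
    means: np.ndarray  # n_classes x n_features
    shrinkage: float
    weights: np.ndarray  # n_features x n_classes
    biases: np.ndarray  # n_classes

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.weights.shape[0]})"
            )
        return X @ self.weights + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties broken toward the lowest class index (argmax convention)
        return self.classes[np.argmax(self.scores(X), axis=1)]


def fit_slda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None
) -> SLDAModel:
    """Fit the shrinkage-LDA classifier.

    ``shrinkage=None`` uses the analytic Ledoit-Wolf intensity computed from
    the within-class-centred samples; a float in [0, 1] forces lambda. With
    lambda = 0 the model coincides with classical LDA (and raises if the
    pooled covariance is singular); with lambda = 1 it is a nearest-class-mean
    classifier under the scaled-identity metric.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")

    n, d = X.shape
    means = np.stack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
    centred = X - means[y_idx]

    if shrinkage is None:
        _, lam = ledoit_wolf(centred, assume_centered=True)
        lam = float(lam)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    cov = (centred.T @ centred) / n
    nu = float(np.trace(cov)) / d
    sigma = (1.0 - lam) * cov + lam * nu * np.eye(d)

    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use shrinkage > 0"
        ) from exc
    solve = lambda B: np.linalg.solve(chol.T, np.linalg.solve(chol, B))
    weights = solve(means.T)  # d x k
    priors = counts / n
    biases = -0.5 * np.einsum("kd,dk->k", means, weights) + np.log(priors)
    return SLDAModel(
        classes=classes, means=means, shrinkage=lam, weights=weights, biases=biases
    )


def predict_proba(model: SLDAModel, X: np.ndarray) -> np.ndarray:
    """Softmax-normalised class probabilities; rows sum to 1."""
    s = model.scores(X)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class AccuracyCurve:
    """Cross-validated accuracy (%) as a function of window-centre time."""

    times: np.ndarray
    accuracy: np.ndarray
    per_fold: np.ndarray = field(default=None)  # positions x (repeats*folds)

    def peak(self) -> tuple[float, float]:
        i = int(np.argmax(self.accuracy))
        return float(self.times[i]), float(self.accuracy[i])


def _cv_splits(
    y: np.ndarray, folds: int, repeats: int, seed: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    rng = np.random.SeedSequence(seed)
    out = []
    for child in rng.spawn(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        )
        out.append(list(skf.split(np.zeros(len(y)), y)))
    return out


def _check_cv(y: np.ndarray, folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} trials; cannot run {folds}-fold CV"
        )


def sliding_accuracy(
    epochs: EpochSet,
    cfg: FeatureWindowConfig,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    times: np.ndarray | None = None,
    shrinkage: float | None = None,
) -> AccuracyCurve:
    """Repeated stratified k-fold CV accuracy of the slid feature window.

    Folds partition trials (never samples); accuracy at each window position
    is the mean over folds and repeats of the per-trial correct-classification
    percentage. Rejected trials are dropped first. Deterministic given seed.
    """
    epochs = epochs.kept()
    _check_cv(epochs.labels, folds)
    half = cfg.length / 2.0 if cfg.alignment == "center" else cfg.length
    t = epochs.times
    if times is None:
        lo = t[0] + (half if cfg.alignment == "center" else cfg.length)
        hi = t[-1] - (half if cfg.alignment == "center" else 0.0)
        times = np.arange(np.ceil(lo / cfg.step), np.floor(hi / cfg.step) + 1) * cfg.step
    times = np.asarray(times, dtype=float)

    splits = _cv_splits(epochs.labels, folds, repeats, seed)
    acc = np.zeros(len(times))
    per_fold = np.zeros((len(times), folds * repeats))
    for i, t_ref in enumerate(times):
        X = extract_features(epochs, t_ref, cfg)
        j = 0
        for rep in splits:
            for train, test in rep:
                model = fit_slda(X[train], epochs.labels[train], shrinkage=shrinkage)
                pred = model.predict(X[test])
                per_fold[i, j] = 100.0 * np.mean(pred == epochs.labels[test])
                j += 1
        acc[i] = per_fold[i].mean()
    return AccuracyCurve(times=times, accuracy=acc, per_fold=per_fold)


def confusion_at(
    epochs: EpochSet,
    cfg: FeatureWindowConfig,
    t_peak: float,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised confusion matrix (%) at one window position.

    Returns ``(classes, matrix)`` with rows = true class summing to 100,
    pooled over all folds and repeats.
    """
    epochs = epochs.kept()
    _check_cv(epochs.labels, folds)
    classes = np.unique(epochs.labels)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    X = extract_features(epochs, t_peak, cfg)
    counts = np.zeros((k, k))
    for rep in _cv_splits(epochs.labels, folds, repeats, seed):
        for train, test in rep:
            model = fit_slda(X[train], epochs.labels[train], shrinkage=shrinkage)
            pred = model.predict(X[test])
            for yt, yp in zip(epochs.labels[test], pred):
                counts[idx[yt], idx[yp]] += 1
    row = counts.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    return classes, 100.0 * counts / row
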