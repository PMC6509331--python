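"""Artifact pipeline: filtering, referencing, ICA cleaning, trial rejection.

The four-step cleaning procedure is:

1. drop noisy channels (AFz by default — it is dominated by ocular activity —
   plus a robust-variance screen standing in for visual inspection);
2. fit an extended-infomax ICA on broadband (0.3-70 Hz) data, PCA-reduced to
   99% variance and restricted to samples within 10.4 median absolute
   deviations, and flag ocular/muscle components by EOG correlation and
   spectral shape;
3. mark trials containing transient artifacts (absolute amplitude beyond
   +-100 uV, abnormal joint probability, abnormal kurtosis — the latter two
   at 5 sd of their statistic across trials);
4. apply the cached ICA weights to the narrow-band (0.3-3 Hz) data, remove
   the flagged components, and back-project.

Zero-phase filtering (forward-backward Butterworth) is used offline; the
online path uses the causal single-pass variant with steady-state initial
conditions so the stream has no onset transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sps
from scipy.stats import kurtosis as _kurtosis

from .data import EEGRecording, EpochSet

__all__ = [
    "ICAModel",
    "RejectionReport",
    "bandpass",
    "notch",
    "detect_bad_channels",
    "robust_sample_mask",
    "fit_ica",
    "identify_artifact_ics",
    "remove_ics",
    "mark_bad_trials",
    "common_average_reference",
]


def _apply_channelwise(rec: EEGRecording, func) -> EEGRecording:
    out = rec.copy()
    out.signals = func(out.signals)
    return out


def bandpass(
    rec: EEGRecording,
    low_hz: float,
    high_hz: float,
    order: int = 4,
    mode: str = "zero_phase",
) -> EEGRecording:
    """Butterworth band-pass, zero-phase (forward-backward) or causal.

    Zero-phase mode squares the magnitude response and has zero group delay;
    causal mode is a single pass initialised at steady state for the first
    sample, so a constant input produces no onset transient.
    """
    if not 0 < low_hz < high_hz < rec.rate / 2:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for rate {rec.rate} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate, output="sos")
    if mode == "zero_phase":
        return _apply_channelwise(rec, lambda x: sps.sosfiltfilt(sos, x, axis=1))
    if mode == "causal":
        zi = sps.sosfilt_zi(sos)

        def causal(x: np.ndarray) -> np.ndarray:
            out = np.empty_like(x)
            for i in range(x.shape[0]):
                out[i], _ = sps.sosfilt(sos, x[i], zi=zi * x[i, 0])
            return out

        return _apply_channelwise(rec, causal)
    raise ValueError(f"unknown filter mode {mode!r}")


def notch(rec: EEGRecording, freq: float = 50.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at ``freq`` Hz (> 30 dB at the notch, < 1 dB 5 Hz away)."""
    if not 0 < freq < rec.rate / 2:
        raise ValueError(f"notch frequency {freq} Hz invalid for rate {rec.rate} Hz")
    b, a = sps.iirnotch(freq, Q=q, fs=rec.rate)
    return _apply_channelwise(rec, lambda x: sps.filtfilt(b, a, x, axis=1))


def detect_bad_channels(
    rec: EEGRecording,
    robust_z: float = 5.0,
    default_bad: tuple[str, ...] = ("AFz",),
) -> set[str]:
    """Flag noisy EEG channels.

    ``default_bad`` channels (AFz, blink-sensitive) are always flagged when
    present. Additionally a channel is flagged when the log of its median
    absolute deviation departs from the channel population median by more
    than ``robust_z`` robust standard deviations (1.4826 x MAD of the log
    spreads) — an automated stand-in for visual screening.
    """
    eeg = rec.channel_indices(kind="EEG")
    if len(eeg) < 2:
        raise ValueError("need at least 2 EEG channels")
    names = [rec.channels[i].name for i in eeg]
    flagged = {n for n in default_bad if n in names}

    spread = np.array(
        [
            np.median(np.abs(rec.signals[i] - np.median(rec.signals[i])))
            for i in eeg
        ]
    )
    log_spread = np.log(np.maximum(spread, 1e-12))
    centre = np.median(log_spread)
    scale = 1.4826 * np.median(np.abs(log_spread - centre))
    if scale > 0:
        for name, ls in zip(names, log_spread):
            if abs(ls - centre) > robust_z * scale:
                flagged.add(name)
    if len(flagged) >= len(eeg):
        raise RuntimeError("all EEG channels flagged bad; cannot continue")
    return flagged


def robust_sample_mask(signals: np.ndarray, k: float = 10.4) -> np.ndarray:
    """Per-channel mask: keep samples with ``|x - median| < k * MAD``.

    ``k = 10.4`` corresponds to 7 standard deviations for Gaussian data.
    Channels with MAD = 0 keep every sample.
    """
    signals = np.atleast_2d(np.asarray(signals))
    med = np.median(signals, axis=1, keepdims=True)
    mad = np.median(np.abs(signals - med), axis=1, keepdims=True)
    mask = np.abs(signals - med) < k * mad
    mask[np.broadcast_to(mad == 0, mask.shape)] = True
    return mask


@dataclass
class ICAModel:
    """Cached ICA decomposition fitted on broadband data.

    ``pca_components`` (q x n_ch) projects good-EEG-channel data onto the
    retained principal subspace (after removing ``pca_mean``); ``unmixing``
    (q x q) maps that subspace to sources; ``mixing`` is its inverse. The
    composition mixing o unmixing is the identity on the retained subspace.
    """

    channel_names: list[str]
    pca_mean: np.ndarray
    pca_components: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    explained_variance: float
    artifact_ics: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, rec: EEGRecording) -> np.ndarray:
        """Component time courses (q x samples) for ``rec``."""
        idx = [rec.channel_index(n) for n in self.channel_names]
        x = rec.signals[idx] - self.pca_mean[:, None]
        return self.unmixing @ (self.pca_components @ x)


def fit_ica(
    rec_broadband: EEGRecording,
    variance_keep: float = 0.99,
    mask: np.ndarray | None = None,
    max_iter: int = 200,
    seed: int = 0,
) -> ICAModel:
    """Fit extended-infomax ICA on PCA-reduced, sample-masked broadband data.

    ``mask`` is a per-channel boolean array (channels x samples, as from
    :func:`robust_sample_mask` on the good EEG channels); a sample is used
    only if it is kept on every channel. The fitted transforms are cached in
    the returned model and can later be applied to differently filtered data.
    """
    import warnings

    from mne.preprocessing import infomax

    good = rec_broadband.channel_indices(kind="EEG", good_only=True)
    x = rec_broadband.signals[good]
    names = [rec_broadband.channels[i].name for i in good]
    if mask is not None:
        keep = np.all(np.asarray(mask, dtype=bool), axis=0)
        x = x[:, keep]
    if x.shape[1] < 4 * x.shape[0]:
        raise ValueError("masked sample count too small relative to channel count")

    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)
    frac = np.cumsum(evals) / evals.sum()
    q = int(np.searchsorted(frac, variance_keep) + 1)
    if q < 2:
        raise ValueError("input is effectively rank-deficient (fewer than 2 components)")
    # whitened projection: rows are sphered principal directions
    pca_components = (evecs[:, :q] / np.sqrt(evals[:q])).T
    y = pca_components @ xc  # q x samples, identity covariance

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = infomax(
            y.T, extended=True, max_iter=max_iter,
            rng=np.random.default_rng(seed), verbose="error",
        )
    unmixing = np.asarray(w)
    mixing = np.linalg.inv(unmixing)
    return ICAModel(
        channel_names=names,
        pca_mean=mean,
        pca_components=pca_components,
        unmixing=unmixing,
        mixing=mixing,
        explained_variance=float(frac[q - 1]),
    )


def identify_artifact_ics(
    model: ICAModel,
    rec: EEGRecording,
    eog_corr_threshold: float = 0.7,
    muscle_power_ratio: float = 2.0,
) -> set[int]:
    """Flag ocular and muscle-like independent components.

    A component is ocular if its time course correlates with any EOG channel
    with ``|r| >= eog_corr_threshold``; muscle-like if its high-band
    (30 Hz - Nyquist) Welch power exceeds ``muscle_power_ratio`` times its
    low-band (< 15 Hz) power. Automated stand-in for manual inspection.
    """
    eog = rec.channel_indices(kind="EOG")
    if not eog:
        raise ValueError("no EOG channels present")
    src = model.sources(rec)
    flagged: set[int] = set()
    eog_sig = rec.signals[eog]
    for k in range(src.shape[0]):
        s = src[k]
        if np.std(s) == 0:
            continue
        for e in eog_sig:
            if np.std(e) == 0:
                continue
            r = np.corrcoef(s, e)[0, 1]
            if abs(r) >= eog_corr_threshold:
                flagged.add(k)
                break
        if k in flagged:
            continue
        freqs, psd = sps.welch(s, fs=rec.rate, nperseg=min(len(s), 1024))
        low = psd[(freqs >= 0.5) & (freqs < 15.0)].sum()
        high = psd[(freqs >= 30.0)].sum()
        if low > 0 and high / low >= muscle_power_ratio:
            flagged.add(k)
    return flagged


def remove_ics(
    rec_fullband: EEGRecording, model: ICAModel, indices: set[int] | None = None
) -> EEGRecording:
    """Apply cached ICA weights, remove ``indices``, and back-project.

    Output equals the input minus the mixed contribution of the selected
    components; with an empty index set the good EEG channels are reproduced
    up to the retained-subspace projection. Channels outside the model (EOG,
    bad channels) pass through unchanged.
    """
    if indices is None:
        indices = model.artifact_ics
    bad = [i for i in indices if not 0 <= i < model.n_components]
    if bad:
        raise ValueError(f"component indices out of range: {bad}")
    out = rec_fullband.copy()
    idx = [out.channel_index(n) for n in model.channel_names]
    x = out.signals[idx] - model.pca_mean[:, None]
    src = model.unmixing @ (model.pca_components @ x)
    if indices:
        sel = sorted(indices)
        # back-project only the removed components to channel space
        removed = model.mixing[:, sel] @ src[sel]
        pinv = np.linalg.pinv(model.pca_components)
        out.signals[idx] = out.signals[idx] - pinv @ removed
    return out


@dataclass
class RejectionReport:
    """Per-trial rejection flags with reasons; per-channel bad flags."""

    rejected: np.ndarray
    reasons: list[set[str]]
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for flag, reason in zip(self.rejected, self.reasons):
            if flag and not reason:
                raise ValueError("every rejected trial needs at least one reason")

    @property
    def n_rejected(self) -> int:
        return int(np.sum(self.rejected))

    def to_table(self) -> "list[tuple[int, str]]":
        return [
            (i, ",".join(sorted(r)))
            for i, (f, r) in enumerate(zip(self.rejected, self.reasons))
            if f
        ]


def _joint_probability_stat(data: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Per-trial single-trial log-improbability statistic.

    For each channel a histogram density is pooled over all trials; a trial's
    statistic is the mean of ``-log p`` of its samples over channels and time.
    """
    n_trials, n_ch, _ = data.shape
    stat = np.zeros(n_trials)
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            continue
        hist, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi), density=True)
        width = edges[1] - edges[0]
        p = np.maximum(hist * width, 1e-12)
        bins = np.clip(np.digitize(data[:, c, :], edges[1:-1]), 0, n_bins - 1)
        stat += -np.log(p[bins]).mean(axis=1)
    return stat / n_ch


def mark_bad_trials(
    epochs: EpochSet,
    sd_k: float = 5.0,
    amp_uv: float = 100.0,
) -> RejectionReport:
    """Flag trials with transient artifacts (amplitude / joint probability / kurtosis).

    Amplitude: any good-EEG sample beyond ``+-amp_uv``. Joint probability and
    kurtosis: trials whose statistic exceeds the across-trial mean by more
    than ``sd_k`` standard deviations.
    """
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 trials")
    eeg = epochs.channel_indices(kind="EEG", good_only=True)
    data = epochs.data[:, eeg, :]
    n = epochs.n_trials
    reasons: list[set[str]] = [set() for _ in range(n)]

    amp_bad = np.any(np.abs(data) > amp_uv, axis=(1, 2))
    for i in np.nonzero(amp_bad)[0]:
        reasons[i].add("amplitude")

    for name, stat in (
        ("joint_probability", _joint_probability_stat(data)),
        ("kurtosis", _kurtosis(data, axis=2, fisher=True).mean(axis=1)),
    ):
        sd = stat.std()
        if sd == 0:
            continue
        bad = stat > stat.mean() + sd_k * sd
        for i in np.nonzero(bad)[0]:
            reasons[i].add(name)

    rejected = np.array([bool(r) for r in reasons])
    return RejectionReport(
        rejected=rejected,
        reasons=reasons,
        bad_channels={c.name for c in epochs.channels if c.is_bad},
    )


def common_average_reference(obj: EEGRecording | EpochSet):
    """Subtract the instantaneous mean over good EEG channels from each.

    EOG and bad channels are left untouched. Idempotent.
    """
    eeg = obj.channel_indices(kind="EEG", good_only=True)
    if len(eeg) < 2:
        raise ValueError("need at least 2 good EEG channels for CAR")
    if isinstance(obj, EEGRecording):
        out = obj.copy()
        mean = out.signals[eeg].mean(axis=0, keepdims=True)
        out.signals[eeg] = out.signals[eeg] - mean
        return out
    out = EpochSet(
        data=obj.data.copy(),
        rate=obj.rate,
        t0_offset=obj.t0_offset,
        channels=list(obj.channels),
        labels=obj.labels.copy(),
        rejected=obj.rejected.copy(),
    )
    mean = out.data[:, eeg, :].mean(axis=1, keepdims=True)
    out.data[:, eeg, :] = out.data[:, eeg, :] - mean
    return out
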