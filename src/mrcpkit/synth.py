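"""Paradigm-faithful synthetic EEG sessions with class-dependent MRCPs.

Three session types mirror the study designs: a cue-based offline paradigm
(5 movement classes, cue 2 s into a 5 s trial), an online training paradigm
(class cue, ready cue, shrinking-circle go cue, plus 70 s rest runs), and an
online test paradigm (60 s self-paced movement or rest periods with reported
attempts). Each movement adds a two-peak movement-related cortical potential
(MRCP) at Cz — an early positive lobe followed by a later negative lobe —
whose per-trial amplitudes and latencies are drawn from group-level peak
statistics, spread over the scalp by a radially decaying gain centred on Cz.

Background activity is 1/f (pink) noise per channel, with optional 50 Hz line
interference, ocular blinks projected to EOG and frontal channels, transient
single-channel artifacts, and globally noisy ("bad") channels, so that every
stage of the artifact pipeline has a target.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config (PCG64, fixed algorithm), so sessions are byte-identical across runs
and platforms for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ChannelInfo, EEGRecording, EventMarker
from .montage import EEG_CHANNELS, EOG_CHANNELS, eeg_positions

__all__ = [
    "CLASSES_5",
    "ONLINE_CLASSES",
    "PeakStats",
    "MRCPTemplateParams",
    "ParadigmConfig",
    "NoiseConfig",
    "SessionTruth",
    "default_template_params",
    "online_template_params",
    "make_mrcp_waveform",
    "generate_offline_session",
    "generate_online_training_session",
    "generate_online_test_session",
]

CLASSES_5 = ("pronation", "supination", "hand_open", "palmar_grasp", "lateral_grasp")
ONLINE_CLASSES = ("hand_open", "palmar_grasp")

#: Half-widths (s) of the raised-cosine lobes forming the MRCP waveform.
POS_LOBE_HALFWIDTH = 0.2
NEG_LOBE_HALFWIDTH = 0.3

#: Spatial std dev (radians of angular distance from Cz) of the MRCP scalp gain.
#: Chosen so the gain is ~1e-3 at temporal sites (~1.5 rad from the vertex).
SPATIAL_SIGMA = 0.42


@dataclass(frozen=True)
class PeakStats:
    """Mean/sd of amplitude (uV) and latency (s) for one peak of one class."""

    amp_mean: float
    amp_sd: float
    lat_mean: float
    lat_sd: float

    def __post_init__(self) -> None:
        if self.amp_sd < 0 or self.lat_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.lat_mean <= 0:
            raise ValueError("latencies must be positive")


# Group-level descriptive statistics of the positive and negative Cz peaks per
# movement class (amplitude uV / latency s, mean and sd). These are the
# generative defaults of the simulator.
_PEAK_TABLE: dict[str, tuple[PeakStats, PeakStats]] = {
    "pronation": (PeakStats(8.01, 2.97, 0.44, 0.14), PeakStats(-5.48, 2.38, 1.10, 0.09)),
    "supination": (PeakStats(8.44, 3.79, 0.49, 0.13), PeakStats(-6.05, 2.15, 1.05, 0.11)),
    "hand_open": (PeakStats(8.17, 3.36, 0.51, 0.11), PeakStats(-5.33, 2.41, 1.35, 0.59)),
    "palmar_grasp": (PeakStats(6.56, 3.34, 0.53, 0.08), PeakStats(-4.45, 2.02, 1.41, 0.41)),
    "lateral_grasp": (PeakStats(6.68, 2.86, 0.56, 0.08), PeakStats(-3.68, 2.19, 1.27, 0.21)),
}


@dataclass(frozen=True)
class MRCPTemplateParams:
    """Per-class two-peak MRCP statistics plus waveform/spatial options.

    ``positive_scale`` shrinks the early positive (cue-processing) lobe — the
    online paradigms elicit a much reduced positive peak. ``second_negativity``
    adds a fixed extra negative lobe 0.5 s after the main negative peak,
    emulating the short-attempt session morphology.
    """

    peaks: dict[str, tuple[PeakStats, PeakStats]] = field(
        default_factory=lambda: dict(_PEAK_TABLE)
    )
    positive_scale: float = 1.0
    second_negativity: bool = False
    second_negativity_amp: float = -2.5
    spatial_sigma: float = SPATIAL_SIGMA

    def classes(self) -> tuple[str, ...]:
        return tuple(self.peaks)


def default_template_params() -> MRCPTemplateParams:
    """Defaults for the cue-based offline paradigm (full positive peak)."""
    return MRCPTemplateParams()


def online_template_params(second_negativity: bool = False) -> MRCPTemplateParams:
    """Defaults for go-cue-locked online paradigms: reduced positive lobe."""
    return MRCPTemplateParams(positive_scale=0.3, second_negativity=second_negativity)


@dataclass
class ParadigmConfig:
    """Session schedule parameters. Times in seconds.

    Only the fields relevant to ``paradigm`` are consulted:

    offline
        ``runs`` x ``trials_per_run`` cue-based trials; class cue at
        ``cue_offset`` into the 5 s trial; breaks uniform in ``break_range``.
    online_training
        ``runs`` x ``trials_per_run`` movement trials (class cue at 0, ready
        cue at ``ready_offset``, go cue after a uniform delay in
        ``ready_delay_range`` plus a shrink in ``shrink_range``), then
        ``rest_runs`` rest runs of ``rest_len`` each.
    online_test
        ``runs`` runs of ``movement_trials_per_run`` + ``rest_trials_per_run``
        trials; 5 s class cue then a 60 s self-paced period; attempts at least
        ``min_attempt_gap`` apart, reported ``report_delay`` later with
        uniform jitter ``report_jitter``.
    """

    paradigm: str = "offline"
    runs: int = 9
    trials_per_run: int = 40
    classes: tuple[str, ...] = CLASSES_5
    seed: int = 0
    # offline timing
    cue_offset: float = 2.0
    trial_len: float = 5.0
    break_range: tuple[float, float] = (1.0, 3.0)
    # online training timing
    ready_offset: float = 2.0
    ready_delay_range: tuple[float, float] = (0.5, 1.0)
    shrink_range: tuple[float, float] = (2.0, 4.0)
    post_go: float = 2.0
    rest_runs: int = 4
    rest_len: float = 70.0
    # online test timing
    cue_len: float = 5.0
    period_len: float = 60.0
    movement_trials_per_run: int = 4
    rest_trials_per_run: int = 1
    min_attempt_gap: float = 3.0
    attempt_gap_jitter: float = 3.0
    report_delay: float = 2.0
    report_jitter: float = 0.3
    rate: float = 256.0

    def __post_init__(self) -> None:
        if self.paradigm not in ("offline", "online_training", "online_test"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        for rng_pair in (self.break_range, self.ready_delay_range, self.shrink_range):
            if rng_pair[0] < 0 or rng_pair[1] < rng_pair[0]:
                raise ValueError(f"invalid timing range {rng_pair}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class NoiseConfig:
    """Amplitudes (uV) and rates (events/min) of the nuisance components.

    Defaults give a realistic low-frequency EEG floor: ~5 uV RMS pink noise,
    a 2 uV 50 Hz line component, two blinks per minute at ~120 uV on EOG.
    """

    pink_rms: float = 5.0
    line_amp: float = 2.0
    line_freq: float = 50.0
    blink_rate: float = 2.0
    blink_amp: float = 120.0
    artifact_rate: float = 0.5
    artifact_amp: float = 80.0
    bad_channel_count: int = 0

    def __post_init__(self) -> None:
        for name in ("pink_rms", "line_amp", "blink_rate", "blink_amp",
                     "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bad_channel_count < 0:
            raise ValueError("bad_channel_count must be >= 0")


@dataclass
class SessionTruth:
    """Ground truth logged by the generators.

    ``trials`` holds one dict per trial (times in seconds, drawn peak values);
    ``attempts`` holds self-paced attempt times for the test paradigm;
    ``bad_channels`` names the channels rendered noisy.
    """

    trials: list[dict] = field(default_factory=list)
    attempts: list[dict] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# waveform


def _hann_lobe(t: np.ndarray, centre: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump: 1 at ``centre``, 0 outside ``centre +- halfwidth``."""
    u = (t - centre) / halfwidth
    out = np.zeros_like(t, dtype=float)
    inside = np.abs(u) < 1.0
    out[inside] = np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


def _draw_peaks(
    cls: str, params: MRCPTemplateParams, rng: np.random.Generator
) -> dict[str, float]:
    pos, neg = params.peaks[cls]
    pos_amp = pos.amp_mean + pos.amp_sd * rng.standard_normal()
    pos_lat = pos.lat_mean + pos.lat_sd * rng.standard_normal()
    neg_amp = neg.amp_mean + neg.amp_sd * rng.standard_normal()
    neg_lat = neg.lat_mean + neg.lat_sd * rng.standard_normal()
    # latencies must stay positive and ordered; clip rather than redraw so the
    # number of rng draws per trial is fixed (determinism of the stream)
    pos_lat = float(np.clip(pos_lat, 0.1, 1.2))
    neg_lat = float(np.clip(neg_lat, pos_lat + 0.2, 2.6))
    return {
        "pos_amp": float(pos_amp) * params.positive_scale,
        "pos_lat": pos_lat,
        "neg_amp": float(neg_amp),
        "neg_lat": neg_lat,
    }


def _eval_mrcp(t: np.ndarray, draws: dict[str, float], params: MRCPTemplateParams) -> np.ndarray:
    """Evaluate the two-lobe waveform on times ``t`` (s, relative to cue).

    The lobe coefficients are solved so the waveform passes exactly through
    the drawn amplitudes at the drawn latencies (with the default widths the
    lobes do not overlap, so the extrema equal the drawn amplitudes).
    """
    tp, tn = draws["pos_lat"], draws["neg_lat"]
    extra = np.zeros_like(t, dtype=float)
    if params.second_negativity:
        extra = params.second_negativity_amp * _hann_lobe(t, tn + 0.5, NEG_LOBE_HALFWIDTH)

    def basis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            _hann_lobe(x, tp, POS_LOBE_HALFWIDTH),
            _hann_lobe(x, tn, NEG_LOBE_HALFWIDTH),
        )

    pts = np.array([tp, tn])
    h1p, h2p = basis(pts)
    extra_p = (
        params.second_negativity_amp * _hann_lobe(pts, tn + 0.5, NEG_LOBE_HALFWIDTH)
        if params.second_negativity
        else np.zeros(2)
    )
    A = np.array([[h1p[0], h2p[0]], [h1p[1], h2p[1]]])
    b = np.array([draws["pos_amp"] - extra_p[0], draws["neg_amp"] - extra_p[1]])
    coef = np.linalg.solve(A, b)
    h1, h2 = basis(np.asarray(t, dtype=float))
    return coef[0] * h1 + coef[1] * h2 + extra


def make_mrcp_waveform(
    cls: str,
    params: MRCPTemplateParams | None = None,
    rng: np.random.Generator | int | None = None,
    rate: float = 256.0,
    duration: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Draw one single-channel MRCP waveform for ``cls``.

    Returns ``(times, waveform_uv, truth)`` where ``times`` spans
    ``[0, duration)`` at ``rate`` and ``truth`` holds the drawn peak
    amplitudes/latencies. With all sd = 0 the draw is a point mass at the
    class means.
    """
    params = params or default_template_params()
    if cls not in params.peaks:
        raise ValueError(f"unknown class {cls!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = _draw_peaks(cls, params, rng)
    t = np.arange(int(round(duration * rate))) / rate
    return t, _eval_mrcp(t, draws, params), draws


# ---------------------------------------------------------------------------
# channels, noise, rendering


def make_channels(positions: dict[str, tuple[float, float]] | None = None) -> list[ChannelInfo]:
    """The standard 61 EEG + 3 EOG channel list."""
    pos = positions or eeg_positions()
    chans = [ChannelInfo(name=n, kind="EEG", position=pos[n]) for n in EEG_CHANNELS]
    chans += [ChannelInfo(name=n, kind="EOG") for n in EOG_CHANNELS]
    return chans


def _spatial_gains(channels: list[ChannelInfo], sigma: float) -> np.ndarray:
    """Radially decaying MRCP gain around Cz; exactly 1 at Cz, 0 on EOG."""
    pos = eeg_positions()
    cz = np.array(pos["Cz"])
    g = np.zeros(len(channels))
    for i, c in enumerate(channels):
        if c.kind != "EEG":
            continue
        d = np.linalg.norm(np.array(c.position) - cz)
        g[i] = np.exp(-(d**2) / (2 * sigma**2))
    return g


def _frontal_gains(channels: list[ChannelInfo]) -> np.ndarray:
    """Blink projection: 1 on EOG, decaying from the frontopolar row on EEG.

    The spread is broad enough that ocular activity measurably reaches the
    central row (~15 % of the frontopolar amplitude at Cz), as in real EEG.
    """
    pos = eeg_positions()
    fpz = np.array(pos["Fpz"])
    g = np.zeros(len(channels))
    for i, c in enumerate(channels):
        if c.kind == "EOG":
            g[i] = 1.0
        else:
            d = np.linalg.norm(np.array(c.position) - fpz)
            g[i] = 0.7 * np.exp(-(d**2) / (2 * 0.7**2))
    return g


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, rms: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, per-channel RMS = ``rms``."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    cur = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    cur[cur == 0] = 1.0
    return shaped / cur * rms


def _blink_waveform(t: np.ndarray, onset: float) -> np.ndarray:
    """Biphasic ocular deflection: 0.25 s positive lobe, smaller rebound."""
    return _hann_lobe(t, onset + 0.125, 0.125) - 0.35 * _hann_lobe(t, onset + 0.4, 0.15)


def _render_noise(
    sig: np.ndarray,
    channels: list[ChannelInfo],
    rate: float,
    ncfg: NoiseConfig,
    rng: np.random.Generator,
    truth: SessionTruth,
) -> None:
    n_ch, n = sig.shape
    dur_min = n / rate / 60.0
    sig += _pink_noise(rng, n_ch, n, ncfg.pink_rms)
    t = np.arange(n) / rate
    if ncfg.line_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        sig += ncfg.line_amp * np.sin(
            2 * np.pi * ncfg.line_freq * t[None, :] + phases[:, None]
        )
    # blinks
    n_blinks = rng.poisson(ncfg.blink_rate * dur_min) if ncfg.blink_rate > 0 else 0
    if n_blinks:
        gains = _frontal_gains(channels)
        onsets = np.sort(rng.uniform(0, max(n / rate - 1.0, 0.0), n_blinks))
        blink_tc = np.zeros(n)
        for onset in onsets:
            i0 = int(onset * rate)
            i1 = min(n, i0 + int(0.8 * rate))
            blink_tc[i0:i1] += ncfg.blink_amp * _blink_waveform(t[i0:i1], onset)
        sig += gains[:, None] * blink_tc[None, :]
    # transient single-channel artifacts
    n_art = rng.poisson(ncfg.artifact_rate * dur_min) if ncfg.artifact_rate > 0 else 0
    eeg_idx = [i for i, c in enumerate(channels) if c.kind == "EEG"]
    for _ in range(n_art):
        ch = int(rng.choice(eeg_idx))
        onset = rng.uniform(0, max(n / rate - 0.1, 0.0))
        amp = ncfg.artifact_amp * rng.choice([-1.0, 1.0])
        i0 = int(onset * rate)
        i1 = min(n, i0 + int(0.05 * rate))
        sig[ch, i0:i1] += amp * _hann_lobe(t[i0:i1], onset + 0.025, 0.025)
    # bad channels: swamp with broadband noise (never Cz — the analysis anchor)
    if ncfg.bad_channel_count:
        candidates = [i for i in eeg_idx if channels[i].name != "Cz"]
        bad = rng.choice(candidates, size=ncfg.bad_channel_count, replace=False)
        for ch in np.atleast_1d(bad):
            sig[int(ch)] += rng.standard_normal(n) * max(10 * ncfg.pink_rms, 20.0)
            truth.bad_channels.append(channels[int(ch)].name)


def _add_mrcp(
    sig: np.ndarray,
    gains: np.ndarray,
    rate: float,
    cue_time: float,
    draws: dict[str, float],
    params: MRCPTemplateParams,
) -> None:
    n = sig.shape[1]
    i0 = int(round(cue_time * rate))
    i1 = min(n, i0 + int(round(3.5 * rate)))
    if i0 >= n:
        return
    t_rel = (np.arange(i0, i1) - i0) / rate
    w = _eval_mrcp(t_rel, draws, params)
    sig[:, i0:i1] += gains[:, None] * w[None, :]


def _balanced_labels(
    classes: tuple[str, ...], n_trials: int, rng: np.random.Generator
) -> list[str]:
    if n_trials % len(classes) != 0:
        raise ValueError(
            f"{n_trials} trials cannot be balanced across {len(classes)} classes"
        )
    seq = list(classes) * (n_trials // len(classes))
    perm = rng.permutation(len(seq))
    return [seq[i] for i in perm]


# ---------------------------------------------------------------------------
# session generators


def generate_offline_session(
    pcfg: ParadigmConfig,
    tparams: MRCPTemplateParams | None = None,
    ncfg: NoiseConfig | None = None,
) -> tuple[EEGRecording, SessionTruth]:
    """Simulate one cue-based offline session.

    Trials: fixation/beep at trial start, class cue ``cue_offset`` (2 s)
    later, trial length 5 s, inter-trial break uniform in ``break_range``.
    The class-specific MRCP is added at the cue through the Cz-centred
    spatial pattern. Classes are balanced within the session.
    """
    if pcfg.paradigm != "offline":
        raise ValueError("paradigm must be 'offline'")
    tparams = tparams or default_template_params()
    ncfg = ncfg or NoiseConfig()
    rng = np.random.default_rng(pcfg.seed)
    n_trials = pcfg.runs * pcfg.trials_per_run
    labels = _balanced_labels(pcfg.classes, n_trials, rng)

    truth = SessionTruth()
    events: list[tuple[float, str]] = []
    placements: list[tuple[float, dict[str, float]]] = []
    t = 2.0  # lead-in
    k = 0
    for _run in range(pcfg.runs):
        for _trial in range(pcfg.trials_per_run):
            cls = labels[k]
            cue_t = t + pcfg.cue_offset
            events.append((t, "trial_start"))
            events.append((cue_t, f"class_cue:{cls}"))
            draws = _draw_peaks(cls, tparams, rng)
            placements.append((cue_t, draws))
            truth.trials.append({"trial_start": t, "cue": cue_t, "class": cls, **draws})
            t += pcfg.trial_len + rng.uniform(*pcfg.break_range)
            k += 1
    duration = t + 2.0

    channels = make_channels()
    n = int(round(duration * pcfg.rate))
    sig = np.zeros((len(channels), n))
    _render_noise(sig, channels, pcfg.rate, ncfg, rng, truth)
    gains = _spatial_gains(channels, tparams.spatial_sigma)
    for cue_t, draws in placements:
        _add_mrcp(sig, gains, pcfg.rate, cue_t, draws, tparams)

    markers = [
        EventMarker(int(round(ts * pcfg.rate)), lab) for ts, lab in sorted(events)
    ]
    rec = EEGRecording(signals=sig, rate=pcfg.rate, channels=channels, events=markers)
    return rec, truth


def generate_online_training_session(
    pcfg: ParadigmConfig,
    tparams: MRCPTemplateParams | None = None,
    ncfg: NoiseConfig | None = None,
) -> tuple[EEGRecording, SessionTruth]:
    """Simulate one online training session (go-cue-locked MRCPs + rest runs).

    Movement trial: class cue at 0 s, ready cue at 2 s, go cue after a uniform
    0.5-1 s delay plus a uniform 2-4 s shrink; the MRCP is time-locked to the
    go cue. Rest runs of 70 s each follow the movement runs.
    """
    if pcfg.paradigm != "online_training":
        raise ValueError("paradigm must be 'online_training'")
    tparams = tparams or online_template_params()
    ncfg = ncfg or NoiseConfig()
    rng = np.random.default_rng(pcfg.seed)
    n_trials = pcfg.runs * pcfg.trials_per_run
    labels = _balanced_labels(pcfg.classes, n_trials, rng)

    truth = SessionTruth()
    events: list[tuple[float, str]] = []
    placements: list[tuple[float, dict[str, float]]] = []
    t = 2.0
    k = 0
    for _run in range(pcfg.runs):
        for _trial in range(pcfg.trials_per_run):
            cls = labels[k]
            events.append((t, "trial_start"))
            events.append((t, f"class_cue:{cls}"))
            ready_t = t + pcfg.ready_offset
            events.append((ready_t, "ready_cue"))
            go_t = ready_t + rng.uniform(*pcfg.ready_delay_range) + rng.uniform(
                *pcfg.shrink_range
            )
            events.append((go_t, "go_cue"))
            draws = _draw_peaks(cls, tparams, rng)
            placements.append((go_t, draws))
            truth.trials.append(
                {"trial_start": t, "go": go_t, "class": cls, **draws}
            )
            t = go_t + pcfg.post_go + rng.uniform(2.0, 3.0)
            k += 1
    for _rest in range(pcfg.rest_runs):
        events.append((t, "rest_start"))
        truth.trials.append({"trial_start": t, "class": "rest", "len": pcfg.rest_len})
        t += pcfg.rest_len + 2.0
    duration = t + 2.0

    channels = make_channels()
    sig = np.zeros((len(channels), int(round(duration * pcfg.rate))))
    _render_noise(sig, channels, pcfg.rate, ncfg, rng, truth)
    gains = _spatial_gains(channels, tparams.spatial_sigma)
    for go_t, draws in placements:
        _add_mrcp(sig, gains, pcfg.rate, go_t, draws, tparams)

    markers = [
        EventMarker(int(round(ts * pcfg.rate)), lab) for ts, lab in sorted(events)
    ]
    rec = EEGRecording(signals=sig, rate=pcfg.rate, channels=channels, events=markers)
    return rec, truth


def generate_online_test_session(
    pcfg: ParadigmConfig,
    tparams: MRCPTemplateParams | None = None,
    ncfg: NoiseConfig | None = None,
    attempt_rate: float | None = None,
) -> tuple[EEGRecording, SessionTruth]:
    """Simulate one online test session with self-paced attempts.

    Each run holds ``movement_trials_per_run`` movement trials and
    ``rest_trials_per_run`` rest trials in shuffled order. A trial shows its
    class cue for 5 s, then a 60 s period. Movement trials contain self-paced
    MRCPs at randomized times at least ``min_attempt_gap`` apart, each
    followed ``report_delay`` (+/- jitter) later by a ``reported_movement``
    marker. ``attempt_rate`` (attempts/min) of 0 suppresses all attempts.
    """
    if pcfg.paradigm != "online_test":
        raise ValueError("paradigm must be 'online_test'")
    tparams = tparams or online_template_params()
    ncfg = ncfg or NoiseConfig()
    rng = np.random.default_rng(pcfg.seed)

    truth = SessionTruth()
    events: list[tuple[float, str]] = []
    placements: list[tuple[float, dict[str, float]]] = []
    t = 2.0
    for _run in range(pcfg.runs):
        move = _balanced_labels(
            tuple(pcfg.classes), pcfg.movement_trials_per_run, rng
        )
        trial_classes = move + ["rest"] * pcfg.rest_trials_per_run
        order = rng.permutation(len(trial_classes))
        for idx in order:
            cls = trial_classes[idx]
            events.append((t, "trial_start"))
            events.append((t, f"class_cue:{cls}"))
            period_start = t + pcfg.cue_len
            period_end = period_start + pcfg.period_len
            if cls == "rest":
                events.append((period_start, "rest_start"))
                truth.trials.append(
                    {"trial_start": t, "class": "rest",
                     "period": (period_start, period_end)}
                )
            else:
                truth.trials.append(
                    {"trial_start": t, "class": cls,
                     "period": (period_start, period_end)}
                )
                if attempt_rate == 0:
                    t = period_end + 3.0
                    continue
                at = period_start + rng.uniform(1.0, 3.0)
                while at < period_end - 3.0:
                    draws = _draw_peaks(cls, tparams, rng)
                    placements.append((at, draws))
                    report_t = at + pcfg.report_delay + rng.uniform(
                        -pcfg.report_jitter, pcfg.report_jitter
                    )
                    events.append((report_t, "reported_movement"))
                    truth.attempts.append(
                        {"time": at, "report": report_t, "class": cls, **draws}
                    )
                    at += pcfg.min_attempt_gap + rng.uniform(
                        0.0, pcfg.attempt_gap_jitter
                    )
            t = period_end + 3.0
    duration = t + 2.0

    channels = make_channels()
    sig = np.zeros((len(channels), int(round(duration * pcfg.rate))))
    _render_noise(sig, channels, pcfg.rate, ncfg, rng, truth)
    gains = _spatial_gains(channels, tparams.spatial_sigma)
    for at, draws in placements:
        _add_mrcp(sig, gains, pcfg.rate, at, draws, tparams)

    markers = [
        EventMarker(int(round(ts * pcfg.rate)), lab) for ts, lab in sorted(events)
    ]
    rec = EEGRecording(signals=sig, rate=pcfg.rate, channels=channels, events=markers)
    return rec, truth
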