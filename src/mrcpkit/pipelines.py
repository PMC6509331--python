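"""End-to-end orchestration of the two experiments on synthetic sessions.

``run_offline_analysis`` reproduces the multi-participant cue-based decoding
study: simulate each participant, clean (bad channels, optional ICA, trial
rejection), band-pass 0.3-3 Hz, re-reference, compute sliding-window
cross-validated accuracy curves, the grand average with its t-distribution
confidence interval, the peak confusion matrix, Cz peak features with
Friedman tests, and difference topoplots with a max-statistic permutation
mask.

``run_online_experiment`` reproduces the self-paced proof-of-concept:
simulate a training session, select ``t_train``, train the 5-class detector,
replay a causally filtered test session sample by sample through the
detection state machine, choose the true-positive window offset, and score
TPR, FP/min, accuracy and detection delay.

Every report field is reproducible from the config plus the master seed;
per-participant seeds are spawned from the master seed with
``numpy.random.SeedSequence``. No step mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .data import EEGRecording, EpochSet, epoch
from .decoding import FeatureWindowConfig, confusion_at, fit_slda, predict_proba, sliding_accuracy
from .group_stats import (
    difference_topoplots,
    friedman_by_class,
    interpolate_bad_channels,
    peak_features,
    permutation_max_stat,
    significance_threshold,
    t_ci,
)
from .online import (
    ONLINE_CLASS_ORDER,
    DetectionConfig,
    build_five_class_training,
    detection_delay,
    evaluate_online,
    run_detector,
    select_t_train,
    select_tp_offset,
)
from .preprocessing import (
    bandpass,
    common_average_reference,
    detect_bad_channels,
    fit_ica,
    identify_artifact_ics,
    mark_bad_trials,
    notch,
    remove_ics,
    robust_sample_mask,
)
from .synth import (
    ONLINE_CLASSES,
    MRCPTemplateParams,
    NoiseConfig,
    ParadigmConfig,
    default_template_params,
    generate_offline_session,
    generate_online_test_session,
    generate_online_training_session,
    online_template_params,
)

__all__ = [
    "RunConfig",
    "preprocess_offline",
    "preprocess_online",
    "cut_rest_epochs",
    "probability_trace",
    "run_offline_analysis",
    "run_online_experiment",
]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one end-to-end run."""

    seed: int = 0
    n_participants: int = 10
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    templates: MRCPTemplateParams | None = None
    window: FeatureWindowConfig = field(default_factory=FeatureWindowConfig)
    folds: int = 10
    repeats: int = 10
    use_ica: bool = True
    epoch_window: tuple[float, float] = (-2.0, 3.0)
    curve_times: tuple[float, ...] | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    # online test-session sizes (session 1 of the proof-of-concept by default)
    test_runs: int = 6
    test_movement_trials: int = 2
    test_rest_trials: int = 1
    test_period: float = 60.0
    out_dir: str | None = None

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


def _participant_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def preprocess_offline(
    rec: EEGRecording,
    use_ica: bool = True,
    band: tuple[float, float] = (0.3, 3.0),
    ica_band: tuple[float, float] = (0.3, 70.0),
    ica_max_iter: int = 200,
    seed: int = 0,
) -> tuple[EEGRecording, dict]:
    """The four-step offline cleaning pipeline on a raw recording.

    Returns the cleaned narrow-band recording (bad channels flagged, ICA
    artifacts removed, 0.3-3 Hz zero-phase filtered) plus a log of everything
    flagged.
    """
    log: dict = {}
    rec = notch(rec, 50.0)
    bad = detect_bad_channels(rec)
    log["bad_channels"] = sorted(bad)
    rec = rec.copy()
    for i, c in enumerate(rec.channels):
        if c.name in bad:
            rec.channels[i] = replace(c, is_bad=True)

    removed_ics: set[int] = set()
    model = None
    if use_ica:
        broad = bandpass(rec, *ica_band, mode="zero_phase")
        good = broad.channel_indices(kind="EEG", good_only=True)
        mask = robust_sample_mask(broad.signals[good])
        model = fit_ica(broad, variance_keep=0.99, mask=mask, max_iter=ica_max_iter, seed=seed)
        removed_ics = identify_artifact_ics(model, broad)
        log["n_components"] = model.n_components
        rec = remove_ics(rec, model, removed_ics)
    log["removed_ics"] = sorted(removed_ics)
    rec = bandpass(rec, *band, mode="zero_phase")
    return rec, log


def preprocess_online(
    rec: EEGRecording, band: tuple[float, float] = (0.3, 3.0)
) -> tuple[EEGRecording, dict]:
    """Online-path cleaning: causal band-pass, default bad channels, no ICA."""
    rec = notch(rec, 50.0)
    bad = detect_bad_channels(rec)
    out = rec.copy()
    for i, c in enumerate(out.channels):
        if c.name in bad:
            out.channels[i] = replace(c, is_bad=True)
    out = bandpass(out, *band, mode="causal")
    return out, {"bad_channels": sorted(bad)}


def _class_averages(epochs: EpochSet, channel_sel: list[int]) -> dict[str, np.ndarray]:
    kept = epochs.kept()
    return {
        c: kept.data[kept.labels == c][:, channel_sel, :].mean(axis=0)
        for c in np.unique(kept.labels)
    }


def _interpolated_topomap_data(
    epochs: EpochSet,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Trial data on the full EEG grid with bad channels interpolated."""
    eeg = epochs.channel_indices(kind="EEG")
    names = [epochs.channels[i].name for i in eeg]
    positions = np.array([epochs.channels[i].position for i in eeg])
    bad = np.array([epochs.channels[i].is_bad for i in eeg])
    kept = epochs.kept()
    data = kept.data[:, eeg, :]
    if bad.any():
        data = np.stack([interpolate_bad_channels(tr, positions, bad) for tr in data])
    return data, kept.labels, names


def run_offline_analysis(cfg: RunConfig) -> dict:
    """Simulate, clean, decode and test a full offline study.

    Returns a report dict; writes plain tables under ``cfg.out_dir`` when set.
    """
    templates = cfg.templates or default_template_params()
    seeds = _participant_seeds(cfg.seed, cfg.n_participants)
    curves, confusions, cz_avgs, topo_trials, logs = [], [], [], [], []
    times_grid = np.asarray(cfg.curve_times) if cfg.curve_times is not None else None
    n_classes = len(cfg.paradigm.classes)
    kept_trials = []

    post_cue_times = None
    for p, seed in enumerate(seeds):
        pcfg = replace(cfg.paradigm, seed=seed)
        rec, _truth = generate_offline_session(pcfg, templates, cfg.noise)
        clean, log = preprocess_offline(rec, use_ica=cfg.use_ica, seed=seed)
        eps = epoch(clean, "class_cue", cfg.epoch_window)
        report = mark_bad_trials(eps)
        eps.rejected = report.rejected
        log["n_rejected_trials"] = report.n_rejected
        eps = common_average_reference(eps)
        kept_trials.append(int((~eps.rejected).sum()))

        curve = sliding_accuracy(
            eps, cfg.window, folds=cfg.folds, repeats=cfg.repeats,
            seed=seed, times=times_grid,
        )
        curves.append(curve)
        t_peak_p, _ = curve.peak()
        cls_order, conf = confusion_at(
            eps, cfg.window, t_peak_p, folds=cfg.folds, repeats=cfg.repeats, seed=seed
        )
        confusions.append(conf)
        cz = eps.channel_index("Cz")
        cz_avgs.append(_class_averages(eps, [cz]))
        data, labels, topo_names = _interpolated_topomap_data(eps)
        sel = eps.times >= 0.0
        topo_trials.append((data[:, :, sel], labels))
        post_cue_times = eps.times[sel]
        logs.append(log)

    # grand accuracy curve + CI at peak
    acc = np.stack([c.accuracy for c in curves])
    grand = acc.mean(axis=0)
    times = curves[0].times
    i_peak = int(np.argmax(grand))
    peak_mean, peak_lo, peak_hi = (
        t_ci(acc[:, i_peak], cfg.alpha)
        if cfg.n_participants >= 2
        else (float(grand[i_peak]), float("nan"), float("nan"))
    )
    # grand-average threshold: pooled kept trials across participants
    threshold = significance_threshold(
        n_trials=int(np.sum(kept_trials)), n_classes=n_classes,
        alpha=cfg.alpha, n_comparisons=len(times),
    )

    t_peak = float(times[i_peak])
    confusion = np.mean(confusions, axis=0)

    # Cz peak features + Friedman tests
    classes = sorted(cz_avgs[0])
    cz_stack = np.stack(
        [np.stack([avgs[c][0] for c in classes]) for avgs in cz_avgs]
    )  # participants x classes x time
    epoch_times = None
    # reconstruct times axis of epochs from window
    n_samp = cz_stack.shape[-1]
    epoch_times = cfg.epoch_window[0] + np.arange(n_samp) / cfg.paradigm.rate
    pf = peak_features(cz_stack, epoch_times)
    friedman = {
        name: friedman_by_class(tab)
        for name, tab in (
            ("pos_amp", pf.pos_amp),
            ("neg_amp", pf.neg_amp),
            ("pos_lat", pf.pos_lat),
            ("neg_lat", pf.neg_lat),
        )
    } if cfg.n_participants >= 2 else {}

    # difference topoplots + permutation mask
    mask, grid, thr = permutation_max_stat(
        topo_trials, post_cue_times, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
    )

    report = {
        "times": times,
        "grand_accuracy": grand,
        "per_participant_accuracy": acc,
        "peak_time": t_peak,
        "peak_accuracy": float(grand[i_peak]),
        "peak_ci": (peak_mean, peak_lo, peak_hi),
        "significance_threshold": threshold,
        "kept_trials": kept_trials,
        "confusion": confusion,
        "confusion_classes": cls_order,
        "classes": classes,
        "peak_features": pf,
        "friedman": friedman,
        "diff_grid": grid,
        "diff_mask": mask,
        "diff_threshold": thr,
        "topo_channel_names": topo_names,
        "logs": logs,
    }
    if cfg.out_dir:
        _write_offline_tables(cfg.out_dir, report)
    return report


def _write_offline_tables(out_dir: str, report: dict) -> None:
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(
        {"time_s": report["times"], "grand_accuracy_pct": report["grand_accuracy"]}
    ).to_csv(os.path.join(out_dir, "accuracy_curve.csv"), index=False)
    pd.DataFrame(
        report["per_participant_accuracy"].T,
        columns=[f"P{i+1:02d}" for i in range(report["per_participant_accuracy"].shape[0])],
    ).assign(time_s=report["times"]).to_csv(
        os.path.join(out_dir, "accuracy_per_participant.csv"), index=False
    )
    pd.DataFrame(
        report["diff_grid"], index=report["topo_channel_names"]
    ).to_csv(os.path.join(out_dir, "difference_topoplots.csv"))
    pd.DataFrame(
        report["diff_mask"].astype(int), index=report["topo_channel_names"]
    ).to_csv(os.path.join(out_dir, "difference_topoplot_mask.csv"))


def cut_rest_epochs(
    rec: EEGRecording,
    n_trials: int,
    window: tuple[float, float],
    rest_label: str = "rest_start",
    rest_len: float = 70.0,
) -> EpochSet:
    """Cut continuous rest runs into ``n_trials`` evenly spaced pseudo-trials.

    Pseudo-alignment points are spread over all rest periods so that the rest
    class matches the movement trial count; each pseudo-trial is epoched with
    the same window as the movement trials.
    """
    rests = rec.events_like(rest_label)
    if not rests:
        raise ValueError("recording contains no rest runs")
    lo, hi = window
    anchors = []
    per = n_trials // len(rests)
    extra = n_trials - per * len(rests)
    for i, ev in enumerate(rests):
        k = per + (1 if i < extra else 0)
        t0 = ev.onset / rec.rate
        usable_lo = t0 - lo  # ensure window start >= rest start
        usable_hi = t0 + rest_len - hi
        pts = np.linspace(usable_lo, usable_hi, k)
        anchors.extend(pts)
    n_win = int(round((hi - lo) * rec.rate))
    data = []
    for a in anchors:
        s0 = int(round((a + lo) * rec.rate))
        data.append(rec.signals[:, s0 : s0 + n_win])
    return EpochSet(
        data=np.stack(data),
        rate=rec.rate,
        t0_offset=lo,
        channels=list(rec.channels),
        labels=np.full(len(anchors), "rest", dtype=object),
    )


def probability_trace(
    rec: EEGRecording,
    model,
    cfg: FeatureWindowConfig,
    class_order: tuple[str, ...] = ONLINE_CLASS_ORDER,
    chunk: int = 65536,
) -> tuple[np.ndarray, int]:
    """Per-sample class probabilities of the causally filtered stream.

    Evaluates the classifier at every sample (the replay cadence); the first
    valid sample is the one where the full causal lag grid is available.
    Returns ``(trace, first_sample)`` with trace rows aligned to samples
    ``first_sample ...`` of the recording.
    """
    if cfg.alignment != "causal":
        raise ValueError("online replay requires a causal feature window")
    eeg = rec.channel_indices(kind="EEG", good_only=True)
    sig = rec.signals[eeg]
    lag_samp = np.round(cfg.lag_offsets() * rec.rate).astype(int)  # negative ... 0
    first = -lag_samp[0]
    n = rec.n_samples
    order = [list(model.classes).index(c) for c in class_order]
    out = np.empty((n - first, len(class_order)))
    for start in range(first, n, chunk):
        stop = min(n, start + chunk)
        idx = np.arange(start, stop)
        cols = [sig[:, idx + l] for l in lag_samp]  # each ch x t
        X = np.stack(cols, axis=-1).transpose(1, 0, 2).reshape(len(idx), -1)
        out[start - first : stop - first] = predict_proba(model, X)[:, order]
    return out, first


def run_online_experiment(cfg: RunConfig) -> dict:
    """Train the 5-class detector and replay a synthetic test session.

    The config's ``paradigm`` field is interpreted as the *training* paradigm
    sizes; the test session uses the online-test defaults with the same
    noise. Returns a report with the session table (attempts, TP, TPR,
    FP/min, accuracy), t_train, the chosen offset and the detection delay.
    """
    seeds = _participant_seeds(cfg.seed, 3)
    templates = cfg.templates or online_template_params()
    train_cfg = replace(
        cfg.paradigm, paradigm="online_training", classes=ONLINE_CLASSES, seed=seeds[0]
    )
    rec_train, truth_train = generate_online_training_session(
        train_cfg, templates, cfg.noise
    )
    clean_train, log_train = preprocess_online(rec_train)
    clean_train = common_average_reference(clean_train)
    wcfg = FeatureWindowConfig(
        length=cfg.window.length, lag_spacing=cfg.window.lag_spacing,
        alignment="causal", step=cfg.window.step,
    )
    move_eps = epoch(clean_train, "go_cue", (-2.0, 3.0))
    rest_eps = cut_rest_epochs(
        clean_train, move_eps.n_trials, (-2.0, 3.0),
        rest_len=train_cfg.rest_len,
    )
    combined = EpochSet(
        data=np.concatenate([move_eps.data, rest_eps.data]),
        rate=move_eps.rate,
        t0_offset=move_eps.t0_offset,
        channels=list(move_eps.channels),
        labels=np.concatenate([move_eps.labels, rest_eps.labels]),
    )
    t_train, t_train_acc = select_t_train(
        combined, wcfg, folds=cfg.folds, seed=seeds[0]
    )
    X, y = build_five_class_training(move_eps, rest_eps, t_train, wcfg)
    model = fit_slda(X, y)

    test_cfg = ParadigmConfig(
        paradigm="online_test",
        runs=cfg.test_runs,
        classes=ONLINE_CLASSES,
        movement_trials_per_run=cfg.test_movement_trials,
        rest_trials_per_run=cfg.test_rest_trials,
        period_len=cfg.test_period,
        seed=seeds[1],
        rate=cfg.paradigm.rate,
    )
    rec_test, truth_test = generate_online_test_session(test_cfg, templates, cfg.noise)
    clean_test, _ = preprocess_online(rec_test)
    # the deployed classifier fixes the channel policy: reuse the training
    # session's bad-channel set so feature dimensions match
    train_bad = set(log_train["bad_channels"])
    for i, c in enumerate(clean_test.channels):
        clean_test.channels[i] = replace(c, is_bad=c.name in train_bad)
    clean_test = common_average_reference(clean_test)
    trace, first = probability_trace(clean_test, model, wcfg)
    detections = run_detector(
        trace, clean_test.rate, cfg.detection, t_start=first / clean_test.rate
    )

    reported = np.array([a["report"] for a in truth_test.attempts])
    truth_classes = np.array([a["class"] for a in truth_test.attempts])
    rest_intervals = np.array(
        [t["period"] for t in truth_test.trials if t["class"] == "rest"]
    )
    if len(reported):
        offset, degenerate = select_tp_offset(detections, reported)
        evaluation = evaluate_online(
            detections, reported, truth_classes, rest_intervals, offset, t_train
        )
    else:
        offset, degenerate = 0.0, True
        evaluation = evaluate_online(
            detections, reported, truth_classes, rest_intervals, 0.0, t_train
        )

    report = {
        "t_train": t_train,
        "t_train_accuracy": t_train_acc,
        "detection_delay": detection_delay(t_train),
        "n_detections": len(detections),
        "detections": detections,
        "tp_offset": offset,
        "offset_degenerate": degenerate,
        "evaluation": evaluation,
        "n_reported": len(reported),
        "log": log_train,
    }
    if cfg.out_dir:
        _write_online_table(cfg.out_dir, report)
    return report


def _write_online_table(out_dir: str, report: dict) -> None:
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    ev = report["evaluation"]
    pd.DataFrame(
        [
            {
                "movement_attempts": ev.n_attempts,
                "tp_count": ev.tp_count,
                "tpr_pct": ev.tpr,
                "fp_per_min": ev.fp_per_min,
                "accuracy_pct": ev.accuracy,
                "tp_offset_s": ev.tp_offset,
                "detection_delay_s": ev.detection_delay,
                "t_train_s": report["t_train"],
            }
        ]
    ).to_csv(os.path.join(out_dir, "online_session_results.csv"), index=False)
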