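"""Self-paced movement detection: training-set construction, the three-window
state machine, delay accounting, and session evaluation.

The online classifier distinguishes five classes: the two movement classes
(hand open, palmar grasp), rest, and two auxiliary classes — *pre* and *post*
— trained on feature windows shifted -500 ms and +500 ms from ``t_train``
(the post-go-cue time of maximal cross-validated training accuracy). During
replay, a movement is detected at decision time ``t`` (with ``t0 = t -
650 ms``) when the pre-class probability exceeds 0.7 for a cumulative 150 ms
inside ``[t0-650, t0-350] ms``, either movement probability exceeds 0.9
inside ``[t0-50, t0+50] ms``, and the post-class probability exceeds 0.7 for
150 ms inside ``[t0+350, t0+650] ms``. The detected class is the movement
class with the higher probability inside the movement window; a 2 s
refractory period follows every detection. The decision uses samples up to
``t`` only, so the detector is causal.

Evaluation follows the deployed bookkeeping: a detection is a true positive
when it falls inside a 2 s window offset from a reported attempt (the offset
chosen by maximising the TP/FP detection ratio over a 0-5 s grid); TPR =
TP / P * 100 over reported attempts; FP/min counts detections in rest trials
only; class accuracy is computed over true positives only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EpochSet
from .decoding import FeatureWindowConfig, extract_features, sliding_accuracy

__all__ = [
    "MOVEMENT_CLASSES",
    "ONLINE_CLASS_ORDER",
    "DetectionConfig",
    "DetectionEvent",
    "OnlineEvaluation",
    "select_t_train",
    "build_five_class_training",
    "run_detector",
    "detection_delay",
    "select_tp_offset",
    "evaluate_online",
]

MOVEMENT_CLASSES = ("hand_open", "palmar_grasp")
ONLINE_CLASS_ORDER = ("hand_open", "palmar_grasp", "rest", "pre", "post")


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and windows of the detection state machine (times in s)."""

    pre_window: tuple[float, float] = (-0.650, -0.350)
    movement_window: tuple[float, float] = (-0.050, 0.050)
    post_window: tuple[float, float] = (0.350, 0.650)
    gate_threshold: float = 0.7
    gate_dwell: float = 0.150
    movement_threshold: float = 0.9
    refractory: float = 2.0
    consecutive_dwell: bool = False

    def __post_init__(self) -> None:
        for w in (self.pre_window, self.movement_window, self.post_window):
            if w[1] <= w[0]:
                raise ValueError(f"window {w} must be increasing")
        if not (self.pre_window[1] <= self.movement_window[0]
                and self.movement_window[1] <= self.post_window[0]):
            raise ValueError("windows must be ordered and non-overlapping")
        for th in (self.gate_threshold, self.movement_threshold):
            if not 0.0 < th < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.gate_dwell > self.pre_window[1] - self.pre_window[0]:
            raise ValueError("dwell cannot exceed the gate window length")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass(frozen=True)
class DetectionEvent:
    """One detection: decision time, reference time t0, class, window maxima."""

    time: float
    t0: float
    detected_class: str
    movement_probs: dict[str, float] = field(compare=False, default_factory=dict)


@dataclass
class OnlineEvaluation:
    """Session-level detection/classification metrics."""

    n_attempts: int
    tp_count: int
    tpr: float
    fp_per_min: float
    accuracy: float
    tp_offset: float
    detection_delay: float

    def __post_init__(self) -> None:
        if self.n_attempts > 0:
            assert abs(self.tpr - self.tp_count / self.n_attempts * 100.0) < 1e-9


def select_t_train(
    training_epochs: EpochSet,
    cfg: FeatureWindowConfig | None = None,
    interval: tuple[float, float] = (1.0, 2.0),
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid-search the post-go-cue time of maximal 10-fold CV accuracy.

    The grid covers ``interval`` in 1/16 s steps with a causal 1.4 s feature
    window; ties resolve to the earliest time. Returns ``(t_train,
    accuracy_percent)``. An accuracy near chance indicates uninformative
    training data and is up to the caller to act on.
    """
    cfg = cfg or FeatureWindowConfig(length=1.4, lag_spacing=0.2, alignment="causal")
    times = np.arange(
        np.ceil(interval[0] / cfg.step - 1e-9),
        np.floor(interval[1] / cfg.step + 1e-9) + 1,
    ) * cfg.step
    curve = sliding_accuracy(
        training_epochs, cfg, folds=folds, repeats=1, seed=seed, times=times
    )
    best = int(np.argmax(curve.accuracy))  # argmax takes the earliest tie
    return float(curve.times[best]), float(curve.accuracy[best])


def build_five_class_training(
    movement_epochs: EpochSet,
    rest_epochs: EpochSet,
    t_train: float,
    cfg: FeatureWindowConfig | None = None,
    pre_post_shift: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 5-class training set around ``t_train``.

    Movement classes contribute features at ``t_train``; the pre and post
    classes pool both movement classes at ``t_train -/+ pre_post_shift``
    (never rest trials); rest trials contribute at ``t_train``. The caller
    supplies ``rest_epochs`` already cut so that the rest trial count equals
    the total movement trial count (see :func:`cut_rest_epochs`).
    """
    cfg = cfg or FeatureWindowConfig(length=1.4, lag_spacing=0.2, alignment="causal")
    X_move = extract_features(movement_epochs, t_train, cfg)
    X_pre = extract_features(movement_epochs, t_train - pre_post_shift, cfg)
    X_post = extract_features(movement_epochs, t_train + pre_post_shift, cfg)
    X_rest = extract_features(rest_epochs, t_train, cfg)
    X = np.vstack([X_move, X_rest, X_pre, X_post])
    y = np.concatenate([
        movement_epochs.labels,
        np.full(rest_epochs.n_trials, "rest", dtype=object),
        np.full(movement_epochs.n_trials, "pre", dtype=object),
        np.full(movement_epochs.n_trials, "post", dtype=object),
    ])
    return X, y


def run_detector(
    prob_trace: np.ndarray,
    rate: float,
    cfg: DetectionConfig | None = None,
    class_order: tuple[str, ...] = ONLINE_CLASS_ORDER,
    t_start: float = 0.0,
) -> list[DetectionEvent]:
    """Run the three-window state machine over a 5-class probability trace.

    ``prob_trace`` is samples x classes in ``class_order``; the decision at
    sample ``t`` inspects only samples ``<= t``. Dwell is counted in whole
    samples (150 ms at 256 Hz means >= 39 supra-threshold samples), cumulative
    by default or consecutive with ``cfg.consecutive_dwell``. Returns the
    (refractory-respecting) detections, timestamped relative to ``t_start``.
    """
    cfg = cfg or DetectionConfig()
    p = np.asarray(prob_trace, dtype=float)
    if p.ndim != 2 or p.shape[1] != len(class_order):
        raise ValueError(f"trace must be samples x {len(class_order)} classes")
    n = p.shape[0]
    i_pre = class_order.index("pre")
    i_post = class_order.index("post")
    i_move = [class_order.index(c) for c in MOVEMENT_CLASSES]

    span = int(round((cfg.post_window[1] - cfg.pre_window[0]) * rate))
    if n < span + 1:
        return []

    dwell_n = int(np.ceil(cfg.gate_dwell * rate))
    pre_above = p[:, i_pre] > cfg.gate_threshold
    post_above = p[:, i_post] > cfg.gate_threshold
    move_p = p[:, i_move]
    move_max = move_p.max(axis=1)

    def window_idx(t_idx: int, w: tuple[float, float]) -> tuple[int, int]:
        a = t_idx + int(round(w[0] * rate))
        b = t_idx + int(round(w[1] * rate))
        return a, b + 1  # inclusive window, half-open slice

    def dwell_ok(above: np.ndarray, a: int, b: int) -> bool:
        seg = above[a:b]
        if not cfg.consecutive_dwell:
            return int(seg.sum()) >= dwell_n
        run = best = 0
        for v in seg:
            run = run + 1 if v else 0
            best = max(best, run)
        return best >= dwell_n

    detections: list[DetectionEvent] = []
    refr_n = int(round(cfg.refractory * rate))
    offset0 = int(round(-cfg.pre_window[0] * rate))  # t - t0 in samples... see below
    t0_lag = int(round(cfg.post_window[1] * rate))  # decision point is t0 + 650 ms
    t = t0_lag + offset0  # first sample where the full span is available
    while t < n:
        t0 = t - t0_lag
        a_pre, b_pre = window_idx(t0, cfg.pre_window)
        a_mov, b_mov = window_idx(t0, cfg.movement_window)
        a_post, b_post = window_idx(t0, cfg.post_window)
        if a_pre >= 0 and b_post <= t + 1:
            if (
                dwell_ok(pre_above, a_pre, b_pre)
                and move_max[a_mov:b_mov].max() > cfg.movement_threshold
                and dwell_ok(post_above, a_post, b_post)
            ):
                win_max = move_p[a_mov:b_mov].max(axis=0)
                cls = MOVEMENT_CLASSES[int(np.argmax(win_max))]
                detections.append(
                    DetectionEvent(
                        time=t_start + t / rate,
                        t0=t_start + t0 / rate,
                        detected_class=cls,
                        movement_probs={
                            c: float(v) for c, v in zip(MOVEMENT_CLASSES, win_max)
                        },
                    )
                )
                t += refr_n
                continue
        t += 1
    return detections


def detection_delay(t_train: float, post_shift: float = 0.5, half_dwell: float = 0.075) -> float:
    """Average maximum delay between attempt and detection: t_train + 575 ms.

    Composed of the classifier's discriminative lag (``t_train``), the shift
    to the post-window centre (500 ms), and half the 150 ms dwell.
    """
    if t_train < 0:
        raise ValueError("t_train must be >= 0")
    return t_train + post_shift + half_dwell


def _tp_windows(reported: np.ndarray, offset: float, window_len: float) -> np.ndarray:
    half = window_len / 2.0
    centres = reported + offset
    return np.stack([centres - half, centres + half], axis=1)


def _in_any_window(times: np.ndarray, windows: np.ndarray) -> np.ndarray:
    if len(windows) == 0:
        return np.zeros(len(times), dtype=bool)
    inside = (times[:, None] >= windows[None, :, 0]) & (
        times[:, None] <= windows[None, :, 1]
    )
    return inside.any(axis=1)


def select_tp_offset(
    detections: list[DetectionEvent],
    reported_events: np.ndarray,
    window_len: float = 2.0,
    grid: tuple[float, float] = (0.0, 5.0),
    grid_step: float = 0.1,
) -> tuple[float, bool]:
    """Choose the true-positive window offset maximising the TP/FP ratio.

    For each offset on the grid, detections inside any ``window_len`` window
    centred at ``event + offset`` are TPs (class-agnostic) and the rest FPs.
    Zero-FP offsets dominate all finite ratios and are compared by TP count;
    ties resolve to the smallest offset. Returns ``(offset, degenerate)``
    where ``degenerate`` flags the no-detection case (ratio 0 everywhere).
    """
    reported = np.asarray(reported_events, dtype=float)
    if len(reported) == 0:
        raise ValueError("need at least one reported attempt")
    det_times = np.array([d.time for d in detections])
    if len(det_times) == 0:
        return grid[0], True
    offsets = np.arange(grid[0], grid[1] + 1e-9, grid_step)
    best_key: tuple[float, float] = (-1.0, -1.0)
    best_off = offsets[0]
    for off in offsets:
        tp = int(_in_any_window(det_times, _tp_windows(reported, off, window_len)).sum())
        fp = len(det_times) - tp
        key = (float("inf"), float(tp)) if fp == 0 and tp > 0 else (
            tp / fp if fp > 0 else 0.0,
            float(tp),
        )
        if key > best_key:  # strict: ties keep the smallest offset
            best_key, best_off = key, float(off)
    return best_off, False


def evaluate_online(
    detections: list[DetectionEvent],
    reported_events: np.ndarray,
    truth_classes: np.ndarray,
    rest_intervals: np.ndarray,
    offset: float,
    t_train: float,
    window_len: float = 2.0,
) -> OnlineEvaluation:
    """Score a replayed session.

    ``reported_events`` are the attempt-report times with ``truth_classes``
    the cued class of each; ``rest_intervals`` is (n, 2) start/end times of
    the rest periods. TPR = TP / P * 100; FP/min counts detections inside
    rest intervals normalised by total rest minutes; accuracy is the % of TPs
    whose detected class matches the cue. Movement-trial detections outside
    the TP windows enter neither number.
    """
    reported = np.asarray(reported_events, dtype=float)
    truth_classes = np.asarray(truth_classes)
    rest_intervals = np.asarray(rest_intervals, dtype=float).reshape(-1, 2)
    det_times = np.array([d.time for d in detections])
    det_classes = np.array([d.detected_class for d in detections])

    windows = _tp_windows(reported, offset, window_len)
    tp_mask = _in_any_window(det_times, windows) if len(det_times) else np.array([], bool)
    tp_count = int(tp_mask.sum())
    p = len(reported)
    tpr = tp_count / p * 100.0 if p else 0.0

    correct = 0
    for t, c in zip(det_times[tp_mask], det_classes[tp_mask]):
        inside = (t >= windows[:, 0]) & (t <= windows[:, 1])
        centre_dist = np.abs(reported + offset - t)
        centre_dist[~inside] = np.inf
        j = int(np.argmin(centre_dist))
        if truth_classes[j] == c:
            correct += 1
    accuracy = 100.0 * correct / tp_count if tp_count else float("nan")

    rest_minutes = float(np.sum(rest_intervals[:, 1] - rest_intervals[:, 0])) / 60.0
    if len(det_times):
        in_rest = (
            (det_times[:, None] >= rest_intervals[None, :, 0])
            & (det_times[:, None] <= rest_intervals[None, :, 1])
        ).any(axis=1)
        fp_rest = int(in_rest.sum())
    else:
        fp_rest = 0
    fp_per_min = fp_rest / rest_minutes if rest_minutes > 0 else 0.0

    return OnlineEvaluation(
        n_attempts=p,
        tp_count=tp_count,
        tpr=tpr,
        fp_per_min=fp_per_min,
        accuracy=accuracy,
        tp_offset=offset,
        detection_delay=detection_delay(t_train),
    )
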