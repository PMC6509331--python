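"""Group-level statistics: difference topoplots, permutation testing, Cz peaks.

Difference topoplots summarise where class information lives on the scalp:
for each participant the trial-averaged potentials of every class pair are
subtracted, the absolute differences averaged over all pairs, then averaged
within non-overlapping 250 ms segments over 0-3 s after the class cue; the
grand grid is the mean over participants. Family-wise significance over
channels x segments is assessed with a one-tailed max-statistic permutation
test: class labels are shuffled within each participant, the shuffled grid
recomputed, and the null distribution built from the maximum over all cells,
so a single threshold controls the family-wise error by construction.

Cz peak analysis measures the early positive and later negative peaks of the
class-average waveform in fixed search windows, and class effects on those
features are tested with the Friedman rank test over participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.interpolate import RBFInterpolator

__all__ = [
    "DifferenceTopoplotGrid",
    "PeakFeatures",
    "difference_topoplots",
    "interpolate_bad_channels",
    "permutation_max_stat",
    "peak_features",
    "friedman_by_class",
    "t_ci",
    "significance_threshold",
]

#: Default segmentation: twelve 250 ms segments spanning 0-3 s post-cue.
DEFAULT_SEGMENT_EDGES = np.arange(0.0, 3.0 + 1e-9, 0.25)

#: Default Cz peak search windows (s post-cue): early maximum, later minimum.
POS_PEAK_WINDOW = (0.2, 0.9)
NEG_PEAK_WINDOW = (0.7, 2.5)


@dataclass
class DifferenceTopoplotGrid:
    """Channels x segments map of mean absolute pairwise class differences."""

    values: np.ndarray
    segment_edges: np.ndarray
    channel_names: list[str]
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("difference topoplot values must be non-negative")

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]


def _pairwise_abs_diff(class_avgs: dict[str, np.ndarray]) -> np.ndarray:
    """Mean over the C(k,2) pairwise |difference| maps (channels x time)."""
    keys = sorted(class_avgs)
    if len(keys) < 2:
        raise ValueError("need at least 2 classes")
    pairs = list(combinations(keys, 2))
    acc = np.zeros_like(class_avgs[keys[0]], dtype=float)
    for a, b in pairs:
        acc += np.abs(class_avgs[a] - class_avgs[b])
    return acc / len(pairs)


def _segment_average(
    grid: np.ndarray, times: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    out = np.zeros((grid.shape[0], len(edges) - 1))
    for s in range(len(edges) - 1):
        sel = (times >= edges[s]) & (times < edges[s + 1])
        if not np.any(sel):
            raise ValueError(f"no samples in segment [{edges[s]}, {edges[s+1]}) s")
        out[:, s] = grid[:, sel].mean(axis=1)
    return out


def difference_topoplots(
    class_averages: list[dict[str, np.ndarray]],
    times: np.ndarray,
    channel_names: list[str],
    segment_edges: np.ndarray | None = None,
) -> DifferenceTopoplotGrid:
    """Grand difference-topoplot grid.

    ``class_averages`` holds, per participant, a dict mapping class name to
    its trial-averaged channels x time potentials on a common channel grid
    (interpolate bad channels first). Symmetric in class order by
    construction (|a-b| = |b-a|).
    """
    edges = DEFAULT_SEGMENT_EDGES if segment_edges is None else np.asarray(segment_edges)
    per_part = [
        _segment_average(_pairwise_abs_diff(avgs), times, edges)
        for avgs in class_averages
    ]
    return DifferenceTopoplotGrid(
        values=np.mean(per_part, axis=0),
        segment_edges=edges,
        channel_names=list(channel_names),
    )


def interpolate_bad_channels(
    topomap: np.ndarray,
    positions: np.ndarray,
    bad: np.ndarray,
) -> np.ndarray:
    """Replace flagged channels by smooth-surface (biharmonic spline) interpolation.

    ``topomap`` is channels x time (or channels,), ``positions`` channels x 2,
    ``bad`` a boolean mask. Good channels are returned unchanged. Uses the
    thin-plate radial basis, the 2-D biharmonic Green's function.
    """
    topomap = np.asarray(topomap, dtype=float)
    single = topomap.ndim == 1
    vals = topomap[:, None] if single else topomap.copy()
    bad = np.asarray(bad, dtype=bool)
    if not bad.any():
        return topomap.copy()
    good = ~bad
    if good.sum() < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    interp = RBFInterpolator(
        positions[good], vals[good], kernel="thin_plate_spline"
    )
    vals = vals.copy()
    vals[bad] = interp(positions[bad])
    return vals[:, 0] if single else vals


def _segment_trials(data: np.ndarray, times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Trials x channels x segments means (commutes with class averaging)."""
    out = np.zeros(data.shape[:2] + (len(edges) - 1,))
    for s in range(len(edges) - 1):
        sel = (times >= edges[s]) & (times < edges[s + 1])
        if not np.any(sel):
            raise ValueError(f"no samples in segment [{edges[s]}, {edges[s+1]}) s")
        out[..., s] = data[..., sel].mean(axis=-1)
    return out


def _grid_from_segmented(seg: np.ndarray, labels: np.ndarray) -> np.ndarray:
    avgs = {c: seg[labels == c].mean(axis=0) for c in np.unique(labels)}
    return _pairwise_abs_diff(avgs)


def _grand_grid_from_trials(
    trials: list[tuple[np.ndarray, np.ndarray]],
    times: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    per_part = []
    for data, labels in trials:
        avgs = {
            c: data[labels == c].mean(axis=0) for c in np.unique(labels)
        }
        per_part.append(_segment_average(_pairwise_abs_diff(avgs), times, edges))
    return np.mean(per_part, axis=0)


def permutation_max_stat(
    trials: list[tuple[np.ndarray, np.ndarray]],
    times: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    segment_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-tailed max-statistic permutation test of the difference grid.

    ``trials`` holds, per participant, ``(data, labels)`` with data of shape
    trials x channels x time. Per permutation, class labels are shuffled
    within each participant and the grand grid recomputed; the null
    distribution is the maximum of each shuffled grid over channels x
    segments. A cell is significant when the observed grid exceeds the
    (1 - alpha) null quantile — one threshold for the whole family.

    Returns ``(mask, observed_grid, threshold)``.
    """
    import warnings

    if len(trials) < 1:
        raise ValueError("need at least one participant")
    if n_perm < 1 / alpha:
        warnings.warn(
            f"{n_perm} permutations cannot resolve alpha = {alpha}", stacklevel=2
        )
    edges = DEFAULT_SEGMENT_EDGES if segment_edges is None else np.asarray(segment_edges)
    rng = np.random.default_rng(seed)
    # segment-average once: class means commute with the (linear) segment mean
    segmented = [
        (_segment_trials(data, times, edges), labels) for data, labels in trials
    ]
    observed = np.mean(
        [_grid_from_segmented(seg, labels) for seg, labels in segmented], axis=0
    )
    null_max = np.empty(n_perm)
    for m in range(n_perm):
        grid = np.mean(
            [
                _grid_from_segmented(seg, labels[rng.permutation(len(labels))])
                for seg, labels in segmented
            ],
            axis=0,
        )
        null_max[m] = grid.max()
    # conservative order-statistic threshold (exact permutation validity)
    threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    if alpha >= 1.0:
        mask = np.ones_like(observed, dtype=bool)
    else:
        mask = observed > threshold
    return mask, observed, threshold


@dataclass
class PeakFeatures:
    """Positive/negative peak amplitude (uV) and latency (s) per waveform.

    ``degenerate`` flags waveforms where the measured peaks violate the
    expected morphology (non-positive early peak, non-negative late peak, or
    inverted latency order).
    """

    pos_amp: np.ndarray
    pos_lat: np.ndarray
    neg_amp: np.ndarray
    neg_lat: np.ndarray
    degenerate: np.ndarray


def peak_features(
    waveforms: np.ndarray,
    times: np.ndarray,
    pos_window: tuple[float, float] = POS_PEAK_WINDOW,
    neg_window: tuple[float, float] = NEG_PEAK_WINDOW,
) -> PeakFeatures:
    """Measure the two Cz peaks on class-average waveforms.

    ``waveforms`` is (..., time); the positive peak is the maximum inside
    ``pos_window``, the negative peak the minimum inside ``neg_window``.
    Degenerate morphologies (wrong sign or order) are measured anyway and
    flagged.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    pos_sel = (times >= pos_window[0]) & (times <= pos_window[1])
    neg_sel = (times >= neg_window[0]) & (times <= neg_window[1])
    if not pos_sel.any() or not neg_sel.any():
        raise ValueError("peak search windows outside the waveform time axis")
    flat = waveforms.reshape(-1, waveforms.shape[-1])
    ip = np.argmax(flat[:, pos_sel], axis=1)
    inn = np.argmin(flat[:, neg_sel], axis=1)
    tp, tn = times[pos_sel], times[neg_sel]
    shape = waveforms.shape[:-1]
    pos_amp = flat[np.arange(len(flat)), np.nonzero(pos_sel)[0][ip]].reshape(shape)
    neg_amp = flat[np.arange(len(flat)), np.nonzero(neg_sel)[0][inn]].reshape(shape)
    pos_lat = tp[ip].reshape(shape)
    neg_lat = tn[inn].reshape(shape)
    degenerate = (pos_amp <= 0) | (neg_amp >= 0) | (pos_lat >= neg_lat)
    return PeakFeatures(pos_amp, pos_lat, neg_amp, neg_lat, degenerate)


def friedman_by_class(values: np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test of a participants x classes table.

    Returns ``(chi2, df, p)`` with df = k - 1; ties are mid-ranked.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 participants and >= 2 classes")
    if np.any(~np.isfinite(values)):
        raise ValueError("table must have no missing cells")
    k = values.shape[1]
    if np.all(values == values[:, :1]):
        return 0.0, k - 1, 1.0  # scipy rejects all-identical columns
    chi2, p = stats.friedmanchisquare(*[values[:, j] for j in range(k)])
    return float(chi2), k - 1, float(p)


def t_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean with a t-distribution confidence interval: mean +- t * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need n >= 2")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    return mean, mean - tq * sem, mean + tq * sem


def significance_threshold(
    n_trials: int,
    n_classes: int,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> float:
    """Better-than-chance accuracy threshold (%), adjusted Wald + Bonferroni.

    Upper bound of the add-z^2/2 (adjusted Wald) binomial confidence interval
    around chance p0 = 1/n_classes with ``n_trials`` trials, at two-sided
    level ``alpha / n_comparisons``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    p0 = 1.0 / n_classes
    z = float(stats.norm.ppf(1.0 - (alpha / n_comparisons) / 2.0))
    x = n_trials * p0 + z**2 / 2.0
    n_adj = n_trials + z**2
    p_adj = x / n_adj
    upper = p_adj + z * np.sqrt(p_adj * (1.0 - p_adj) / n_adj)
    return float(min(upper, 1.0) * 100.0)
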