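"""Core signal/event containers: recordings, events, and epoch sets.

Conventions
-----------
* Sample indexing is 0-based throughout.
* Epoch sample ranges are half-open ``[start, end)``.
* Signals are stored channels x samples in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelInfo",
    "EventMarker",
    "EEGRecording",
    "EpochSet",
    "epoch",
    "KNOWN_EVENT_PREFIXES",
]

#: Closed enumeration of event labels understood by the pipelines. Labels with
#: a trailing ``:`` take a suffix (e.g. ``class_cue:palmar_grasp``). Unknown
#: labels round-trip through IO but are ignored by all pipeline stages.
KNOWN_EVENT_PREFIXES: tuple[str, ...] = (
    "trial_start",
    "class_cue:",
    "ready_cue",
    "go_cue",
    "reported_movement",
    "detection:",
    "rest_start",
)


@dataclass(frozen=True)
class ChannelInfo:
    """One recorded channel.

    Parameters
    ----------
    name : str
        Electrode label (10-5 system for EEG channels).
    kind : {"EEG", "EOG"}
    position : tuple of float or None
        2-D scalp coordinate for topographic maps; required for EEG channels.
    is_bad : bool
        Marked noisy; bad channels are excluded from decoding and referencing.
    """

    name: str
    kind: str = "EEG"
    position: tuple[float, float] | None = None
    is_bad: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("EEG", "EOG"):
            raise ValueError(f"channel kind must be EEG or EOG, got {self.kind!r}")
        if self.kind == "EEG" and self.position is None:
            raise ValueError(f"EEG channel {self.name!r} needs a 2-D position")


@dataclass(frozen=True, order=True)
class EventMarker:
    """A timestamped marker: 0-based sample index plus a string label."""

    onset: int
    label: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")

    @property
    def is_known(self) -> bool:
        return any(
            self.label == p or (p.endswith(":") and self.label.startswith(p))
            for p in KNOWN_EVENT_PREFIXES
        )


@dataclass
class EEGRecording:
    """Continuous multichannel recording in microvolts.

    ``signals`` has shape (n_channels, n_samples); ``events`` is sorted by
    onset. The hardware reference/ground are metadata and never appear as
    channels.
    """

    signals: np.ndarray
    rate: float
    channels: list[ChannelInfo]
    events: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but {len(self.channels)} channels"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            self.events = sorted(self.events)
        for e in self.events:
            if e.onset >= self.n_samples:
                raise ValueError(f"event {e.label!r} at {e.onset} beyond recording end")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def channel_indices(self, kind: str | None = None, good_only: bool = False) -> list[int]:
        out = []
        for i, c in enumerate(self.channels):
            if kind is not None and c.kind != kind:
                continue
            if good_only and c.is_bad:
                continue
            out.append(i)
        return out

    def events_like(self, prefix: str) -> list[EventMarker]:
        """Events whose label equals ``prefix`` or starts with ``prefix:``."""
        return [
            e for e in self.events
            if e.label == prefix or e.label.startswith(prefix + ":")
        ]

    def copy(self, signals: np.ndarray | None = None) -> "EEGRecording":
        return EEGRecording(
            signals=self.signals.copy() if signals is None else np.asarray(signals),
            rate=self.rate,
            channels=[replace(c) for c in self.channels],
            events=list(self.events),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGRecording):
            return NotImplemented
        return (
            self.rate == other.rate
            and self.channels == other.channels
            and self.events == other.events
            and self.signals.shape == other.signals.shape
            and np.array_equal(self.signals, other.signals)
        )


@dataclass
class EpochSet:
    """Trials x channels x samples, aligned to a reference event.

    ``t0_offset`` is the time (s) of the first sample relative to the
    alignment event; ``labels`` carries one class per trial and ``rejected``
    the artifact-rejection mask (True = dropped from analysis).
    """

    data: np.ndarray
    rate: float
    t0_offset: float
    channels: list[ChannelInfo]
    labels: np.ndarray
    rejected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("one rejection flag per trial required")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel list does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times (s) relative to the alignment event."""
        return self.t0_offset + np.arange(self.n_samples) / self.rate

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"no channel named {name!r}")

    def channel_indices(self, kind: str | None = None, good_only: bool = False) -> list[int]:
        out = []
        for i, c in enumerate(self.channels):
            if kind is not None and c.kind != kind:
                continue
            if good_only and c.is_bad:
                continue
            out.append(i)
        return out

    def kept(self) -> "EpochSet":
        """The subset of non-rejected trials."""
        keep = ~self.rejected
        return EpochSet(
            data=self.data[keep],
            rate=self.rate,
            t0_offset=self.t0_offset,
            channels=list(self.channels),
            labels=self.labels[keep],
            rejected=np.zeros(int(keep.sum()), dtype=bool),
        )

    def sample_at(self, t: float) -> int:
        """Index of the sample at time ``t`` (s, relative to alignment)."""
        idx = int(round((t - self.t0_offset) * self.rate))
        if not 0 <= idx < self.n_samples:
            raise ValueError(f"time {t} s outside the epoch window")
        return idx


def epoch(
    rec: EEGRecording,
    align_label: str,
    window: tuple[float, float],
    class_from: str = "preceding_class_cue",
) -> EpochSet:
    """Cut trials around every event matching ``align_label``.

    The first sample of each trial is ``round(onset + start_s * rate)`` and the
    sample range is half-open. Labels are drawn from the nearest preceding
    ``class_cue:<class>`` event (``class_from="preceding_class_cue"``), from
    the alignment event's own suffix (``"self"``), or left empty (``"none"``).

    Raises
    ------
    ValueError
        If any matched event's window falls outside the recording; the message
        lists every offending event.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError("epoch window must satisfy start < end")
    matched = rec.events_like(align_label)
    n_win = int(round((end_s - start_s) * rec.rate))

    starts, labels, bad = [], [], []
    cues = rec.events_like("class_cue")
    for ev in matched:
        s0 = int(round(ev.onset + start_s * rec.rate))
        if s0 < 0 or s0 + n_win > rec.n_samples:
            bad.append(ev)
            continue
        starts.append(s0)
        if class_from == "preceding_class_cue":
            prev = [c for c in cues if c.onset <= ev.onset]
            labels.append(prev[-1].label.split(":", 1)[1] if prev else "")
        elif class_from == "self":
            labels.append(ev.label.split(":", 1)[1] if ":" in ev.label else "")
        elif class_from == "none":
            labels.append("")
        else:
            raise ValueError(f"unknown labelling rule {class_from!r}")
    if bad:
        desc = ", ".join(f"{e.label}@{e.onset}" for e in bad)
        raise ValueError(f"epoch window outside recording for events: {desc}")

    data = (
        np.stack([rec.signals[:, s0 : s0 + n_win] for s0 in starts])
        if starts
        else np.empty((0, rec.n_channels, n_win))
    )
    return EpochSet(
        data=data,
        rate=rec.rate,
        t0_offset=start_s,
        channels=[replace(c) for c in rec.channels],
        labels=np.array(labels, dtype=object),
    )
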