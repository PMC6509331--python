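"""Reading and writing recordings.

Fixture format
--------------
A single HDF5 file with this layout (all fields required):

``/signals``
    float64 dataset, channels x samples, microvolts.
``/rate``
    scalar float attribute on the root group.
``/channels/{name,kind,is_bad}``
    parallel datasets (UTF-8 strings / uint8); ``/channels/position`` is a
    (n, 2) float dataset with NaN rows for channels without a position.
``/events/{onset,label}``
    parallel datasets (int64 sample indices / UTF-8 strings), onset-sorted.

The format round-trips bit-faithfully. The deposited study recordings
(GDF/EDF) can optionally be read through :func:`read_recording` with
``format="gdf_or_edf"``; nothing in the package requires them.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .data import ChannelInfo, EEGRecording, EventMarker

__all__ = ["read_recording", "write_recording"]

_STR = h5py.string_dtype(encoding="utf-8")


def write_recording(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write ``rec`` to the HDF5 fixture format (bit-faithful round-trip)."""
    try:
        f = h5py.File(path, "w")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write recording to {path!r}: {exc}") from exc
    with f:
        f.create_dataset("signals", data=rec.signals, dtype=np.float64)
        f.attrs["rate"] = float(rec.rate)
        g = f.create_group("channels")
        g.create_dataset("name", data=[c.name for c in rec.channels], dtype=_STR)
        g.create_dataset("kind", data=[c.kind for c in rec.channels], dtype=_STR)
        g.create_dataset(
            "is_bad", data=np.array([c.is_bad for c in rec.channels], dtype=np.uint8)
        )
        pos = np.full((len(rec.channels), 2), np.nan)
        for i, c in enumerate(rec.channels):
            if c.position is not None:
                pos[i] = c.position
        g.create_dataset("position", data=pos)
        e = f.create_group("events")
        e.create_dataset(
            "onset", data=np.array([ev.onset for ev in rec.events], dtype=np.int64)
        )
        e.create_dataset("label", data=[ev.label for ev in rec.events], dtype=_STR)


def _read_fixture(path: str | os.PathLike) -> EEGRecording:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open fixture file {path!r}: {exc}") from exc
    with f:
        if "rate" not in f.attrs:
            raise ValueError(f"fixture {path!r} is missing the sampling rate")
        for key in ("signals", "channels", "events"):
            if key not in f:
                raise OSError(f"fixture {path!r} is missing /{key}")
        signals = f["signals"][()]
        rate = float(f.attrs["rate"])
        g = f["channels"]
        names = [n.decode() if isinstance(n, bytes) else n for n in g["name"][()]]
        kinds = [k.decode() if isinstance(k, bytes) else k for k in g["kind"][()]]
        bads = g["is_bad"][()].astype(bool)
        pos = g["position"][()]
        channels = [
            ChannelInfo(
                name=names[i],
                kind=kinds[i],
                position=None if np.any(np.isnan(pos[i])) else tuple(pos[i]),
                is_bad=bool(bads[i]),
            )
            for i in range(len(names))
        ]
        e = f["events"]
        onsets = e["onset"][()]
        labels = [l.decode() if isinstance(l, bytes) else l for l in e["label"][()]]
        events = [EventMarker(int(o), lab) for o, lab in zip(onsets, labels)]
    return EEGRecording(signals=signals, rate=rate, channels=channels, events=events)


def _read_gdf_or_edf(path: str | os.PathLike) -> EEGRecording:
    # Optional reader for the deposited recordings; channel kinds are assigned
    # from names and annotations are preserved as generic events.
    import mne

    from .montage import eeg_positions

    path = os.fspath(path)
    reader = mne.io.read_raw_gdf if path.lower().endswith(".gdf") else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise OSError(f"cannot parse biosignal file {path!r}: {exc}") from exc
    if not raw.info["sfreq"]:
        raise ValueError(f"{path!r} does not declare a sampling rate")
    pos = eeg_positions()
    channels = []
    for name in raw.ch_names:
        if "eog" in name.lower():
            channels.append(ChannelInfo(name=name, kind="EOG"))
        else:
            channels.append(
                ChannelInfo(name=name, kind="EEG", position=pos.get(name, (0.0, 0.0)))
            )
    signals = raw.get_data() * 1e6  # volts -> microvolts
    events = [
        EventMarker(int(round(onset * raw.info["sfreq"])), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return EEGRecording(
        signals=signals, rate=float(raw.info["sfreq"]), channels=channels, events=events
    )


def read_recording(path: str | os.PathLike, format: str = "fixture") -> EEGRecording:
    """Read a recording.

    Parameters
    ----------
    path : path
    format : {"fixture", "gdf_or_edf"}
        ``fixture`` is the package's HDF5 container; ``gdf_or_edf`` reads the
        deposited study recordings through mne (optional functionality).
    """
    if format == "fixture":
        return _read_fixture(path)
    if format == "gdf_or_edf":
        return _read_gdf_or_edf(path)
    raise ValueError(f"unknown format {format!r}")
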