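"""Standard 61-channel EEG montage (10-5 system) plus EOG.

The EEG set covers frontal, central, parietal and temporal areas. 2-D scalp
coordinates for topographic maps are obtained by azimuthal-equidistant
projection of the standard 10-5 electrode positions, so that the vertex (Cz)
sits near the origin and angular distance from the vertex is preserved.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: 61 EEG electrode labels (10-5 system) used by the synthetic sessions.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: EOG derivations: one above the nasion, two below the outer canthi.
EOG_CHANNELS: tuple[str, ...] = ("EOG-nasion", "EOG-left", "EOG-right")


@functools.lru_cache(maxsize=1)
def _standard_positions_3d() -> dict[str, np.ndarray]:
    from mne.channels import make_standard_montage

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = make_standard_montage("standard_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def projected_position(name: str) -> tuple[float, float]:
    """2-D scalp coordinate of a 10-5 electrode (azimuthal-equidistant).

    Units are radians of angular distance from the vertex; Cz maps to ~(0, 0),
    temporal electrodes to a radius of ~pi/2.
    """
    pos = _standard_positions_3d()
    if name not in pos:
        raise KeyError(f"electrode {name!r} is not in the 10-5 montage")
    x, y, z = pos[name]
    # recentre on the head sphere fitted to all electrodes
    all_pos = np.array(list(pos.values()))
    centre = all_pos.mean(axis=0)
    v = np.array([x, y, z]) - centre
    r = np.linalg.norm(v)
    theta = np.arccos(np.clip(v[2] / r, -1.0, 1.0))  # angle from vertex axis
    phi = np.arctan2(v[1], v[0])
    return float(theta * np.cos(phi)), float(theta * np.sin(phi))


@functools.lru_cache(maxsize=1)
def eeg_positions() -> dict[str, tuple[float, float]]:
    """Projected 2-D positions for all 61 EEG channels."""
    return {name: projected_position(name) for name in EEG_CHANNELS}
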