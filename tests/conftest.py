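"""Shared fixtures: small synthetic sessions and helper constructors."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from mrcpkit.data import ChannelInfo, EEGRecording, EventMarker
from mrcpkit.synth import (
    MRCPTemplateParams,
    NoiseConfig,
    ParadigmConfig,
    PeakStats,
    default_template_params,
    generate_offline_session,
)


def zero_sd_params(**kwargs) -> MRCPTemplateParams:
    """Template params with all draw sds collapsed to point masses."""
    base = default_template_params()
    peaks = {
        c: (
            PeakStats(p.amp_mean, 0.0, p.lat_mean, 0.0),
            PeakStats(n.amp_mean, 0.0, n.lat_mean, 0.0),
        )
        for c, (p, n) in base.peaks.items()
    }
    return MRCPTemplateParams(peaks=peaks, **kwargs)


def quiet_noise(**kwargs) -> NoiseConfig:
    """No nuisance components at all."""
    defaults = dict(
        pink_rms=0.0, line_amp=0.0, blink_rate=0.0, artifact_rate=0.0,
        bad_channel_count=0,
    )
    defaults.update(kwargs)
    return NoiseConfig(**defaults)


def subset_recording(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Restrict a recording to the named channels (keeps event stream)."""
    idx = [rec.channel_index(n) for n in names]
    return EEGRecording(
        signals=rec.signals[idx].copy(),
        rate=rec.rate,
        channels=[replace(rec.channels[i]) for i in idx],
        events=list(rec.events),
    )


def toy_recording(
    n_channels: int = 4,
    n_samples: int = 512,
    rate: float = 256.0,
    seed: int = 0,
    events: list[tuple[int, str]] | None = None,
) -> EEGRecording:
    """A small random recording with simple grid positions."""
    rng = np.random.default_rng(seed)
    chans = [
        ChannelInfo(name=f"ch{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_channels)
    ]
    evs = [EventMarker(o, lab) for o, lab in (events or [])]
    return EEGRecording(
        signals=rng.standard_normal((n_channels, n_samples)),
        rate=rate,
        channels=chans,
        events=evs,
    )


@pytest.fixture(scope="session")
def small_offline_session():
    """One 2-run x 10-trial offline session with moderate noise (cached)."""
    pcfg = ParadigmConfig(paradigm="offline", runs=2, trials_per_run=10, seed=42)
    return generate_offline_session(pcfg, default_template_params(), NoiseConfig())


@pytest.fixture(scope="session")
def clean_offline_session():
    """Noise-free, sd-free offline session: Cz average equals the template."""
    pcfg = ParadigmConfig(paradigm="offline", runs=1, trials_per_run=10, seed=7)
    return generate_offline_session(pcfg, zero_sd_params(), quiet_noise())
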