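"""Synthetic EEG-like cohort generator.

Generates seeded cohorts with the study shape — groups x subjects x
channels x T samples at 128 Hz — and a controllable spectral contrast
between control and patient groups.  Each segment is a sum of

* band-limited Gaussian noise per clinical band, scaled to the group's
  band-power profile (with a per-subject log-normal jitter shared across
  channels, so subjects are consistent traits rather than fresh noise);
* narrow-band rhythmic oscillators (amplitude- and frequency-jittered
  sinusoids with a slowly varying envelope): an alpha (~10 Hz) rhythm,
  stronger in the eyes-closed groups, and — in the patient profile — a
  slow-wave (~2 Hz) delta rhythm, reflecting the spectral "slowing"
  (power shift toward delta/theta with reduced alpha) that characterises
  Alzheimer-type EEG;
* additive white measurement noise.

The generator is additive band-noise plus oscillators, not a biophysical
model: it reproduces group-level spectral structure, not waveform
morphology, artifacts or cross-channel coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .segments import CHANNELS_1020, Cohort, InvalidInputError, TimeSeriesSegment

__all__ = [
    "CohortSpec",
    "CONTROL_BAND_POWERS",
    "AD_BAND_POWERS",
    "generate_segment",
    "generate_cohort",
    "two_group_spec",
]

#: Band-noise variance profile of healthy elderly controls: alpha-dominant.
CONTROL_BAND_POWERS: dict[str, float] = {
    "delta": 0.6,
    "theta": 0.7,
    "alpha": 2.5,
    "beta": 0.5,
}

#: Patient profile: increased delta/theta, reduced alpha ("slowed" EEG).
AD_BAND_POWERS: dict[str, float] = {
    "delta": 2.5,
    "theta": 1.5,
    "alpha": 0.7,
    "beta": 0.4,
}

_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Centre frequency (Hz) of the rhythmic oscillator attached to each band.
_RHYTHM_FREQ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}

_DEFAULT_RHYTHMS: dict[str, dict[str, float]] = {
    # controls: alpha rhythm, stronger with eyes closed (B)
    "A": {"alpha": 0.9},
    "B": {"alpha": 1.8},
    # patients: attenuated alpha plus a pathological slow-wave delta rhythm
    "C": {"alpha": 0.25, "delta": 1.8},
    "D": {"alpha": 0.5, "delta": 1.8},
}

#: Posterior electrodes carry a stronger rhythmic component (the resting
#: alpha rhythm is occipito-parietal).
_DEFAULT_CHANNEL_GAIN = {
    ch: 1.25 for ch in ("O1", "O2", "Pz", "P3", "P4", "T5", "T6")
}


def _default_band_powers() -> dict[str, dict[str, float]]:
    return {
        "A": dict(CONTROL_BAND_POWERS),
        "B": dict(CONTROL_BAND_POWERS),
        "C": dict(AD_BAND_POWERS),
        "D": dict(AD_BAND_POWERS),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the seed determines it all."""

    groups: tuple[str, ...] = ("A", "B", "C", "D")
    subjects_per_group: int = 24
    channels: tuple[str, ...] = CHANNELS_1020
    T: int = 1024
    sampling_rate: float = 128.0
    band_powers: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_band_powers
    )
    rhythms: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in _DEFAULT_RHYTHMS.items()}
    )
    channel_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHANNEL_GAIN)
    )
    #: channels generated with the pooled mean profile of all groups —
    #: i.e. carrying no group contrast (useful as negative controls).
    null_channels: tuple[str, ...] = ()
    noise_level: float = 0.3
    subject_jitter: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise InvalidInputError("channel labels must be unique")
        if self.T < 64:
            raise InvalidInputError("T must be at least 64")
        if self.subjects_per_group < 1:
            raise InvalidInputError("need at least one subject per group")
        for g in self.groups:
            if g not in self.band_powers:
                raise InvalidInputError(f"no band-power profile for group {g!r}")
            for band, p in self.band_powers[g].items():
                if band not in _BAND_EDGES:
                    raise InvalidInputError(f"unknown band {band!r} in profile")
                if p < 0:
                    raise InvalidInputError("band powers must be nonnegative")
        for g, rh in self.rhythms.items():
            for band, amp in rh.items():
                if band not in _RHYTHM_FREQ:
                    raise InvalidInputError(f"unknown rhythm band {band!r}")
                if amp < 0:
                    raise InvalidInputError("rhythm amplitudes must be nonnegative")


def subject_ids(spec: CohortSpec) -> tuple[str, ...]:
    return tuple(f"s{i + 1:02d}" for i in range(spec.subjects_per_group))


def _rng_for(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(spec_seed),) + key))


@lru_cache(maxsize=64)
def _sos(order: int, lo: float, hi: float | None, btype: str, fs: float):
    wn = (lo, hi) if hi is not None else lo
    return scipy.signal.butter(order, wn, btype=btype, fs=fs, output="sos")


def _band_noise(rng, T: int, fs: float, band: str) -> np.ndarray:
    lo, hi = _BAND_EDGES[band]
    sos = _sos(4, lo, hi, "bandpass", fs)
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(T + 256))[128:-128]
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillator(rng, T: int, fs: float, freq: float) -> np.ndarray:
    """Unit-RMS narrow-band rhythm: jittered sinusoid with a slow envelope."""
    f = freq * float(np.exp(rng.normal(0.0, 0.03)))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(T) / fs
    slow = scipy.signal.sosfiltfilt(
        _sos(2, 0.4, None, "lowpass", fs), rng.standard_normal(T)
    )
    sd = slow.std()
    env = 1.0 + 0.3 * (slow / sd if sd > 0 else slow)
    env = np.clip(env, 0.1, None)
    x = env * np.sin(2.0 * np.pi * f * t + phase)
    return x / x.std()


def _effective_profiles(
    spec: CohortSpec, channel: str
) -> tuple[Mapping[str, Mapping[str, float]], Mapping[str, Mapping[str, float]]]:
    """Band-power and rhythm maps for a channel, pooled on null channels."""
    if channel not in spec.null_channels:
        return spec.band_powers, spec.rhythms
    bands = sorted(_BAND_EDGES)
    pooled_p = {
        b: float(np.mean([spec.band_powers[g].get(b, 0.0) for g in spec.groups]))
        for b in bands
    }
    pooled_r = {
        b: float(np.mean([spec.rhythms.get(g, {}).get(b, 0.0) for g in spec.groups]))
        for b in _RHYTHM_FREQ
    }
    return {g: pooled_p for g in spec.groups}, {g: pooled_r for g in spec.groups}


def generate_segment(
    spec: CohortSpec,
    group: str,
    channel: str,
    subject: str | int,
    seed: int | None = None,
) -> TimeSeriesSegment:
    """One deterministic synthetic segment for (seed, group, channel, subject)."""
    spec.validate()
    if group not in spec.groups:
        raise InvalidInputError(f"group {group!r} not in spec")
    if channel not in spec.channels:
        raise InvalidInputError(f"channel {channel!r} not in spec")
    base_seed = spec.seed if seed is None else int(seed)
    gi = spec.groups.index(group)
    ci = spec.channels.index(channel)
    if isinstance(subject, str):
        si = subject_ids(spec).index(subject)
        sid = subject
    else:
        si = int(subject)
        sid = f"s{si + 1:02d}"

    band_powers, rhythms = _effective_profiles(spec, channel)
    # subject-level band-power jitter: shared across channels
    subj_rng = _rng_for(base_seed, 1, gi, si)
    bands = sorted(_BAND_EDGES)
    jitter = {
        b: float(np.exp(subj_rng.normal(0.0, spec.subject_jitter))) for b in bands
    }
    rng = _rng_for(base_seed, 2, gi, si, ci)
    fs, T = spec.sampling_rate, spec.T
    gain = float(spec.channel_gain.get(channel, 1.0))

    x = np.zeros(T)
    for b in bands:
        power = band_powers[group].get(b, 0.0) * jitter[b]
        if power > 0:
            x += np.sqrt(power) * _band_noise(rng, T, fs, b)
    for b, amp in rhythms.get(group, {}).items():
        if amp > 0:
            x += amp * gain * jitter.get(b, 1.0) * _oscillator(
                rng, T, fs, _RHYTHM_FREQ[b]
            )
    if spec.noise_level > 0:
        x += spec.noise_level * rng.standard_normal(T)
    return TimeSeriesSegment(
        values=x,
        sampling_rate=fs,
        channel=channel,
        group=group,
        subject_id=sid,
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """The full groups x subjects x channels cohort for a spec."""
    spec.validate()
    cohort = Cohort()
    for group in spec.groups:
        for sid in subject_ids(spec):
            for channel in spec.channels:
                cohort.add(generate_segment(spec, group, channel, sid, seed=seed))
    return cohort


def two_group_spec(
    channels: Sequence[str] = ("F7",),
    groups: tuple[str, str] = ("A", "C"),
    subjects_per_group: int = 24,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A compact control-vs-patient spec (default profiles, fewer channels)."""
    return replace(
        CohortSpec(seed=seed),
        groups=tuple(groups),
        channels=tuple(channels),
        subjects_per_group=subjects_per_group,
        **overrides,
    )
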