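"""Acquisition-device profiles for the synthetic cohort generator.

Two profiles are registered. ``emotiv_like`` emulates a consumer-grade,
saline-electrode 128 Hz headset recorded in a school environment: stronger
50 Hz mains contamination, a narrowband hardware/environment harmonic near
32 Hz, more low-frequency electrode drift, and a higher rate of
high-amplitude artifact bursts. ``biosemi_like`` emulates a research-grade,
gel-electrode 512 Hz laboratory system with active shielding: the same
nuisance terms, but much weaker.

Amplitudes are root-mean-square microvolts of the injected component;
``artifact_rate`` is the expected fraction of one-second segments corrupted
by a burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DeviceProfile:
    name: str
    fs: float                 # sampling rate, Hz
    line_noise_amp: float     # 50 Hz sinusoid amplitude, uV
    harmonic_bump_amp: float  # ~32 Hz narrowband component, uV RMS
    drift_amp: float          # <1 Hz drift, uV RMS
    artifact_rate: float      # expected fraction of corrupted segments
    channels: tuple[str, ...] = ("F3", "F4")

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for attr in ("line_noise_amp", "harmonic_bump_amp", "drift_amp"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        for ch in ("F3", "F4"):
            if ch not in self.channels:
                raise ValueError(f"profile must include channel {ch}")


_REGISTRY: dict[str, DeviceProfile] = {
    "emotiv_like": DeviceProfile(
        name="emotiv_like",
        fs=128.0,
        line_noise_amp=2.0,
        harmonic_bump_amp=1.0,
        drift_amp=6.0,
        artifact_rate=0.04,
    ),
    "biosemi_like": DeviceProfile(
        name="biosemi_like",
        fs=512.0,
        line_noise_amp=0.4,
        harmonic_bump_amp=0.0,
        drift_amp=1.5,
        artifact_rate=0.01,
    ),
}


def device_profile(name: str) -> DeviceProfile:
    """Look up a registered device profile by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists valid names.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown device profile {name!r}; registered profiles: "
            f"{sorted(_REGISTRY)}"
        ) from None


def registered_profiles() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))
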