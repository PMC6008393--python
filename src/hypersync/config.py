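"""Simulation configuration for the synthetic triadic-hyperscanning generator.

The defaults describe the study design the package analyzes: 21 three-person
groups (one listener, two speakers, one of whom is attended), 11 optode
channels per person sampled at 10 Hz, a 280 s resting baseline and 280 s task
sessions, band-limited listener-attended coupling in 0.1-0.4 Hz, verbal /
non-verbal response logs at 1 Hz, 10 Hz speech amplitude envelopes with a
~0.8 Hz brain-envelope co-modulation, and 1/f + cardiac (~1 Hz) + Mayer-wave
(~0.1 Hz) physiological noise that is independent across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

ROLES = ("listener", "speaker_left", "speaker_right")
DYAD_ROLES = ("listener", "attended", "unattended")


class ConfigError(ValueError):
    """Raised for physically impossible simulation settings."""


@dataclass
class CouplingSpec:
    """One band-limited latent shared between two subjects' channels.

    ``strength`` is the variance fraction of the shared latent in each coupled
    channel (band-passed correlation of the pair ~= strength).  ``lag_s`` > 0
    means ``role_a``'s copy of the latent leads ``role_b``'s.
    """

    role_a: str = "listener"
    role_b: str = "attended"
    ch_a: int = 3
    ch_b: int = 3
    band_lo_hz: float = 0.1
    band_hi_hz: float = 0.4
    strength: float = 0.8
    lag_s: float = 0.0

    def validate(self, fs: float, n_channels: int) -> None:
        if self.role_a not in DYAD_ROLES or self.role_b not in DYAD_ROLES:
            raise ConfigError(f"roles must be in {DYAD_ROLES}")
        for ch in (self.ch_a, self.ch_b):
            if not 1 <= ch <= n_channels:
                raise ConfigError(f"channel {ch} outside 1..{n_channels}")
        if not 0 <= self.band_lo_hz < self.band_hi_hz <= fs / 2:
            raise ConfigError("coupling band must satisfy 0 <= lo < hi <= fs/2")
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError("strength must be in [0, 1]")
        if abs(self.lag_s) > 10:
            raise ConfigError("|lag_s| must be <= 10 s")


@dataclass
class BoostSpec:
    """Pre-response coupling boost: a Gaussian gain bump before verbal events.

    The bump is centered ``lead_s`` seconds before each verbal response (its
    neural time); in the measured hemodynamic signal it appears
    ``hemo_delay_s`` seconds later (the fNIRS delay-to-peak, ~6 s).
    """

    amplitude: float = 0.0
    lead_s: float = 5.0
    width_s: float = 2.0
    hemo_delay_s: float = 6.0


@dataclass
class EnvelopeCouplingSpec:
    """Shared ~0.8 Hz modulation between a speech envelope and brain channels.

    The attended speaker's envelope component is mixed into the speaker's own
    ``speaker_channel`` (inferior frontal cortex in the montage) and the
    listener's ``listener_channels`` (sensorimotor/auditory); the unattended
    speaker's envelope is mixed only into their own speaker channel.
    """

    speaker_channel: int = 4
    listener_channels: tuple = (5, 8, 9, 10)
    freq_hz: float = 0.8
    strength: float = 0.0
    band_halfwidth_hz: float = 0.2
    amplitude: float = 0.55  # RMS of the envelope-band component added to a channel


@dataclass
class NoiseSpec:
    """Structured physiological noise, independent across subjects."""

    one_over_f_exponent: float = 1.0
    one_over_f_amp: float = 0.5
    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp: float = 0.3


@dataclass
class SimConfig:
    n_groups: int = 21
    n_channels: int = 11
    fs: float = 10.0
    rest_duration_s: float = 280.0
    task_duration_s: float = 280.0
    couplings: list = field(default_factory=lambda: [CouplingSpec()])
    event_rate_per_min: float = 1.0
    nonverbal_rate_per_min: float = 1.0
    min_event_spacing_s: float = 21.0
    pre_event_boost: BoostSpec = field(default_factory=BoostSpec)
    envelope_coupling: EnvelopeCouplingSpec = field(default_factory=EnvelopeCouplingSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    neural_band_hz: tuple = (0.1, 0.4)
    strength_range: tuple | None = None  # per-group LA strength ~ U(lo, hi)
    couple_only_when_silent: bool = False
    quality_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_channels < 1:
            raise ConfigError("n_groups and n_channels must be positive")
        if self.rest_duration_s <= 0 or self.task_duration_s <= 0:
            raise ConfigError("durations must be positive")
        if self.fs <= 2 * self.envelope_coupling.freq_hz:
            raise ConfigError("fs must exceed twice the envelope coupling frequency")
        if not 0 <= self.envelope_coupling.strength <= 1:
            raise ConfigError("envelope strength must be in [0, 1]")
        env_chs = (self.envelope_coupling.speaker_channel,
                   *self.envelope_coupling.listener_channels)
        if any(not 1 <= c <= self.n_channels for c in env_chs):
            raise ConfigError("envelope coupling channel outside 1..n_channels")
        if self.event_rate_per_min < 0 or self.nonverbal_rate_per_min < 0:
            raise ConfigError("event rates must be >= 0")
        for c in self.couplings:
            c.validate(self.fs, self.n_channels)
        if self.strength_range is not None:
            lo, hi = self.strength_range
            if not 0 <= lo <= hi <= 1:
                raise ConfigError("strength_range must be within [0, 1]")

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["couplings"] = [CouplingSpec(**c) for c in d.get("couplings", [])]
        if "pre_event_boost" in d:
            d["pre_event_boost"] = BoostSpec(**d["pre_event_boost"])
        if "envelope_coupling" in d:
            ec = dict(d["envelope_coupling"])
            if "listener_channels" in ec:
                ec["listener_channels"] = tuple(ec["listener_channels"])
            d["envelope_coupling"] = EnvelopeCouplingSpec(**ec)
        if "noise" in d:
            d["noise"] = NoiseSpec(**d["noise"])
        for key in ("neural_band_hz", "strength_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
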