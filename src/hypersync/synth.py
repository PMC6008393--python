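"""Synthetic triadic-hyperscanning generator with known ground truth.

Signal model per subject channel (all components unit- or configured-variance,
sampled at ``fs``):

* a *neural* band-limited component: white Gaussian noise filtered by a
  zero-phase 4th-order Butterworth band-pass (0.1-0.4 Hz by default), then
  variance-normalized;
* for channels named in a :class:`~hypersync.config.CouplingSpec`, the neural
  component is ``a(t)*latent(t - lag) + sqrt(1 - a(t)^2)*private`` where the
  latent is shared within the dyad and ``a(t) = sqrt(strength)`` modulated by
  the optional pre-response boost kernel, so the band-passed correlation of a
  coupled pair equals ``strength`` when no boost is active;
* an optional ~0.8 Hz envelope-band component shared with a speaker's speech
  amplitude envelope (speaker's own IFC channel; listener's sensorimotor and
  auditory channels for the attended speaker only);
* structured physiological noise: 1/f background plus cardiac (~1 Hz) and
  Mayer-wave (~0.1 Hz) sinusoids with random phase per subject.  Phases are
  independent across subjects, so physiological noise cannot create
  inter-subject coherence.

Randomness uses one counter-based stream per (group, purpose, subject,
channel), split from the master seed with ``numpy`` ``SeedSequence`` spawn
keys, so every series is reproducible independently of generation order.

Rest sessions share the same marginal structure but carry no coupling, no
boost and no envelope component (nobody speaks at rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .config import ConfigError, SimConfig, BoostSpec
from .sessions import EventLog, GroupRecord, mask_from_events

_MAX_LAG_S = 10.0

# stream purpose codes for SeedSequence spawn keys
_ASSIGN, _PRIVATE, _LATENT, _EVENTS, _ENVELOPE, _QUALITY, _PHASES, _PINK = range(8)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (4th-order zero-phase Butterworth)."""
    if not 0 < lo < hi <= fs / 2:
        raise ConfigError(f"band [{lo}, {hi}] invalid for fs={fs} (Nyquist {fs/2})")
    white = rng.standard_normal(n)
    hi_eff = min(hi, 0.499 * fs)
    sos = signal.butter(4, [lo, hi_eff], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via FFT spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class GroundTruth:
    """Per-group realized simulation parameters (the recoverable answer key)."""

    group_index: int
    attended: str
    couplings: list  # realized CouplingSpecs (dyad roles, realized strengths)
    boost: BoostSpec
    verbal_events_s: np.ndarray
    nonverbal_events_s: np.ndarray
    envelope_strength: float
    la_strength: float  # quality driver
    quality: float | None = None
    meta: dict = field(default_factory=dict)


# --- events ---------------------------------------------------------------


def generate_event_log(config: SimConfig, rng: np.random.Generator | None = None,
                       seed: int | None = None) -> EventLog:
    """Verbal/non-verbal responses as a minimum-spacing point process at 1 Hz.

    Events keep >= ``min_event_spacing_s`` apart (epochs of +-10 s never
    overlap) and stay >= 12 s from the session edges so event-locked windows
    survive; the listener speaks for 5-9 s from each verbal onset (~10% of
    frames at the default rate).
    """
    if rng is None:
        rng = _stream(config.seed if seed is None else seed, _EVENTS, 0, 0)
    dur = int(round(config.task_duration_s))
    spacing = float(config.min_event_spacing_s)
    total_rate = (config.event_rate_per_min + config.nonverbal_rate_per_min) / 60.0
    if total_rate * spacing > 1.0:
        raise ConfigError(
            f"event rate {total_rate*60:.2f}/min infeasible with {spacing:.0f} s spacing"
        )
    edge = 12
    usable = dur - 2 * edge
    max_events = int(usable // spacing) + 1 if usable >= 0 else 0
    n_v = min(rng.poisson(config.event_rate_per_min * dur / 60.0), max_events)
    n_nv = min(rng.poisson(config.nonverbal_rate_per_min * dur / 60.0), max_events - n_v)
    k = n_v + n_nv
    labels = np.full(dur, "none", dtype="U9")
    speaking = np.zeros(dur, dtype=bool)
    if k > 0:
        slack = usable - (k - 1) * spacing
        offsets = np.sort(rng.uniform(0.0, max(slack, 0.0), size=k))
        times = np.round(edge + np.arange(k) * spacing + offsets).astype(int)
        cats = np.array(["verbal"] * n_v + ["nonverbal"] * n_nv)
        rng.shuffle(cats)
        for t, cat in zip(times, cats):
            labels[t] = cat
            if cat == "verbal":
                d = int(rng.integers(5, 10))
                speaking[t:t + d] = True
    return EventLog(labels=labels, listener_speaking=speaking)


def apply_event_boost(gain: np.ndarray, event_times_s: np.ndarray, boost: BoostSpec,
                      fs: float) -> np.ndarray:
    """Multiply a coupling-gain series by (1 + amplitude * K(t)).

    ``K`` is a sum of unit-height Gaussian kernels of SD ``width_s`` centered
    ``lead_s`` seconds *before* each event.
    """
    if boost.lead_s < 0:
        raise ConfigError("boost lead_s must be >= 0")
    gain = np.asarray(gain, dtype=float)
    if boost.amplitude == 0 or len(event_times_s) == 0:
        return gain.copy()
    t = np.arange(gain.size) / fs
    K = np.zeros_like(gain)
    for e in np.asarray(event_times_s, dtype=float):
        c = e - boost.lead_s
        K += np.exp(-0.5 * ((t - c) / boost.width_s) ** 2)
    return gain * (1.0 + boost.amplitude * K)


# --- group generation -----------------------------------------------------


def _assignment(config: SimConfig, g: int) -> tuple:
    rng = _stream(config.seed, _ASSIGN, g, 0)
    attended = "speaker_left" if rng.random() < 0.5 else "speaker_right"
    if config.strength_range is not None:
        lo, hi = config.strength_range
        la_strength = float(rng.uniform(lo, hi))
    else:
        la_strength = max((c.strength for c in config.couplings), default=0.0)
    return attended, la_strength


def _realized_couplings(config: SimConfig, la_strength: float) -> list:
    out = []
    for c in config.couplings:
        if config.strength_range is not None and {c.role_a, c.role_b} == {"listener", "attended"}:
            out.append(replace(c, strength=la_strength))
        else:
            out.append(replace(c))
    return out


def _subject_noise(config: SimConfig, g: int, subj: int, n: int, session: int) -> np.ndarray:
    """Structured noise for all channels of one subject (n_ch, n)."""
    ns = config.noise
    fs = config.fs
    t = np.arange(n) / fs
    phase_rng = _stream(config.seed, _PHASES, g, subj)
    # two sinusoid phases per session, drawn in a fixed order (rest first)
    for _ in range(session):
        phase_rng.uniform(0, 2 * np.pi, size=2)
    ph_card, ph_mayer = phase_rng.uniform(0, 2 * np.pi, size=2)
    sines = (
        ns.cardiac_amp * np.sin(2 * np.pi * ns.cardiac_hz * t + ph_card)
        + ns.mayer_amp * np.sin(2 * np.pi * ns.mayer_hz * t + ph_mayer)
    )
    rows = []
    for ch in range(config.n_channels):
        rng = _stream(config.seed, _PINK, g, subj * 100 + ch, session)
        rows.append(ns.one_over_f_amp * pink_noise(rng, n, fs, ns.one_over_f_exponent))
    return np.stack(rows) + sines[None, :]


def generate_group(config: SimConfig, group_index: int) -> tuple:
    """Generate one group's rest + task sessions; returns (GroupRecord, GroundTruth)."""
    config.validate()
    if group_index >= config.n_groups:
        raise ConfigError(f"group_index {group_index} >= n_groups {config.n_groups}")
    fs = config.fs
    n_task = int(round(config.task_duration_s * fs))
    n_rest = int(round(config.rest_duration_s * fs))
    g = group_index
    attended, la_strength = _assignment(config, g)
    couplings = _realized_couplings(config, la_strength)
    lo, hi = config.neural_band_hz

    events = generate_event_log(config, _stream(config.seed, _EVENTS, g, 0))
    verbal = events.event_times("verbal")
    nonverbal = events.event_times("nonverbal")

    record = GroupRecord(
        group_id=g, fs=fs, task_data={}, rest_data={}, attended=attended,
        events=events, envelopes={}, meta={"seed": config.seed},
    )
    roles = ("listener", "speaker_left", "speaker_right")

    # private neural base per (subject, channel), rest then task
    rest_neural, task_neural = {}, {}
    for si, role in enumerate(roles):
        rest_rows, task_rows = [], []
        for ch in range(config.n_channels):
            rng = _stream(config.seed, _PRIVATE, g, si * 100 + ch)
            rest_rows.append(band_noise(rng, n_rest, fs, lo, hi))
            task_rows.append(band_noise(rng, n_task, fs, lo, hi))
        rest_neural[role] = np.stack(rest_rows)
        task_neural[role] = np.stack(task_rows)

    # coupling: overwrite the task neural base of coupled channels
    pad = int(round(_MAX_LAG_S * fs))
    silent_gate = None
    if config.couple_only_when_silent:
        silent_gate = mask_from_events(events, fs).astype(float)
    for ci, cpl in enumerate(couplings):
        if cpl.strength == 0:
            continue
        lrng = _stream(config.seed, _LATENT, g, ci)
        latent_full = band_noise(lrng, n_task + 2 * pad, fs, cpl.band_lo_hz, cpl.band_hi_hz)
        lag_n = int(round(cpl.lag_s * fs))
        seg_a = latent_full[pad:pad + n_task]
        seg_b = latent_full[pad - lag_n:pad - lag_n + n_task]
        gain = np.full(n_task, np.sqrt(cpl.strength))
        if config.pre_event_boost.amplitude != 0 and verbal.size:
            b = config.pre_event_boost
            gain = apply_event_boost(gain, verbal + b.hemo_delay_s, b, fs)
        if silent_gate is not None:
            gain = gain * silent_gate
        gain = np.clip(gain, 0.0, 0.995)
        for side, (seat, ch, seg) in enumerate((
            (cpl.role_a, cpl.ch_a, seg_a),
            (cpl.role_b, cpl.ch_b, seg_b),
        )):
            role = {"listener": "listener", "attended": attended,
                    "unattended": record.unattended}[seat]
            prng = _stream(config.seed, _PRIVATE, g, 7000 + ci * 10 + side)
            private = band_noise(prng, n_task, fs, cpl.band_lo_hz, cpl.band_hi_hz)
            task_neural[role][ch - 1] = gain * seg + np.sqrt(1.0 - gain**2) * private

    # speech envelopes + envelope-band brain components.  The brain's
    # envelope-band (~0.8 Hz) activity exists in BOTH sessions with the same
    # variance; only its shared-with-the-envelope fraction is task-specific.
    # This keeps task and rest channels spectrally matched, so the
    # rest-control comparison is unconfounded when the coupling is off.
    ec = config.envelope_coupling
    se = ec.strength
    env_lo = max(0.05, ec.freq_hz - ec.band_halfwidth_hz)
    env_hi = min(0.499 * fs, ec.freq_hz + ec.band_halfwidth_hz)
    env_components = {}
    for si, speaker in enumerate(("speaker_left", "speaker_right")):
        erng = _stream(config.seed, _ENVELOPE, g, si)
        shared = band_noise(erng, n_task, fs, env_lo, env_hi)
        priv_env = band_noise(erng, n_task, fs, env_lo, env_hi)
        mix = np.sqrt(se) * shared + np.sqrt(1.0 - se) * priv_env
        record.envelopes[speaker] = np.clip(1.0 + 0.5 * mix, 0.0, None)
        env_components[speaker] = (shared, erng)

    def _env_add(role, ch, shared, erng):
        rest_neural[role][ch - 1] += ec.amplitude * band_noise(
            erng, n_rest, fs, env_lo, env_hi)
        priv = band_noise(erng, n_task, fs, env_lo, env_hi)
        task_neural[role][ch - 1] += ec.amplitude * (
            np.sqrt(se) * shared + np.sqrt(1.0 - se) * priv)

    for speaker, (shared, erng) in env_components.items():
        _env_add(speaker, ec.speaker_channel, shared, erng)
    att_shared, att_rng = env_components[attended]
    for ch in ec.listener_channels:
        _env_add("listener", ch, att_shared, att_rng)

    # assemble sessions: neural + structured noise
    for si, role in enumerate(roles):
        record.rest_data[role] = rest_neural[role] + _subject_noise(config, g, si, n_rest, 0)
        record.task_data[role] = task_neural[role] + _subject_noise(config, g, si, n_task, 1)

    truth = GroundTruth(
        group_index=g, attended=attended, couplings=couplings,
        boost=config.pre_event_boost, verbal_events_s=verbal.astype(float),
        nonverbal_events_s=nonverbal.astype(float), envelope_strength=se,
        la_strength=la_strength,
    )
    return record, truth


def generate_speech_envelope(config: SimConfig, group_index: int,
                             speaker: str = "speaker_left") -> np.ndarray:
    """The 10 Hz nonnegative envelope of one speaker (as built by generate_group)."""
    record, _ = generate_group(config, group_index)
    return record.envelopes[speaker]


def generate_quality_scores(truths: list, config: SimConfig) -> np.ndarray:
    """Five-point communication-quality scores driven by the true LA coupling.

    score = 1 + 4 * la_strength + N(0, quality_noise_sd), clipped to [1, 5].
    """
    scores = np.empty(len(truths))
    for i, truth in enumerate(truths):
        rng = _stream(config.seed, _QUALITY, truth.group_index, 0)
        s = 1.0 + 4.0 * truth.la_strength + rng.normal(0.0, config.quality_noise_sd)
        scores[i] = np.clip(s, 1.0, 5.0)
        truth.quality = float(scores[i])
    return scores


def simulate_study(config: SimConfig) -> tuple:
    """All groups of one study; returns (list[GroupRecord], list[GroundTruth])."""
    groups, truths = [], []
    for g in range(config.n_groups):
        rec, truth = generate_group(config, g)
        groups.append(rec)
        truths.append(truth)
    scores = generate_quality_scores(truths, config)
    for rec, q in zip(groups, scores):
        rec.quality = float(q)
    return groups, truths
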