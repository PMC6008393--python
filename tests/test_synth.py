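"""Synthetic generator: determinism, coupling encoding, events, envelopes."""

import numpy as np
import pytest
from scipy import signal

from hypersync.config import (
    BoostSpec,
    ConfigError,
    CouplingSpec,
    EnvelopeCouplingSpec,
    SimConfig,
)
from hypersync.synth import (
    GroundTruth,
    apply_event_boost,
    band_noise,
    generate_event_log,
    generate_group,
    generate_quality_scores,
    pink_noise,
)

FS = 10.0
BP = signal.butter(4, [0.1, 0.4], btype="bandpass", fs=FS, output="sos")


def _bp(x):
    return signal.sosfiltfilt(BP, x)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_cfg):
        a, _ = generate_group(small_cfg, 0)
        b, _ = generate_group(small_cfg, 0)
        for role in a.task_data:
            assert np.array_equal(a.task_data[role], b.task_data[role])
            assert np.array_equal(a.rest_data[role], b.rest_data[role])
        assert np.array_equal(a.events.labels, b.events.labels)

    def test_groups_differ(self, small_cfg):
        a, _ = generate_group(small_cfg, 0)
        b, _ = generate_group(small_cfg, 1)
        assert not np.allclose(a.task_data["listener"], b.task_data["listener"])


class TestCoupling:
    def test_uncoupled_channels_independent(self):
        """With no couplings, cross-subject correlations are sampling noise.

        The bound reflects the effective dof of band-limited + 1/f series
        over 280 s (max over 121 pairs stays below 0.3; independent streams).
        """
        cfg = SimConfig(n_groups=1, seed=9, couplings=[])
        rec, _ = generate_group(cfg, 0)
        L = rec.task_data["listener"]
        A = rec.task_data["speaker_left"]
        C = np.corrcoef(np.vstack([L, A]))[:11, 11:]
        assert np.max(np.abs(C)) < 0.30

    def test_band_passed_correlation_tracks_strength(self):
        """Strength 0.8 -> band-passed Pearson r ~= 0.8 +- 0.1 (noise-diluted)."""
        cfg = SimConfig(n_groups=2, seed=9, couplings=[CouplingSpec(strength=0.8)])
        for g in range(2):
            rec, _ = generate_group(cfg, g)
            x = _bp(rec.task_data["listener"][2])
            y = _bp(rec.task_data[rec.attended][2])
            r = np.corrcoef(x, y)[0, 1]
            assert 0.7 <= r <= 0.9

    def test_lag_encoded_in_cross_correlation(self):
        """A 2 s listener-lead puts the band-passed xcorr peak at -20 samples."""
        cfg = SimConfig(n_groups=1, seed=9,
                        couplings=[CouplingSpec(strength=0.8, lag_s=2.0)])
        rec, _ = generate_group(cfg, 0)
        x = _bp(rec.task_data["listener"][2])
        y = _bp(rec.task_data[rec.attended][2])
        n = x.size
        c = signal.correlate(x - x.mean(), y - y.mean(), mode="full")
        lags = np.arange(-(n - 1), n)
        peak = lags[np.argmax(c)]
        assert abs(peak - (-20)) <= 1

    def test_rest_session_uncoupled(self):
        cfg = SimConfig(n_groups=1, seed=9, couplings=[CouplingSpec(strength=0.9)])
        rec, _ = generate_group(cfg, 0)
        x = _bp(rec.rest_data["listener"][2])
        y = _bp(rec.rest_data[rec.attended][2])
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.3

    def test_invalid_band_rejected(self):
        cfg = SimConfig(couplings=[CouplingSpec(band_lo_hz=0.1, band_hi_hz=6.0)])
        with pytest.raises(ConfigError):
            cfg.validate()


class TestNoiseModel:
    def test_band_noise_spectral_placement(self, rng):
        """>= 80% of latent power falls inside the nominal band (Welch)."""
        z = band_noise(rng, 2800, FS, 0.1, 0.4)
        f, p = signal.welch(z, fs=FS, nperseg=512)
        frac = p[(f >= 0.095) & (f <= 0.42)].sum() / p.sum()
        assert frac >= 0.8
        assert z.std() == pytest.approx(1.0, abs=1e-6)

    def test_pink_noise_slope(self, rng):
        z = pink_noise(rng, 2 ** 14, FS, exponent=1.0)
        f, p = signal.welch(z, fs=FS, nperseg=4096)
        sel = (f > 0.02) & (f < 2.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert -1.4 < slope < -0.6

    def test_physiological_noise_phases_average_out(self):
        """Cardiac sinusoids have subject-specific random phases: any one
        group's cardiac-band correlation is cos(phase offset), but the signed
        correlation averages to ~0 across groups (no systematic locking)."""
        cfg = SimConfig(n_groups=12, seed=3, couplings=[])
        sos = signal.butter(4, [0.9, 1.1], btype="bandpass", fs=FS, output="sos")
        rs = []
        for g in range(cfg.n_groups):
            rec, _ = generate_group(cfg, g)
            x = signal.sosfiltfilt(sos, rec.task_data["listener"][0])
            y = signal.sosfiltfilt(sos, rec.task_data["speaker_left"][0])
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.35


class TestEvents:
    def test_zero_rate_all_none(self):
        cfg = SimConfig(event_rate_per_min=0.0, nonverbal_rate_per_min=0.0)
        log = generate_event_log(cfg)
        assert set(log.labels) == {"none"}
        assert not log.listener_speaking.any()

    def test_minimum_spacing_and_determinism(self):
        cfg = SimConfig(seed=4)
        log1 = generate_event_log(cfg)
        log2 = generate_event_log(cfg)
        assert np.array_equal(log1.labels, log2.labels)
        ev = np.sort(np.concatenate([log1.event_times("verbal"),
                                     log1.event_times("nonverbal")]))
        if ev.size > 1:
            assert np.diff(ev).min() >= 20  # 21 s spacing, integer rounding
        assert 0 < log1.event_times("verbal").size <= 13

    def test_infeasible_rate_raises(self):
        cfg = SimConfig(event_rate_per_min=4.0, nonverbal_rate_per_min=0.0)
        with pytest.raises(ConfigError):
            generate_event_log(cfg)

    def test_round_trip_through_tsv(self, tmp_path):
        from hypersync.sessions import read_events_tsv, write_events_tsv

        log = generate_event_log(SimConfig(seed=8))
        path = tmp_path / "events.tsv"
        write_events_tsv(path, log)
        back = read_events_tsv(path)
        assert np.array_equal(back.labels, log.labels)
        assert np.array_equal(back.listener_speaking, log.listener_speaking)

    def test_listener_speaking_fraction(self):
        """Speaking covers roughly 10% of frames at the default rate."""
        fracs = [generate_event_log(SimConfig(seed=s)).listener_speaking.mean()
                 for s in range(12)]
        assert 0.03 < np.mean(fracs) < 0.2


class TestBoost:
    def test_zero_amplitude_identity(self):
        gain = np.full(2800, 0.5)
        out = apply_event_boost(gain, [100.0], BoostSpec(amplitude=0.0), FS)
        assert np.array_equal(out, gain)

    def test_peak_precedes_event_by_lead(self):
        gain = np.ones(2800)
        boost = BoostSpec(amplitude=1.0, lead_s=5.0, width_s=2.0)
        out = apply_event_boost(gain, [100.0], boost, FS)
        assert abs(np.argmax(out) / FS - 95.0) < 0.11
        assert out.max() == pytest.approx(2.0, rel=1e-6)

    def test_change_confined_to_kernel_support(self):
        gain = np.ones(2800)
        boost = BoostSpec(amplitude=1.0, lead_s=5.0, width_s=2.0)
        out = apply_event_boost(gain, [100.0, 200.0], boost, FS)
        t = np.arange(2800) / FS
        far = np.ones_like(gain, dtype=bool)
        for e in (100.0, 200.0):
            far &= np.abs(t - (e - 5.0)) > 3 * 2.0
        assert np.max(np.abs(out[far] - 1.0)) < np.exp(-4.0)


class TestEnvelope:
    def test_nonnegative(self, coupled_study):
        _, groups, _ = coupled_study
        for g in groups:
            for env in g.envelopes.values():
                assert np.all(env >= 0)

    def test_strength_zero_independent_of_channels(self):
        cfg = SimConfig(n_groups=1, seed=13,
                        envelope_coupling=EnvelopeCouplingSpec(strength=0.0))
        rec, _ = generate_group(cfg, 0)
        env = rec.envelopes[rec.attended]
        sos = signal.butter(4, [0.6, 1.0], btype="bandpass", fs=FS, output="sos")
        e = signal.sosfiltfilt(sos, env)
        ch = signal.sosfiltfilt(sos, rec.task_data[rec.attended][3])
        assert abs(np.corrcoef(e, ch)[0, 1]) < 0.3

    def test_strength_point8_couples_speaker_channel(self):
        cfg = SimConfig(n_groups=1, seed=13,
                        envelope_coupling=EnvelopeCouplingSpec(strength=0.8))
        rec, _ = generate_group(cfg, 0)
        env = rec.envelopes[rec.attended]
        sos = signal.butter(4, [0.6, 1.0], btype="bandpass", fs=FS, output="sos")
        e = signal.sosfiltfilt(sos, env)
        ch = signal.sosfiltfilt(sos, rec.task_data[rec.attended][3])
        assert np.corrcoef(e, ch)[0, 1] >= 0.5


class TestQuality:
    @staticmethod
    def _truths(strengths):
        return [GroundTruth(group_index=i, attended="speaker_left", couplings=[],
                            boost=BoostSpec(), verbal_events_s=np.array([]),
                            nonverbal_events_s=np.array([]), envelope_strength=0.0,
                            la_strength=float(s))
                for i, s in enumerate(strengths)]

    def test_noise_free_scores_rank_with_strength(self):
        from scipy.stats import spearmanr

        cfg = SimConfig(quality_noise_sd=0.0)
        strengths = np.linspace(0.1, 0.9, 21)
        scores = generate_quality_scores(self._truths(strengths), cfg)
        assert spearmanr(scores, strengths).statistic == pytest.approx(1.0)

    def test_equal_strengths_leave_noise_variance(self):
        cfg = SimConfig(quality_noise_sd=0.3, seed=2)
        scores = generate_quality_scores(self._truths(np.full(200, 0.5)), cfg)
        assert np.var(scores) == pytest.approx(0.09, rel=0.35)

    def test_pearson_recovery_rate(self):
        """r(score, strength) > 0.6 in >= 90% of seeds at sd 0.3, n=21."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            strengths = rng.uniform(0.2, 0.8, size=21)
            cfg = SimConfig(quality_noise_sd=0.3, seed=seed)
            scores = generate_quality_scores(self._truths(strengths), cfg)
            hits += np.corrcoef(scores, strengths)[0, 1] > 0.6
        assert hits >= 0.9 * n_seeds
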