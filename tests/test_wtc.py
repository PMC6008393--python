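"""Wavelet transform, smoothing operator, and coherence core."""

import numpy as np
import pytest
from scipy import fft as sfft

from hypersync.wtc import (
    FOURIER_FACTOR,
    CoherenceError,
    GridError,
    ScaleGrid,
    coherence,
    coi_mask,
    cwt_morlet,
    morlet_filters,
    smooth,
)

FS = 10.0


class TestScaleGrid:
    def test_period_scale_relation(self):
        grid = ScaleGrid.default(2800, FS)
        assert np.allclose(grid.periods / grid.scales, FOURIER_FACTOR)
        assert abs(FOURIER_FACTOR - 1.0330) < 1e-4

    def test_default_range(self):
        grid = ScaleGrid.default(2800, FS)
        assert grid.scales[0] == pytest.approx(0.2)
        assert grid.scales[-1] <= 70.0

    @pytest.mark.parametrize("bad", [[1.0, 1.0], [2.0, 1.0], [-1.0, 1.0], []])
    def test_invalid_scales_rejected(self, bad):
        with pytest.raises(GridError):
            ScaleGrid(scales=np.asarray(bad, dtype=float))

    def test_band_indices(self):
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        f = grid.freqs[grid.band_indices(0.1, 0.4)]
        assert np.all((f >= 0.1) & (f <= 0.4))
        with pytest.raises(GridError):
            grid.band_indices(3.0, 4.0)


class TestCwt:
    def test_pure_cosine_peaks_at_matching_period(self):
        """A 0.2 Hz cosine concentrates |W| at the 5 s Fourier period."""
        n = 2800
        t = np.arange(n) / FS
        x = np.cos(2 * np.pi * 0.2 * t)
        grid = ScaleGrid.default(n, FS)
        W = cwt_morlet(x, grid, FS)
        interior = np.abs(W)[:, 800:2000].mean(axis=1)
        peak_period = grid.periods[np.argmax(interior)]
        assert abs(peak_period - 5.0) / 5.0 < 2 ** (1 / grid.voices) - 1 + 0.02

    def test_constant_series_transforms_to_zero(self):
        grid = ScaleGrid.default(512, FS)
        W = cwt_morlet(np.full(512, 3.7), grid, FS)
        assert np.max(np.abs(W)) < 1e-10

    def test_fft_conv_equals_direct_convolution(self, rng):
        """FFT path agrees with brute-force O(n^2) circular convolution."""
        n = 256
        x = rng.standard_normal(n)
        grid = ScaleGrid.default(n, FS)
        W = cwt_morlet(x, grid, FS)
        n_fft = 512  # next power of two above n
        xpad = np.zeros(n_fft)
        xpad[:n] = x - x.mean()
        filt = morlet_filters(grid, n_fft, FS)
        m = np.arange(n_fft)
        for i in [0, grid.n_scales // 2, grid.n_scales - 1]:
            kernel = sfft.ifft(filt[i])  # time-domain daughter on the padded grid
            direct = np.array(
                [np.sum(xpad * kernel[(k - m) % n_fft]) for k in range(n)]
            )
            assert np.max(np.abs(direct - W[i])) / np.max(np.abs(W[i])) < 1e-8

    def test_batched_equals_loop(self, rng):
        x = rng.standard_normal((3, 400))
        grid = ScaleGrid.default(400, FS)
        W = cwt_morlet(x, grid, FS)
        for i in range(3):
            assert np.allclose(W[i], cwt_morlet(x[i], grid, FS))

    def test_grid_vs_record_errors(self):
        grid = ScaleGrid.default(2800, FS)
        with pytest.raises(GridError):
            cwt_morlet(np.zeros(64), grid, FS)  # longest period > n/2


class TestSmooth:
    def test_constant_field_is_fixed_point(self):
        """Edge-renormalized smoothing leaves a constant field unchanged."""
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        f = np.full((grid.n_scales, 600), 2.5)
        out = smooth(f, grid, FS)
        assert np.max(np.abs(out - 2.5)) < 1e-10

    def test_mass_conservation_away_from_edges(self, rng):
        """Total mass of a nonnegative field is conserved within 1%."""
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        n = 2800
        f = rng.random((grid.n_scales, n)) + 0.5
        out = smooth(f, grid, FS)
        # compare interior mass (kernels at in-band scales are < 10 s SD)
        sl = slice(400, n - 400)
        assert abs(out[:, sl].sum() / f[:, sl].sum() - 1.0) < 0.01

    def test_double_smoothing_is_wider_gaussian(self, rng):
        """S(S(f)) at scale s equals one pass at sqrt(2)*s (variance adds)."""
        s = 3.0
        g1 = ScaleGrid(scales=np.array([s]), voices=1)  # voices=1: no scale boxcar
        g2 = ScaleGrid(scales=np.array([s * np.sqrt(2.0)]), voices=1)
        n = 2000
        f = rng.standard_normal((1, n))
        twice = smooth(smooth(f, g1, FS), g1, FS)
        wide = smooth(f, g2, FS)
        sl = slice(300, n - 300)
        scale = np.std(wide[0, sl])
        assert np.max(np.abs(twice[0, sl] - wide[0, sl])) / scale < 0.02

    def test_complex_field_smoothing_matches_parts(self, rng):
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        f = rng.standard_normal((grid.n_scales, 500)) + 1j * rng.standard_normal(
            (grid.n_scales, 500))
        out = smooth(f, grid, FS)
        assert np.allclose(out.real, smooth(f.real, grid, FS), atol=1e-10)
        assert np.allclose(out.imag, smooth(f.imag, grid, FS), atol=1e-10)


class TestCoherence:
    def test_self_coherence_is_unity_inside_coi(self, rng):
        x = rng.standard_normal(2800)
        grid = ScaleGrid.default(2800, FS)
        m = coherence(x, x, grid, FS)
        assert np.max(np.abs(m.r2[m.coi] - 1.0)) < 1e-6

    def test_symmetry_exact(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        grid = ScaleGrid.default(1000, FS)
        a = coherence(x, y, grid, FS)
        b = coherence(y, x, grid, FS)
        # |S(W_x W_y*)| = |S(W_y W_x*)| analytically; FFT round-off only
        assert np.max(np.abs(a.r2 - b.r2)) < 1e-12

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        grid = ScaleGrid.default(1000, FS)
        a = coherence(x, y, grid, FS)
        b = coherence(3.7 * x + 11.0, y, grid, FS)
        assert np.max(np.abs(a.r2 - b.r2)) < 1e-10

    def test_degenerate_inputs_raise(self):
        grid = ScaleGrid.default(1000, FS)
        with pytest.raises(CoherenceError):
            coherence(np.zeros(1000), np.ones(1000), grid, FS)
        with pytest.raises(CoherenceError):
            coherence(np.arange(1000.0), np.arange(999.0), grid, FS)

    def test_independent_noise_bias_bounded(self):
        """Monte-Carlo bound on the smoothing-limited null coherence.

        The Grinsted smoothing operator leaves a known positive bias under
        independence; the frozen bounds come from a 20-seed Monte-Carlo of
        this estimator: in-COI mean < 0.55 at every scale, deep-interior
        mean < 0.40 away from the Nyquist octave.
        """
        n = 2800
        grid = ScaleGrid.default(n, FS)
        acc_coi = np.zeros(grid.n_scales)
        acc_int = np.zeros(grid.n_scales)
        n_seeds = 12
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            m = coherence(r.standard_normal(n), r.standard_normal(n), grid, FS)
            masked = np.where(m.coi, m.r2, np.nan)
            acc_coi += np.nan_to_num(np.nanmean(masked, axis=1))
            acc_int += m.r2[:, 1200:1600].mean(axis=1)
        mean_coi = acc_coi / n_seeds
        mean_int = acc_int / n_seeds
        assert np.all(mean_coi < 0.55)
        away_from_nyquist = grid.periods > 0.4
        assert np.all(mean_int[away_from_nyquist] < 0.45)

    def test_shared_band_source_raises_band_coherence(self, rng):
        """Two series sharing a 0.1-0.4 Hz source at 0.9 beat independent ones."""
        from hypersync.synth import band_noise

        n = 2800
        shared = band_noise(rng, n, FS, 0.1, 0.4)
        mk = lambda: np.sqrt(0.9) * shared + np.sqrt(0.1) * band_noise(rng, n, FS, 0.1, 0.4)
        x, y = mk(), mk()
        u, v = band_noise(rng, n, FS, 0.1, 0.4), band_noise(rng, n, FS, 0.1, 0.4)
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        idx = grid.band_indices(0.1, 0.4)
        coupled = coherence(x, y, grid, FS).r2[idx].mean()
        uncoupled = coherence(u, v, grid, FS).r2[idx].mean()
        assert coupled > uncoupled + 0.25

    def test_coi_marks_edge_decay(self):
        """For an impulse at the record edge, in-cone energy is < e^-2 of peak."""
        n = 1200
        x = np.zeros(n)
        x[0] = 1.0
        grid = ScaleGrid.default(n, FS)
        W = np.abs(cwt_morlet(x, grid, FS)) ** 2
        coi = coi_mask(n, FS, grid)
        for i in range(grid.n_scales):
            # skip near-Nyquist scales: spectral truncation of the analytic
            # wavelet broadens the time envelope there
            if not coi[i].any() or grid.periods[i] < 0.5:
                continue
            peak = W[i].max()
            inside = W[i][coi[i]].max()
            assert inside <= np.exp(-2) * peak * 1.05
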