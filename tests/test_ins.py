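"""INS-increase statistic: band/time averaging, Fisher z, dz pipelines."""

import copy

import numpy as np
import pytest

from hypersync.ins import (
    SessionSpectra,
    band_time_average,
    dyad_matrices,
    fisher_z,
    ins_increase,
    ins_timecourse,
    pair_r2,
    silent_masked_matrices,
)
from hypersync.sessions import mask_from_events
from hypersync.wtc import ScaleGrid

from conftest import FAST

FS = 10.0


class TestFisherZ:
    def test_closed_forms(self):
        assert fisher_z(0.0) == 0.0
        assert float(fisher_z(0.5)) == pytest.approx(0.5493061443, abs=1e-9)

    def test_monotone(self, rng):
        c = np.sort(rng.random(50))
        z = fisher_z(c)
        assert np.all(np.diff(z) >= 0)

    def test_clip_near_one(self):
        assert np.isfinite(fisher_z(1.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)


class TestBandTimeAverage:
    @staticmethod
    def _toy_grid():
        # three scales with frequencies ~0.40, 0.20, 0.10 Hz
        periods = np.array([2.5, 5.0, 10.0])
        from hypersync.wtc import FOURIER_FACTOR

        return ScaleGrid(scales=periods / FOURIER_FACTOR, voices=1)

    def test_hand_computed_mean_with_mask(self):
        grid = self._toy_grid()
        r2 = np.array([
            [0.1, 0.2, 0.3, 0.4],
            [0.5, 0.6, 0.7, 0.8],
            [0.9, 1.0, 0.1, 0.2],
        ])
        mask = np.array([True, False, False, True])
        # scale-mean first: [0.5, 0.6, 11/30, 14/30]; then masked time mean
        expected = (0.5 + 14 / 30) / 2
        got = band_time_average(r2, grid, 0.05, 0.45, mask=mask)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_map_returns_constant(self):
        grid = self._toy_grid()
        assert band_time_average(np.full((3, 7), 0.42), grid, 0.05, 0.45) == \
            pytest.approx(0.42)

    def test_band_subset(self):
        grid = self._toy_grid()
        r2 = np.array([[1.0] * 4, [0.0] * 4, [0.0] * 4])
        # only the 0.4 Hz scale lies in [0.3, 0.45]
        assert band_time_average(r2, grid, 0.3, 0.45) == pytest.approx(1.0)

    def test_empty_mask_raises(self):
        grid = self._toy_grid()
        with pytest.raises(ValueError):
            band_time_average(np.ones((3, 4)), grid, 0.05, 0.45,
                              mask=np.zeros(4, bool))


class TestInsIncrease:
    def test_task_equals_rest_gives_zero(self, small_group):
        rec = copy.deepcopy(small_group[0])
        rec.task_data = {r: v.copy() for r, v in rec.rest_data.items()}
        assert ins_increase(rec, "LA", 3, 3) == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, small_group):
        rec = copy.deepcopy(small_group[0])
        base = ins_increase(rec, "LA", 3, 3)
        rec.task_data["listener"] = rec.task_data["listener"] * 4.2 + 7.0
        rec.rest_data["listener"] = rec.rest_data["listener"] * 0.3 - 2.0
        assert ins_increase(rec, "LA", 3, 3) == pytest.approx(base, abs=1e-9)

    def test_coupled_pair_positive(self, small_group):
        rec, truth = small_group
        dz_c = ins_increase(rec, "LA", 3, 3)
        dz_u = ins_increase(rec, "LA", 1, 2)
        assert dz_c > 0.15
        assert dz_c > dz_u + 0.1

    def test_self_coherence_map_averages_to_one(self, small_group):
        rec, _ = small_group
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        spec = SessionSpectra({"listener": rec.task_data["listener"]}, grid, FS)
        r2 = pair_r2(spec, "listener", 3, spec, "listener", 3)
        assert band_time_average(r2, grid) == pytest.approx(1.0, abs=1e-6)

    def test_fast_path_matches_exact(self, small_group):
        """single precision + time decimation changes dz only marginally."""
        rec, _ = small_group
        exact = ins_increase(rec, "LA", 3, 3)
        fast = ins_increase(rec, "LA", 3, 3, **FAST)
        assert fast == pytest.approx(exact, abs=2e-3)


class TestDyadMatrices:
    def test_matrix_consistent_with_per_pair(self, small_group, small_cfg):
        rec, _ = small_group
        mats = dyad_matrices(rec, dyads=("LA",))
        n = small_cfg.n_channels
        for (a, b) in [(1, 1), (3, 3), (2, 4)]:
            assert mats["LA"][a - 1, b - 1] == pytest.approx(
                ins_increase(rec, "LA", a, b), abs=1e-9)
        assert mats["LA"].shape == (n, n)
        assert np.all(np.isfinite(mats["LA"]))

    def test_au_matrix_transposes_under_attended_swap(self, small_group):
        rec = copy.deepcopy(small_group[0])
        mats = dyad_matrices(rec, dyads=("AU",))
        rec.attended = rec.unattended
        swapped = dyad_matrices(rec, dyads=("AU",))
        assert np.allclose(swapped["AU"], mats["AU"].T, atol=1e-9)


class TestSilentMask:
    def test_no_speaking_equals_unmasked(self, small_group):
        rec = copy.deepcopy(small_group[0])
        rec.events.listener_speaking[:] = False
        masked = silent_masked_matrices(rec, dyads=("LA",))
        plain = dyad_matrices(rec, dyads=("LA",))
        assert np.array_equal(masked["LA"], plain["LA"])

    def test_all_speaking_raises(self, small_group):
        rec = copy.deepcopy(small_group[0])
        rec.events.listener_speaking[:] = True
        with pytest.raises(ValueError):
            silent_masked_matrices(rec, dyads=("LA",))

    def test_silent_only_coupling_recovered_better_when_masked(self):
        """Coupling gated to listener-silent periods: masking helps dz."""
        from hypersync.config import CouplingSpec, EnvelopeCouplingSpec, SimConfig
        from hypersync.synth import generate_group

        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = SimConfig(n_groups=1, n_channels=4, seed=300 + seed,
                            couplings=[CouplingSpec(ch_a=3, ch_b=3, strength=0.7)],
                            couple_only_when_silent=True,
                            envelope_coupling=EnvelopeCouplingSpec(
                                speaker_channel=4, listener_channels=(2,),
                                strength=0.0),
                            event_rate_per_min=2.0, nonverbal_rate_per_min=0.0,
                            min_event_spacing_s=21.0)
            rec, _ = generate_group(cfg, 0)
            masked = silent_masked_matrices(rec, dyads=("LA",), **FAST)
            plain = dyad_matrices(rec, dyads=("LA",), **FAST)
            hits += masked["LA"][2, 2] >= plain["LA"][2, 2]
        assert hits >= 4


class TestTimecourse:
    def test_shift_construction(self, small_group):
        rec, _ = small_group
        tc6 = ins_timecourse(rec, "LA", 3, 3, shift_s=6, **FAST)
        tc0 = ins_timecourse(rec, "LA", 3, 3, shift_s=0, **FAST)
        n = tc0.values.size
        assert np.isnan(tc6.values[-6:]).all()
        assert np.allclose(tc6.values[: n - 6], tc0.values[6:], equal_nan=True)

    def test_averaging_commutes_before_fisher_z(self, small_group):
        """Time-mean of per-second coherence equals the scalar band-time mean."""
        rec, _ = small_group
        grid = ScaleGrid.for_band(0.1, 0.4, FS)
        role_a, role_b = rec.dyad_members("LA")
        spec = SessionSpectra(
            {role_a: rec.task_data[role_a], role_b: rec.task_data[role_b]},
            grid, FS)
        r2 = pair_r2(spec, role_a, 3, spec, role_b, 3)
        scalar = band_time_average(r2, grid)
        idx = grid.band_indices(0.1, 0.4)
        per_second = r2[idx].mean(axis=0).reshape(-1, 10).mean(axis=1)
        assert per_second.mean() == pytest.approx(scalar, abs=1e-6)

    def test_flat_rest_like_series_gives_flat_course(self, small_group):
        rec = copy.deepcopy(small_group[0])
        rec.task_data = {r: v.copy() for r, v in rec.rest_data.items()}
        tc = ins_timecourse(rec, "LA", 3, 3, shift_s=0)
        # identical sessions: values fluctuate around zero with mean ~ 0
        assert abs(np.nanmean(tc.values)) < 0.05

    def test_excessive_shift_raises(self, small_group):
        with pytest.raises(ValueError):
            ins_timecourse(small_group[0], shift_s=10_000)
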