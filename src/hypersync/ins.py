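"""The interpersonal-neural-synchronization (INS) increase statistic.

The core quantity is, per channel pair of a dyad,

    dz = arctanh( <R^2>_band,time (task) ) - arctanh( <R^2>_band,time (rest) )

where ``<R^2>_band,time`` is the squared wavelet coherence averaged
unweighted over the scales whose equivalent frequency falls in the analysis
band (0.1-0.4 Hz by default) and then over time; Fisher's arctanh is applied
to the band-time-averaged value itself (values are clipped to 1 - 1e-6
first).  The rest-session baseline is computed on the same subject pair and
channels and subtracted on the z scale.

Dyads are labeled LA (listener-attended speaker), LU (listener-unattended)
and AU (attended-unattended).  Matrices are n_channels x n_channels with the
row indexing the first member's channel.

Computation is organized around a per-session cache of CWT coefficients and
smoothed auto-spectra so that 121-pair matrices, masked recomputations, time
courses and pseudo-pair permutations all reuse the same transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sessions import GroupRecord, mask_from_events
from .wtc import (
    CoherenceError,
    ScaleGrid,
    coi_mask,
    cwt_morlet,
    r2_from_smoothed,
    smoothed_auto,
    smoothed_cross,
)

DEFAULT_BAND = (0.1, 0.4)


def fisher_z(c):
    """Fisher z (arctanh) of a coherence-scale value in [0, 1)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("coherence values must lie in [0, 1]")
    return np.arctanh(np.clip(c, 0.0, 1.0 - 1e-6))


def band_time_average(r2: np.ndarray, grid: ScaleGrid, f_lo: float = DEFAULT_BAND[0],
                      f_hi: float = DEFAULT_BAND[1], mask: np.ndarray | None = None,
                      coi: np.ndarray | None = None, exclude_coi: bool = False):
    """Unweighted mean over in-band scales, then over (masked) time samples.

    ``r2`` has shape (..., n_scales, n).  ``mask`` selects/weights time
    samples: boolean (True = include) or nonnegative float weights on the
    same time axis.  When ``exclude_coi`` is set, points outside the cone of
    influence are dropped from both averages (``coi`` required).
    """
    r2 = np.asarray(r2)
    idx = grid.band_indices(f_lo, f_hi)
    band = r2[..., idx, :]
    if exclude_coi:
        if coi is None:
            raise ValueError("exclude_coi requires the coi mask")
        band = np.where(coi[idx, :], band, np.nan)
    over_scales = np.nanmean(band, axis=-2)
    if mask is not None:
        w = np.asarray(mask, dtype=float)
        if w.size != r2.shape[-1]:
            raise ValueError("mask length does not match the time axis")
        if w.sum() <= 0:
            raise ValueError("empty time mask: no samples to average")
        valid = np.isfinite(over_scales)
        wt = np.where(valid, w, 0.0)
        out = np.nansum(over_scales * wt, axis=-1) / wt.sum(axis=-1)
    else:
        out = np.nanmean(over_scales, axis=-1)
    if np.any(np.isnan(out)):
        raise ValueError("band-time average undefined (all points excluded)")
    return out


# --- per-session spectra cache -------------------------------------------


class SessionSpectra:
    """CWT coefficients + smoothed auto-spectra for the channels of one session.

    ``single=True`` keeps coefficients in complex64 and ``decimate`` > 1
    block-averages spectra in time before smoothing; both are throughput
    options for the study-scale Monte-Carlo pipelines and leave the statistic
    unchanged to well below its sampling noise.
    """

    def __init__(self, data: dict, grid: ScaleGrid, fs: float,
                 channels: dict | None = None, single: bool = False,
                 decimate: int = 1):
        self.grid = grid
        self.fs = fs
        self.decimate = int(decimate)
        self.W = {}
        self.S = {}
        self.channels = {}
        for role, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            chans = channels.get(role) if channels else list(range(arr.shape[0]))
            sub = arr[chans]
            W = cwt_morlet(sub, grid, fs)
            if single:
                W = W.astype(np.complex64)
            self.W[role] = W
            self.S[role] = smoothed_auto(W, grid, fs, decimate=self.decimate)
            self.channels[role] = {ch: i for i, ch in enumerate(chans)}
        self.n = next(iter(data.values())).shape[-1]

    @property
    def n_dec(self) -> int:
        return self.n // self.decimate if self.decimate > 1 else self.n

    @property
    def fs_dec(self) -> float:
        return self.fs / self.decimate

    def coi(self) -> np.ndarray:
        return coi_mask(self.n_dec, self.fs_dec, self.grid)

    def get(self, role: str, ch0: int):
        i = self.channels[role][ch0]
        return self.W[role][i], self.S[role][i]


def pair_r2(spec_a: SessionSpectra, role_a: str, ch_a: int,
            spec_b: SessionSpectra, role_b: str, ch_b: int) -> np.ndarray:
    """R^2 map for one channel pair (channels 1-based), at spec resolution."""
    Wa, Sa = spec_a.get(role_a, ch_a - 1)
    Wb, Sb = spec_b.get(role_b, ch_b - 1)
    Sab = smoothed_cross(Wa, Wb, spec_a.grid, spec_a.fs, decimate=spec_a.decimate)
    return r2_from_smoothed(Sab, Sa, Sb)


def _cross_rows(spec: SessionSpectra, role_a: str, role_b: str) -> np.ndarray:
    """R^2 for all channel combinations of two roles, one row at a time.

    Returns (n_a, n_b, n_scales, n_dec); rows are batched to bound memory.
    """
    Wa, Sa = spec.W[role_a], spec.S[role_a]
    Wb, Sb = spec.W[role_b], spec.S[role_b]
    rows = []
    for i in range(Wa.shape[0]):
        Sab = smoothed_cross(Wa[i][None, ...], Wb, spec.grid, spec.fs,
                             decimate=spec.decimate)
        rows.append(r2_from_smoothed(Sab, Sa[i][None, ...], Sb))
    return np.stack(rows)


# --- public operations ----------------------------------------------------


def _grids_for(group: GroupRecord, band, grid: ScaleGrid | None):
    if grid is not None:
        return grid
    return ScaleGrid.for_band(band[0], band[1], group.fs)


def _prep_mask(mask, decimate: int):
    if mask is None:
        return None
    w = np.asarray(mask, dtype=float)
    from .wtc import block_mean

    return block_mean(w, decimate) if decimate > 1 else w


def ins_increase(group: GroupRecord, dyad: str = "LA", ch_a: int = 3, ch_b: int = 3,
                 band=DEFAULT_BAND, grid: ScaleGrid | None = None,
                 mask: np.ndarray | None = None, exclude_coi: bool = False,
                 single: bool = False, decimate: int = 1) -> float:
    """dz for one dyad and channel pair (task minus rest baseline)."""
    grid = _grids_for(group, band, grid)
    role_a, role_b = group.dyad_members(dyad)
    chans = {role_a: [ch_a - 1], role_b: [ch_b - 1]}
    if role_a == role_b:
        chans = {role_a: sorted({ch_a - 1, ch_b - 1})}
    opts = dict(single=single, decimate=decimate)
    task = SessionSpectra(
        {r: group.task_data[r] for r in {role_a, role_b}}, grid, group.fs, chans, **opts)
    rest = SessionSpectra(
        {r: group.rest_data[r] for r in {role_a, role_b}}, grid, group.fs, chans, **opts)
    kw = dict(f_lo=band[0], f_hi=band[1], exclude_coi=exclude_coi)
    c_task = band_time_average(
        pair_r2(task, role_a, ch_a, task, role_b, ch_b), grid,
        mask=_prep_mask(mask, decimate), coi=task.coi(), **kw)
    c_rest = band_time_average(
        pair_r2(rest, role_a, ch_a, rest, role_b, ch_b), grid, coi=rest.coi(), **kw)
    return float(fisher_z(c_task) - fisher_z(c_rest))


def dyad_matrices(group: GroupRecord, band=DEFAULT_BAND, grid: ScaleGrid | None = None,
                  dyads=("LA", "LU", "AU"), mask: np.ndarray | None = None,
                  exclude_coi: bool = False, single: bool = False,
                  decimate: int = 1) -> dict:
    """All-channel-combination dz matrices for the requested dyads.

    The optional ``mask`` (boolean at fs) applies to the task side only; the
    rest baseline is always unmasked.
    """
    grid = _grids_for(group, band, grid)
    fs = group.fs
    opts = dict(single=single, decimate=decimate)
    task = SessionSpectra(group.task_data, grid, fs, **opts)
    rest = SessionSpectra(group.rest_data, grid, fs, **opts)
    kw = dict(f_lo=band[0], f_hi=band[1], exclude_coi=exclude_coi)
    coi_t, coi_r = task.coi(), rest.coi()
    w = _prep_mask(mask, decimate)
    out = {}
    for dyad in dyads:
        role_a, role_b = group.dyad_members(dyad)
        c_t = band_time_average(_cross_rows(task, role_a, role_b), grid,
                                mask=w, coi=coi_t, **kw)
        c_r = band_time_average(_cross_rows(rest, role_a, role_b), grid,
                                coi=coi_r, **kw)
        out[dyad] = fisher_z(c_t) - fisher_z(c_r)
    return out


def silent_masked_matrices(group: GroupRecord, band=DEFAULT_BAND,
                           grid: ScaleGrid | None = None,
                           dyads=("LA", "LU", "AU"), **opts) -> dict:
    """dz matrices recomputed on the task samples where the listener is silent."""
    if group.events is None:
        raise ValueError("group has no event log to derive the silent mask from")
    mask = mask_from_events(group.events, group.fs)
    if not mask.any():
        raise ValueError("listener speaks in every frame: empty silent mask")
    return dyad_matrices(group, band=band, grid=grid, dyads=dyads, mask=mask, **opts)


@dataclass
class INSTimecourse:
    """1 Hz dz series for one channel pair, hemodynamic shift already applied."""

    values: np.ndarray  # NaN where the shift ran off the series end
    shift_s: int
    dyad: str
    ch_a: int
    ch_b: int
    rest_z: float


def ins_timecourse(group: GroupRecord, dyad: str = "LA", ch_a: int = 3, ch_b: int = 3,
                   shift_s: int = 6, band=DEFAULT_BAND,
                   grid: ScaleGrid | None = None, single: bool = False,
                   decimate: int = 1) -> INSTimecourse:
    """Per-second dz: band-averaged coherence per second, Fisher z, minus rest.

    The series is then advanced by ``shift_s`` seconds to undo the fNIRS
    delay-to-peak: the value attributed to second ``t`` is the measured value
    at ``t + shift_s``; the tail is NaN.
    """
    grid = _grids_for(group, band, grid)
    fs = group.fs
    role_a, role_b = group.dyad_members(dyad)
    chans = {role_a: [ch_a - 1], role_b: [ch_b - 1]}
    if role_a == role_b:
        chans = {role_a: sorted({ch_a - 1, ch_b - 1})}
    step = int(round(fs))
    if decimate > 1 and step % decimate != 0:
        raise ValueError("decimate must divide the samples-per-second count")
    opts = dict(single=single, decimate=decimate)
    task = SessionSpectra(
        {r: group.task_data[r] for r in {role_a, role_b}}, grid, fs, chans, **opts)
    rest = SessionSpectra(
        {r: group.rest_data[r] for r in {role_a, role_b}}, grid, fs, chans, **opts)
    r2 = pair_r2(task, role_a, ch_a, task, role_b, ch_b)
    idx = grid.band_indices(*band)
    c_t = r2[idx, :].mean(axis=0)  # band-averaged coherence vs time
    step_d = step // max(decimate, 1)
    n_sec = c_t.size // step_d
    c_sec = c_t[: n_sec * step_d].reshape(n_sec, step_d).mean(axis=1)
    c_rest = band_time_average(
        pair_r2(rest, role_a, ch_a, rest, role_b, ch_b), grid,
        f_lo=band[0], f_hi=band[1], coi=rest.coi())
    rest_z = float(fisher_z(c_rest))
    z = fisher_z(c_sec) - rest_z
    shift = int(shift_s)
    if shift >= n_sec:
        raise ValueError(f"shift {shift} s >= series length {n_sec} s")
    out = np.full(n_sec, np.nan)
    if shift >= 0:
        out[: n_sec - shift] = z[shift:]
    else:
        out[-shift:] = z[: n_sec + shift]
    return INSTimecourse(values=out, shift_s=shift, dyad=dyad, ch_a=ch_a, ch_b=ch_b,
                         rest_z=rest_z)


def study_matrices(groups: list, band=DEFAULT_BAND, grid: ScaleGrid | None = None,
                   dyads=("LA", "LU"), mask_silent: bool = False, **opts) -> dict:
    """Stack dz matrices across groups: dyad -> (n_groups, n_ch, n_ch)."""
    per_dyad = {d: [] for d in dyads}
    for group in groups:
        if mask_silent:
            mats = silent_masked_matrices(group, band=band, grid=grid, dyads=dyads,
                                          **opts)
        else:
            mats = dyad_matrices(group, band=band, grid=grid, dyads=dyads, **opts)
        for d in dyads:
            per_dyad[d].append(mats[d])
    return {d: np.stack(v) for d, v in per_dyad.items()}


def study_pair_dz(groups: list, dyad: str, ch_a: int, ch_b: int, band=DEFAULT_BAND,
                  grid: ScaleGrid | None = None, **opts) -> np.ndarray:
    """dz at a single channel pair for every group (fast path)."""
    return np.array([ins_increase(g, dyad, ch_a, ch_b, band=band, grid=grid, **opts)
                     for g in groups])
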