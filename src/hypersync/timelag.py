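"""Time-lagged INS increase: shift listener vs speaker by +-1..10 s.

Positive lag = "listener precede": the listener's activity at time t is
compared with the speaker's at t + lag.  Shifted series are truncated to the
overlapping segment (no wrap-around, which would manufacture coherence across
the seam); the rest baseline is computed unlagged on the full series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ins import DEFAULT_BAND, band_time_average, fisher_z
from .sessions import GroupRecord
from .stats import fdr_bh
from .wtc import ScaleGrid, cwt_morlet, r2_from_smoothed, smoothed_auto, smoothed_cross
from scipy import stats as sps


def _bta_pair(x: np.ndarray, y: np.ndarray, grid: ScaleGrid, fs: float,
              band, single: bool, decimate: int) -> float:
    Wx = cwt_morlet(x, grid, fs)
    Wy = cwt_morlet(y, grid, fs)
    if single:
        Wx = Wx.astype(np.complex64)
        Wy = Wy.astype(np.complex64)
    Sx = smoothed_auto(Wx, grid, fs, decimate=decimate)
    Sy = smoothed_auto(Wy, grid, fs, decimate=decimate)
    Sxy = smoothed_cross(Wx, Wy, grid, fs, decimate=decimate)
    r2 = r2_from_smoothed(Sxy, Sx, Sy)
    return float(band_time_average(r2, grid, f_lo=band[0], f_hi=band[1]))


def lagged_ins(group: GroupRecord, dyad: str = "LA", ch_a: int = 3, ch_b: int = 3,
               lag_s: int = 0, band=DEFAULT_BAND, grid: ScaleGrid | None = None,
               single: bool = False, decimate: int = 1) -> float:
    """dz with the listener-side series shifted by an integer-second lag.

    ``lag_s`` > 0 advances the listener (listener precede); only the
    overlapping (duration - |lag|) segment enters the coherence; the rest
    baseline is unlagged.
    """
    if float(lag_s) != int(lag_s):
        raise ValueError("lag must be an integer number of seconds (1 s step)")
    lag_s = int(lag_s)
    fs = group.fs
    L = int(round(abs(lag_s) * fs))
    role_a, role_b = group.dyad_members(dyad)
    x = np.asarray(group.task_data[role_a][ch_a - 1], dtype=float)
    y = np.asarray(group.task_data[role_b][ch_b - 1], dtype=float)
    n = x.size
    if L >= n:
        raise ValueError(f"|lag| {lag_s}s >= series duration")
    if grid is None:
        grid = ScaleGrid.for_band(band[0], band[1], fs)
    if lag_s > 0:  # listener at t vs speaker at t+lag
        xs, ys = x[: n - L], y[L:]
    elif lag_s < 0:
        xs, ys = x[L:], y[: n - L]
    else:
        xs, ys = x, y
    c_task = _bta_pair(xs, ys, grid, fs, band, single, decimate)
    xr = np.asarray(group.rest_data[role_a][ch_a - 1], dtype=float)
    yr = np.asarray(group.rest_data[role_b][ch_b - 1], dtype=float)
    c_rest = _bta_pair(xr, yr, grid, fs, band, single, decimate)
    return float(fisher_z(c_task) - fisher_z(c_rest))


def lag_profile(groups: list, dyads=("LA", "LU"), ch_a: int = 3, ch_b: int = 3,
                max_lag_s: int = 10, band=DEFAULT_BAND,
                grid: ScaleGrid | None = None, single: bool = True,
                decimate: int = 5) -> dict:
    """Per-group dz at every lag in -max..+max s: dyad -> (n_groups, n_lags)."""
    lags = np.arange(-max_lag_s, max_lag_s + 1)
    fs = groups[0].fs
    if grid is None:
        grid = ScaleGrid.for_band(band[0], band[1], fs)
    out = {}
    for dyad in dyads:
        vals = np.empty((len(groups), lags.size))
        for gi, g in enumerate(groups):
            role_a, role_b = g.dyad_members(dyad)
            x = np.asarray(g.task_data[role_a][ch_a - 1], dtype=float)
            y = np.asarray(g.task_data[role_b][ch_b - 1], dtype=float)
            z_rest = fisher_z(_bta_pair(
                np.asarray(g.rest_data[role_a][ch_a - 1], dtype=float),
                np.asarray(g.rest_data[role_b][ch_b - 1], dtype=float),
                grid, fs, band, single, decimate))
            n = x.size
            for li, lag in enumerate(lags):
                L = int(round(abs(int(lag)) * fs))
                if lag > 0:
                    xs, ys = x[: n - L], y[L:]
                elif lag < 0:
                    xs, ys = x[L:], y[: n - L]
                else:
                    xs, ys = x, y
                c = _bta_pair(xs, ys, grid, fs, band, single, decimate)
                vals[gi, li] = fisher_z(c) - z_rest
        out[dyad] = vals
    out["lags"] = lags
    return out


def lag_profile_contrast(profile: dict, q: float = 0.05) -> pd.DataFrame:
    """Paired LA-vs-LU contrast at each lag, FDR-corrected across lags."""
    la, lu, lags = profile["LA"], profile["LU"], profile["lags"]
    t, p = sps.ttest_rel(la, lu, axis=0)
    sig = fdr_bh(p, q=q)
    return pd.DataFrame(
        {
            "lag_s": lags,
            "mean_dz_LA": la.mean(axis=0),
            "mean_dz_LU": lu.mean(axis=0),
            "t": t,
            "p": p,
            "significant": sig,
        }
    )
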