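"""Brain-to-speech synchronization over 0.01-0.8 Hz.

The speech amplitude envelope (analytic-signal magnitude of the waveform, or
a pass-through when an envelope is supplied directly) is resampled to the
fNIRS rate and wavelet coherence is computed between it and a brain channel
on a scale grid extended to cover 0.01-0.8 Hz (periods >= 1.25 s).  The
control pairing is the same subject's resting-state series against the same
task envelope, and inference is a per-scale paired t across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps

from .ins import SessionSpectra, band_time_average, fisher_z, pair_r2
from .sessions import GroupRecord
from .stats import ancova_paired, StatResult
from .wtc import ScaleGrid, cwt_morlet, r2_from_smoothed, smoothed_auto, smoothed_cross

SPEECH_BAND = (0.01, 0.8)


def speech_grid(fs: float = 10.0, voices: int = 12,
                n_samples: int | None = None) -> ScaleGrid:
    """Scale grid spanning the 0.01-0.8 Hz brain-to-speech range.

    When the record length is known, the slowest frequency is capped so that
    no period exceeds a quarter of the record (the same cap as the default
    grid); slower scales carry no usable coherence information.
    """
    f_lo = SPEECH_BAND[0]
    if n_samples is not None:
        f_lo = max(f_lo, 4.0 * fs / n_samples)
    return ScaleGrid.for_band(f_lo, SPEECH_BAND[1], fs, voices=voices,
                              margin_octaves=0.0)


def condition_envelope(x: np.ndarray, fs_in: float, fs_out: float = 10.0) -> np.ndarray:
    """Bring a waveform or envelope to a nonnegative envelope at ``fs_out``.

    A waveform (any negative samples) is converted to its analytic-signal
    magnitude; the envelope is anti-alias low-passed at 4 Hz, resampled, and
    clipped nonnegative.  An input already at ``fs_out`` and nonnegative is
    returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    is_waveform = np.any(x < 0)
    if is_waveform:
        if fs_in < fs_out:
            raise ValueError(f"waveform sampling rate {fs_in} Hz below target {fs_out}")
        env = np.abs(signal.hilbert(x))
    else:
        if fs_in == fs_out:
            return x
        env = x
    if fs_in > 2 * 4.0:
        sos = signal.butter(4, 4.0, btype="lowpass", fs=fs_in, output="sos")
        env = signal.sosfiltfilt(sos, env)
    up, down = (np.round([fs_out, fs_in]) / np.gcd(int(round(fs_out)),
                                                   int(round(fs_in)))).astype(int)
    env = signal.resample_poly(env, up, down)
    return np.clip(env, 0.0, None)


@dataclass
class BrainSpeechProfile:
    """Per-scale time-mean coherence, task vs rest-control, with paired t."""

    channel: int
    freqs: np.ndarray
    coh_task: np.ndarray  # (n_groups, n_scales)
    coh_control: np.ndarray
    t: np.ndarray
    p: np.ndarray

    def table(self, threshold: float = 0.0005) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "coh_task": self.coh_task.mean(axis=0),
                "coh_control": self.coh_control.mean(axis=0),
                "t": self.t,
                "p": self.p,
                "significant": self.p < threshold,
            }
        )


def _scale_mean_coherence(x: np.ndarray, env: np.ndarray, grid: ScaleGrid,
                          fs: float, single: bool, decimate: int) -> np.ndarray:
    Wx = cwt_morlet(x, grid, fs)
    We = cwt_morlet(env, grid, fs)
    if single:
        Wx = Wx.astype(np.complex64)
        We = We.astype(np.complex64)
    Sx = smoothed_auto(Wx, grid, fs, decimate=decimate)
    Se = smoothed_auto(We, grid, fs, decimate=decimate)
    Sxe = smoothed_cross(Wx, We, grid, fs, decimate=decimate)
    r2 = r2_from_smoothed(Sxe, Sx, Se)
    return r2.mean(axis=-1)  # time-mean per scale


def brain_speech_profile(groups: list, channel: int, role: str = "listener",
                         speaker: str = "attended", grid: ScaleGrid | None = None,
                         single: bool = True, decimate: int = 2) -> BrainSpeechProfile:
    """Task vs rest-control coherence profile between a channel and an envelope.

    ``role`` picks whose brain ('listener' or 'speaker' = the envelope's
    owner); ``speaker`` picks whose envelope ('attended' or 'unattended').
    """
    fs = groups[0].fs
    if grid is None:
        grid = speech_grid(fs, n_samples=groups[0].task_data["listener"].shape[-1])
    task_rows, ctrl_rows = [], []
    for g in groups:
        env_role = g.role_of(speaker)
        brain_role = "listener" if role == "listener" else env_role
        env = np.asarray(g.envelopes[env_role], dtype=float)
        x_task = np.asarray(g.task_data[brain_role][channel - 1], dtype=float)
        x_rest = np.asarray(g.rest_data[brain_role][channel - 1], dtype=float)
        n = min(env.size, x_task.size, x_rest.size)
        task_rows.append(_scale_mean_coherence(x_task[:n], env[:n], grid, fs,
                                               single, decimate))
        ctrl_rows.append(_scale_mean_coherence(x_rest[:n], env[:n], grid, fs,
                                               single, decimate))
    coh_task = np.vstack(task_rows)
    coh_ctrl = np.vstack(ctrl_rows)
    t, p = sps.ttest_rel(coh_task, coh_ctrl, axis=0)
    return BrainSpeechProfile(channel=channel, freqs=grid.freqs, coh_task=coh_task,
                              coh_control=coh_ctrl, t=t, p=p)


def speech_covariate_adjustment(dz_la: np.ndarray, dz_lu: np.ndarray,
                                la_matrices: np.ndarray,
                                lu_matrices: np.ndarray,
                                speech_channels=(4, 5, 8, 9, 10)) -> StatResult:
    """LA-vs-LU contrast at one pair adjusted for speech-related channels.

    For each speech-synchronized channel c the dz values over all
    combinations involving c (row or column) are averaged per group and per
    dyad, averaged over dyads, and used as covariates in the paired ANCOVA.
    """
    covs = []
    for c in speech_channels:
        i = c - 1
        rows = np.concatenate([la_matrices[:, i, :], la_matrices[:, :, i],
                               lu_matrices[:, i, :], lu_matrices[:, :, i]], axis=1)
        covs.append(rows.mean(axis=1))
    covariates = np.column_stack(covs) if covs else None
    return ancova_paired(dz_la, dz_lu, covariates)
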