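"""Morlet continuous wavelet transform and wavelet transform coherence (WTC).

Implements the Grinsted-style squared wavelet coherence used throughout the
package:

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where ``W_x`` is the Morlet (omega0 = 6) CWT of ``x``, ``W_xy = W_x conj(W_y)``
and ``S`` is the Torrence-Webster smoothing operator: a Gaussian in time with
standard deviation ``s`` at scale ``s`` (frequency-domain kernel
``exp(-(s*omega)^2 / 2)``, the width used by the Grinsted wavelet-coherence
package) followed by a boxcar over scales 0.6 octaves wide.  Smoothing is normalized (the kernel mass inside the
data window divides the convolution) so a constant field is an eigenfunction
of ``S`` with eigenvalue 1, also at the edges.

The cone of influence (COI) uses the Morlet e-folding time ``sqrt(2) * s``:
a scale-time point is inside the cone when it is more than ``sqrt(2) * s``
seconds away from both edges of the record.

All transforms accept arrays with arbitrary leading (batch) dimensions; the
time axis is always the last axis.  This is what makes the 11 x 11-channel
pipelines affordable: one FFT pass covers a whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sfft

OMEGA0 = 6.0
#: Fourier period of a Morlet wavelet at unit scale: 4*pi / (w0 + sqrt(2 + w0^2)).
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
#: e-folding time of the Morlet envelope, in units of scale.
EFOLD = np.sqrt(2.0)


class GridError(ValueError):
    """Raised for scale grids that the record length / sampling cannot support."""


class CoherenceError(ValueError):
    """Raised when coherence is undefined (e.g. an all-zero input series)."""


def _next_pow2(n: int) -> int:
    p = 1 << (int(n) - 1).bit_length()
    return p if p > n else 2 * p


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric ladder of wavelet scales.

    Scales are in seconds; the equivalent Fourier period is
    ``FOURIER_FACTOR * scale`` (~1.033 * scale for omega0 = 6) and the
    equivalent frequency its reciprocal.
    """

    scales: np.ndarray
    voices: int = 12

    def __post_init__(self):
        s = np.asarray(self.scales, dtype=float)
        if s.ndim != 1 or s.size == 0 or np.any(np.diff(s) <= 0) or s[0] <= 0:
            raise GridError("scales must be a strictly increasing positive 1-D array")
        object.__setattr__(self, "scales", s)

    @property
    def periods(self) -> np.ndarray:
        return FOURIER_FACTOR * self.scales

    @property
    def freqs(self) -> np.ndarray:
        return 1.0 / self.periods

    @property
    def n_scales(self) -> int:
        return self.scales.size

    def band_indices(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Indices of scales whose equivalent frequency lies in [f_lo, f_hi]."""
        f = self.freqs
        idx = np.nonzero((f >= f_lo) & (f <= f_hi))[0]
        if idx.size == 0:
            raise GridError(f"no scales with frequency in [{f_lo}, {f_hi}] Hz")
        return idx

    @classmethod
    def default(cls, n: int, fs: float, voices: int = 12) -> "ScaleGrid":
        """Grinsted-style grid: s0 = 2*dt up to n*dt/4, `voices` per octave."""
        dt = 1.0 / fs
        s0 = 2.0 * dt
        smax = n * dt / 4.0
        if smax <= s0:
            raise GridError("record too short for the default scale range")
        J = int(np.floor(voices * np.log2(smax / s0)))
        scales = s0 * 2.0 ** (np.arange(J + 1) / voices)
        return cls(scales=scales, voices=voices)

    @classmethod
    def for_band(
        cls,
        f_lo: float,
        f_hi: float,
        fs: float,
        voices: int = 12,
        margin_octaves: float = 0.4,
    ) -> "ScaleGrid":
        """Grid covering [f_lo, f_hi] Hz plus a margin for the scale smoother.

        The margin keeps the 0.6-octave boxcar scale smoothing unbiased at the
        band edges when only the band is of interest.
        """
        if not (0 < f_lo < f_hi <= fs / 2):
            raise GridError("band must satisfy 0 < f_lo < f_hi <= fs/2")
        s_lo = (1.0 / f_hi) / FOURIER_FACTOR * 2.0 ** (-margin_octaves)
        s_hi = (1.0 / f_lo) / FOURIER_FACTOR * 2.0 ** (margin_octaves)
        s_lo = max(s_lo, 2.0 / fs)
        J = int(np.ceil(voices * np.log2(s_hi / s_lo)))
        scales = s_lo * 2.0 ** (np.arange(J + 1) / voices)
        return cls(scales=scales, voices=voices)


def _check_grid(grid: ScaleGrid, n: int, fs: float) -> None:
    dt = 1.0 / fs
    if grid.scales[0] < 2.0 * dt - 1e-12:
        raise GridError(f"smallest scale {grid.scales[0]:g}s below 2*dt = {2*dt:g}s")
    if grid.periods[-1] > n * dt / 2.0 + 1e-12:
        raise GridError(
            f"largest period {grid.periods[-1]:g}s exceeds half the record ({n*dt/2:g}s)"
        )


def morlet_filters(grid: ScaleGrid, n_fft: int, fs: float) -> np.ndarray:
    """Frequency-domain L2-normalized Morlet daughters, shape (n_scales, n_fft).

    The daughter at scale s has Fourier transform
    ``sqrt(2*pi*s*fs) * pi^(-1/4) * exp(-(s*w - w0)^2 / 2)`` on positive
    angular frequencies ``w`` and zero elsewhere (analytic wavelet).
    """
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)
    s = grid.scales[:, None]
    arg = s * omega[None, :] - OMEGA0
    filt = np.sqrt(2.0 * np.pi * s * fs) * np.pi**-0.25 * np.exp(-0.5 * arg**2)
    filt[:, omega <= 0] = 0.0
    return filt


def cwt_morlet(x: np.ndarray, grid: ScaleGrid, fs: float) -> np.ndarray:
    """Morlet CWT by FFT convolution; returns complex (..., n_scales, n).

    The series is mean-removed (a DC offset is meaningless to a zero-mean
    wavelet; no other filtering or detrending is applied), zero-padded to the
    next power of two, convolved with the frequency-domain daughters, and the
    padding removed.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    _check_grid(grid, n, fs)
    x = x - x.mean(axis=-1, keepdims=True)
    n_fft = _next_pow2(n)
    X = sfft.fft(x, n=n_fft, axis=-1)
    filt = morlet_filters(grid, n_fft, fs)
    W = sfft.ifft(X[..., None, :] * filt, axis=-1)
    return np.ascontiguousarray(W[..., :n])


@lru_cache(maxsize=32)
def _smooth_kernels(scales_key: tuple, n: int, fs: float) -> tuple:
    """Precompute FFT-domain time kernels and the edge-normalization field.

    Returns (n_fft, rfft multiplier, full-grid multiplier, edge norm); the
    multipliers are the Fourier transform of a unit-mass Gaussian of SD ``s``
    seconds at scale ``s`` (the Grinsted kernel ``exp(-(s*omega)^2 / 2)``).
    """
    scales = np.asarray(scales_key)
    n_fft = sfft.next_fast_len(int(n + np.ceil(5.0 * scales[-1] * fs)))
    omega_r = 2.0 * np.pi * np.fft.rfftfreq(n_fft, d=1.0 / fs)
    omega_f = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)
    gft_r = np.exp(-0.5 * (scales[:, None] * omega_r[None, :]) ** 2)
    gft_f = np.exp(-0.5 * (scales[:, None] * omega_f[None, :]) ** 2)
    ones = np.ones((1, n))
    norm = sfft.irfft(sfft.rfft(ones, n=n_fft, axis=-1) * gft_r, n=n_fft, axis=-1)[:, :n]
    norm = np.maximum(norm, 1e-300)
    return n_fft, gft_r, gft_f, norm


def _boxcar_scales(out: np.ndarray, voices: int) -> np.ndarray:
    """Normalized boxcar over 0.6 octaves along the scale axis (axis -2)."""
    win = max(1, int(round(0.6 * voices)))
    n_sc = out.shape[-2]
    if win <= 1 or n_sc == 1:
        return out
    lo = win // 2          # points taken below each index
    hi = win - 1 - lo      # points above
    cs = np.cumsum(out, axis=-2, dtype=out.dtype)
    pad_shape = out.shape[:-2] + (1,) + out.shape[-1:]
    zeros = np.zeros(pad_shape, dtype=out.dtype)
    cs = np.concatenate([zeros, cs], axis=-2)  # cs[k] = sum of first k
    idx_hi = np.minimum(np.arange(n_sc) + hi + 1, n_sc)
    idx_lo = np.maximum(np.arange(n_sc) - lo, 0)
    sums = cs[..., idx_hi, :] - cs[..., idx_lo, :]
    counts = (idx_hi - idx_lo).astype(np.float32 if out.real.dtype == np.float32
                                      else np.float64)
    return sums / counts.reshape((out.ndim - 2) * (1,) + (n_sc, 1))


def smooth(field: np.ndarray, grid: ScaleGrid, fs: float) -> np.ndarray:
    """Torrence-Webster smoothing of a (..., n_scales, n) field.

    Time: normalized (edge-renormalized) Gaussian convolution, SD = s at
    scale s.  Scale: normalized boxcar, 0.6 octaves wide.  Preserves single
    vs double precision and real vs complex dtype.
    """
    field = np.asarray(field)
    n = field.shape[-1]
    if field.shape[-2] != grid.n_scales:
        raise ValueError("field scale axis does not match the grid")
    n_fft, gft_r, gft_f, norm = _smooth_kernels(tuple(grid.scales), n, fs)
    single = field.real.dtype == np.float32
    if np.iscomplexobj(field):
        mult = gft_f.astype(np.complex64) if single else gft_f
        F = sfft.fft(field, n=n_fft, axis=-1)
        F *= mult
        out = sfft.ifft(F, axis=-1)[..., :n]
    else:
        mult = gft_r.astype(np.float32) if single else gft_r
        F = sfft.rfft(field, n=n_fft, axis=-1)
        F *= mult
        out = sfft.irfft(F, n=n_fft, axis=-1)[..., :n]
    out = out / (norm.astype(np.float32) if single else norm)
    return _boxcar_scales(out, grid.voices)


def coi_mask(n: int, fs: float, grid: ScaleGrid) -> np.ndarray:
    """Boolean (n_scales, n) mask, True where a point is inside the cone."""
    dt = 1.0 / fs
    t_edge = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    return EFOLD * grid.scales[:, None] <= t_edge[None, :]


@dataclass
class CoherenceMap:
    """Squared wavelet coherence in [0, 1] with its cone-of-influence mask."""

    r2: np.ndarray
    coi: np.ndarray
    grid: ScaleGrid
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.r2.shape != self.coi.shape:
            raise ValueError("r2 and coi shapes differ")


def block_mean(x: np.ndarray, d: int) -> np.ndarray:
    """Average the last axis in non-overlapping blocks of ``d`` samples."""
    if d <= 1:
        return x
    n = x.shape[-1]
    nb = n // d
    return x[..., : nb * d].reshape(x.shape[:-1] + (nb, d)).mean(axis=-1)


def smoothed_auto(W: np.ndarray, grid: ScaleGrid, fs: float,
                  decimate: int = 1) -> np.ndarray:
    """S(|W|^2 / s) for batched CWT coefficients (..., n_scales, n).

    ``decimate`` > 1 block-averages the spectrum in time before smoothing
    (valid because the Gaussian kernel is much wider than a block); used by
    the study-scale pipelines for throughput.
    """
    sinv = (1.0 / grid.scales[:, None]).astype(W.real.dtype)
    A = (W.real**2 + W.imag**2) * sinv
    return smooth(block_mean(A, decimate), grid, fs / decimate)


def smoothed_cross(Wa: np.ndarray, Wb: np.ndarray, grid: ScaleGrid, fs: float,
                   decimate: int = 1) -> np.ndarray:
    """S(W_a conj(W_b) / s), batched; see smoothed_auto for ``decimate``."""
    sinv = (1.0 / grid.scales[:, None]).astype(Wa.real.dtype)
    C = Wa * np.conj(Wb) * sinv
    return smooth(block_mean(C, decimate), grid, fs / decimate)


def r2_from_smoothed(Sab: np.ndarray, Sa: np.ndarray, Sb: np.ndarray) -> np.ndarray:
    """Squared coherence from smoothed cross- and auto-spectra, clipped to [0, 1]."""
    denom = Sa * Sb
    tiny = np.finfo(denom.dtype).tiny
    r2 = (Sab.real**2 + Sab.imag**2) / np.maximum(denom, tiny)
    return np.clip(r2, 0.0, 1.0)


def coherence(x: np.ndarray, y: np.ndarray, grid: ScaleGrid, fs: float) -> CoherenceMap:
    """Squared wavelet coherence of two equally sampled series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CoherenceError("x and y must be 1-D series of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CoherenceError("coherence undefined for a constant (all-zero) series")
    Wx = cwt_morlet(x, grid, fs)
    Wy = cwt_morlet(y, grid, fs)
    Sx = smoothed_auto(Wx, grid, fs)
    Sy = smoothed_auto(Wy, grid, fs)
    Sxy = smoothed_cross(Wx, Wy, grid, fs)
    r2 = r2_from_smoothed(Sxy, Sx, Sy)
    return CoherenceMap(r2=r2, coi=coi_mask(x.size, fs, grid), grid=grid, fs=fs)
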