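"""Pseudo-group permutation null for the INS increase.

All participants are re-assigned, role-preservingly, to new three-member
groups: listeners are permuted over triads and so are the two speaker seats
(each speaker keeps the attended/unattended label of their original
assignment).  Pseudo listener-speaker pairs therefore come from different
original groups and carry no true interaction; re-running the dz pipeline on
them builds the null distribution of the group-mean INS increase.

Empirical p-values use the add-one convention
``p = (1 + #{null >= observed}) / (1 + n_perm)`` (one-sided for an increase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ins import DEFAULT_BAND, SessionSpectra, band_time_average, fisher_z
from .wtc import ScaleGrid, r2_from_smoothed, smoothed_cross


@dataclass
class PermutationScheme:
    n_perm: int = 1000
    seed: int = 0
    exclude_original: bool = True


def permute_assignment(n_groups: int, scheme: PermutationScheme, iteration: int) -> dict:
    """Role-preserving reassignment for one iteration (deterministic).

    Returns arrays ``listener_src``, ``attended_src``, ``unattended_src`` of
    original group indices: pseudo triad ``i`` takes its listener from
    ``listener_src[i]`` etc.  No pseudo triad re-unites a listener with a
    speaker from the same original group (such pairs would carry true
    interaction), and the identity assignment is excluded when flagged.
    """
    if n_groups < 2:
        raise ValueError("cannot permute fewer than 2 groups")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scheme.seed, spawn_key=(77, iteration)))
    while True:
        listener = rng.permutation(n_groups)
        attended = rng.permutation(n_groups)
        unattended = rng.permutation(n_groups)
        if np.any(listener == attended) or np.any(listener == unattended):
            continue
        if scheme.exclude_original and (
            np.array_equal(listener, attended) and np.array_equal(listener, unattended)
        ):
            continue
        return {"listener_src": listener, "attended_src": attended,
                "unattended_src": unattended}


def _pair_spectra(groups, ch_l: int, ch_p: int, partner_dyad: str, grid, fs,
                  single: bool, decimate: int):
    """Per-group spectra for the listener channel and the partner channel."""
    Wl_t, Sl_t, Wp_t, Sp_t = [], [], [], []
    Wl_r, Sl_r, Wp_r, Sp_r = [], [], [], []
    for g in groups:
        partner = g.dyad_members(partner_dyad)[1]
        for data, Wl, Sl, Wp, Sp in (
            (g.task_data, Wl_t, Sl_t, Wp_t, Sp_t),
            (g.rest_data, Wl_r, Sl_r, Wp_r, Sp_r),
        ):
            spec = SessionSpectra(
                {"listener": data["listener"], partner: data[partner]},
                grid, fs, channels={"listener": [ch_l - 1], partner: [ch_p - 1]},
                single=single, decimate=decimate)
            wl, sl = spec.get("listener", ch_l - 1)
            wp, sp = spec.get(partner, ch_p - 1)
            Wl.append(wl), Sl.append(sl), Wp.append(wp), Sp.append(sp)
    stack = lambda v: np.stack(v)
    return (
        (stack(Wl_t), stack(Sl_t), stack(Wp_t), stack(Sp_t)),
        (stack(Wl_r), stack(Sl_r), stack(Wp_r), stack(Sp_r)),
    )


def _mean_dz(task, rest, li, pi, grid, fs, band, decimate):
    """Group-mean dz for listener indices ``li`` paired with partners ``pi``."""
    (Wl_t, Sl_t, Wp_t, Sp_t) = task
    (Wl_r, Sl_r, Wp_r, Sp_r) = rest
    fs_d = fs / decimate
    out = []
    for (Wl, Sl, Wp, Sp) in (
        (Wl_t[li], Sl_t[li], Wp_t[pi], Sp_t[pi]),
        (Wl_r[li], Sl_r[li], Wp_r[pi], Sp_r[pi]),
    ):
        Sab = smoothed_cross(Wl, Wp, grid, fs, decimate=decimate)
        r2 = r2_from_smoothed(Sab, Sl, Sp)
        out.append(fisher_z(band_time_average(r2, grid, f_lo=band[0], f_hi=band[1])))
    return float(np.mean(out[0] - out[1]))


def null_distribution(groups: list, scheme: PermutationScheme, ch_a: int = 3,
                      ch_b: int = 3, dyad: str = "LA", band=DEFAULT_BAND,
                      grid: ScaleGrid | None = None, single: bool = True,
                      decimate: int = 5) -> dict:
    """Permutation null of the group-mean dz at one channel pair.

    Returns the observed statistic, ``n_perm`` null samples, summary
    quantiles and the one-sided empirical p of the true pairing.
    """
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("cannot permute fewer than 2 groups")
    fs = groups[0].fs
    if grid is None:
        grid = ScaleGrid.for_band(band[0], band[1], fs)
    # smoothing at full resolution per original pairing happens once; the
    # CWTs and auto-spectra are shared by every iteration
    task, rest = _pair_spectra(groups, ch_a, ch_b, dyad, grid, fs, single, decimate)
    ident = np.arange(n_groups)
    observed = _mean_dz(task, rest, ident, ident, grid, fs, band, decimate)
    null = np.empty(scheme.n_perm)
    for it in range(scheme.n_perm):
        asg = permute_assignment(n_groups, scheme, it)
        src = asg["attended_src" if dyad == "LA" else "unattended_src"]
        null[it] = _mean_dz(task, rest, asg["listener_src"], src, grid, fs, band,
                            decimate)
    p = empirical_p(observed, null)
    return {
        "observed": observed,
        "null": null,
        "p": p,
        "q2.5": float(np.percentile(null, 2.5)),
        "q97.5": float(np.percentile(null, 97.5)),
        "pair": (ch_a, ch_b),
        "dyad": dyad,
    }


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one one-sided permutation p for an increase."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
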