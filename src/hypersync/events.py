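"""Event-locked analysis of the 1 Hz INS-increase time course.

Epochs run from -10 s (before a response) to +10 s (after it), 21 offsets,
anchored at the onset second of each response; the time course is expected to
be already adjusted for the fNIRS delay-to-peak (see ``ins.ins_timecourse``),
so offsets are in neural time.  Category-mean curves are compared point-wise
against the per-group no-response baseline with paired t-tests (FDR over the
21 offsets), and pre-response offsets are correlated with communication
quality across groups (Sidak-adjusted over the pre-response family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ins import INSTimecourse
from .sessions import EventLog
from .stats import fdr_bh, sidak

WINDOW = (-10, 10)


@dataclass
class EpochStack:
    category: str
    offsets: np.ndarray  # fixed -10..+10
    epochs: np.ndarray  # (n_events, 21)
    dropped: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.epochs.shape[0]


def extract_epochs(tc: INSTimecourse | np.ndarray, log: EventLog,
                   window=WINDOW) -> dict:
    """Per-category epoch stacks from a 1 Hz series and an event log.

    Events whose window would cross either series edge (or run into the NaN
    tail left by the delay adjustment) are dropped and recorded.
    """
    values = tc.values if isinstance(tc, INSTimecourse) else np.asarray(tc, dtype=float)
    lo, hi = int(window[0]), int(window[1])
    offsets = np.arange(lo, hi + 1)
    out = {}
    for cat in ("verbal", "nonverbal"):
        onsets = log.event_times(cat)
        rows, dropped = [], []
        for t in onsets:
            a, b = t + lo, t + hi
            if a < 0 or b >= values.size or np.any(~np.isfinite(values[a:b + 1])):
                dropped.append(int(t))
                continue
            rows.append(values[a:b + 1])
        epochs = np.vstack(rows) if rows else np.empty((0, offsets.size))
        out[cat] = EpochStack(category=cat, offsets=offsets, epochs=epochs,
                              dropped=dropped)
    return out


def category_average(stack: EpochStack) -> np.ndarray:
    """Mean curve over the events of one category (NaN curve when empty)."""
    if stack.n_events == 0:
        return np.full(stack.offsets.size, np.nan)
    return stack.epochs.mean(axis=0)


def baseline_index(tc: INSTimecourse | np.ndarray, log: EventLog) -> float:
    """Mean dz over seconds labeled as no response (someone else talking)."""
    values = tc.values if isinstance(tc, INSTimecourse) else np.asarray(tc, dtype=float)
    sel = (log.labels == "none") & np.isfinite(values)
    if not sel.any():
        raise ValueError("no usable no-response frames")
    return float(values[sel].mean())


def pointwise_tests(curves: np.ndarray, baselines: np.ndarray,
                    q: float = 0.05) -> pd.DataFrame:
    """Paired t at each offset: group curves vs per-group baseline, FDR over offsets."""
    curves = np.asarray(curves, dtype=float)  # (n_groups, 21)
    baselines = np.asarray(baselines, dtype=float)
    valid = np.all(np.isfinite(curves), axis=1) & np.isfinite(baselines)
    curves, baselines = curves[valid], baselines[valid]
    diffs = curves - baselines[:, None]
    t, p = sps.ttest_rel(curves, np.tile(baselines[:, None], curves.shape[1]), axis=0)
    sig = fdr_bh(p, q=q)
    n_off = curves.shape[1]
    offsets = np.arange(WINDOW[0], WINDOW[1] + 1)[:n_off]
    return pd.DataFrame(
        {
            "offset_s": offsets,
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1),
            "mean_diff": diffs.mean(axis=0),
            "n": curves.shape[0],
            "t": t,
            "p": p,
            "significant": sig,
        }
    )


def quality_correlation(curves: np.ndarray, quality: np.ndarray,
                        pre_response_only: bool = True,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r between group quality scores and the curve at each offset.

    The adjustment family is the set of offsets tested: by default the
    pre-response offsets (-10..-1) only.
    """
    curves = np.asarray(curves, dtype=float)
    quality = np.asarray(quality, dtype=float)
    offsets = np.arange(WINDOW[0], WINDOW[1] + 1)
    if pre_response_only:
        sel = offsets < 0
    else:
        sel = np.ones_like(offsets, dtype=bool)
    offs = offsets[sel]
    cols = curves[:, sel]
    r = np.empty(offs.size)
    p = np.empty(offs.size)
    for i in range(offs.size):
        valid = np.isfinite(cols[:, i]) & np.isfinite(quality)
        r[i], p[i] = sps.pearsonr(cols[valid, i], quality[valid])
    p_adj = sidak(p, m=offs.size)
    return pd.DataFrame(
        {
            "offset_s": offs,
            "r": r,
            "p": p,
            "p_sidak": p_adj,
            "significant": p_adj < alpha,
        }
    )
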