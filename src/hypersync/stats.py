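"""Group-level inference on INS-increase matrices.

All tests are two-tailed.  The repeated-measures machinery exploits that in a
fully within-group 2 x 2 x 2 design every 1-df effect is a within-group
contrast, so its F equals the squared paired t on the per-group contrast
scores, with df = (1, n_groups - 1).  Multiple testing across the 121 channel
combinations of one map uses Benjamini-Hochberg FDR (per map); families of
correlations use the Sidak adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    statistic: float
    df: tuple
    p: float
    effect: str = ""
    kind: str = "t"
    extra: dict = field(default_factory=dict)


# --- repeated-measures ANOVA ----------------------------------------------

_EFFECTS = ("condition", "task", "dyad", "condition:task", "condition:dyad",
            "task:dyad", "condition:task:dyad")


def rm_anova_2x2x2(cells: np.ndarray) -> dict:
    """Three-way fully repeated-measures ANOVA with 2-level factors.

    ``cells`` has shape (n_groups, 2, 2, 2) ordered (condition, task, dyad).
    Each effect is tested as the paired contrast with +-1 weights;
    F = (mean / SE)^2 with df (1, n-1).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 4 or cells.shape[1:] != (2, 2, 2):
        raise ValueError("cells must have shape (n_groups, 2, 2, 2)")
    if np.any(~np.isfinite(cells)):
        raise ValueError("design is incomplete: non-finite cell values")
    n = cells.shape[0]
    codes = np.array([-1.0, 1.0])
    out = {}
    for name in _EFFECTS:
        parts = name.split(":")
        w = np.ones((2, 2, 2))
        for axis, fac in enumerate(("condition", "task", "dyad")):
            if fac in parts:
                shape = [1, 1, 1]
                shape[axis] = 2
                w = w * codes.reshape(shape)
        scores = (cells * w[None]).sum(axis=(1, 2, 3)) / w.size
        m = scores.mean()
        se = scores.std(ddof=1) / np.sqrt(n)
        if se == 0:
            F, p = 0.0, 1.0
        else:
            F = (m / se) ** 2
            p = float(sps.f.sf(F, 1, n - 1))
        out[name] = StatResult(statistic=float(F), df=(1, n - 1), p=p,
                               effect=name, kind="F",
                               extra={"contrast_mean": float(m)})
    return out


# --- t maps over channel combinations --------------------------------------


@dataclass
class TestMap:
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    df: int
    mode: str
    q: float


def t_map(a: np.ndarray, b=None, mode: str = "paired", popmean: float = 0.0,
          q: float = 0.05) -> TestMap:
    """Per-channel-pair t-test over groups with BH-FDR across the map.

    ``a`` (and ``b``) have shape (n_groups, n_ch, n_ch).  Modes: one_sample
    (vs ``popmean``), paired, two_sample.
    """
    a = np.asarray(a, dtype=float)
    if mode == "one_sample":
        t, p = sps.ttest_1samp(a, popmean, axis=0)
        df = a.shape[0] - 1
    elif mode == "paired":
        t, p = sps.ttest_rel(a, np.asarray(b, dtype=float), axis=0)
        df = a.shape[0] - 1
    elif mode == "two_sample":
        b = np.asarray(b, dtype=float)
        t, p = sps.ttest_ind(a, b, axis=0)
        df = a.shape[0] + b.shape[0] - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    sig = fdr_bh(p.ravel(), q=q).reshape(p.shape)
    return TestMap(t=t, p=p, significant=sig, df=df, mode=mode, q=q)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over one family."""
    p = np.asarray(p_values, dtype=float).ravel()
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def sidak(p_values, m: int | None = None) -> np.ndarray:
    """Sidak-adjusted p-values: 1 - (1 - p)^m for family size m."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return 1.0 - (1.0 - p) ** m


def pearson_r(x, y) -> StatResult:
    """Pearson correlation with its two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = sps.pearsonr(x, y)
    return StatResult(statistic=float(r), df=(x.size - 2,), p=float(p), kind="r")


def ancova_paired(a: np.ndarray, b: np.ndarray,
                  covariates: np.ndarray | None = None) -> StatResult:
    """Paired contrast adjusted for group-level covariates.

    Regresses the per-group difference d = a - b on mean-centered covariates
    and tests the intercept; F(1, n - 1 - k).  With no covariates this is
    exactly the squared paired t.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        X = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        C = C - C.mean(axis=0, keepdims=True)
        X = np.column_stack([np.ones(n), C])
        k = C.shape[1]
    import statsmodels.api as sm

    fit = sm.OLS(d, X).fit()
    t0 = fit.tvalues[0]
    F = float(t0**2)
    df = (1, n - 1 - k)
    p = float(sps.f.sf(F, *df))
    return StatResult(statistic=F, df=df, p=p, kind="F",
                      extra={"adjusted_mean": float(fit.params[0])})
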