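"""Fisher linear discriminant analysis of LA vs LU dyads with LOOCV.

Features are the 121 channel-combination dz values of each dyad; with
p = 121 features and ~42 dyads the pooled covariance is singular, so the
discriminant is regularized toward its diagonal:

    Sigma_lambda = (1 - lambda) * Sigma_pooled + lambda * diag(Sigma_pooled)
    w = Sigma_lambda^-1 (mu_LA - mu_LU),  threshold at the projected midpoint.

``lambda = 0`` is classical FLDA (pseudo-inverse fallback when singular);
``lambda = 1`` is the diagonal (independent-feature) discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FLDAModel:
    w: np.ndarray
    threshold: float
    classes: tuple  # (negative, positive)
    mu_neg: np.ndarray
    mu_pos: np.ndarray
    pooled_sd: np.ndarray
    shrinkage: float
    used_pinv: bool = False


def _class_split(X, y):
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) != 2:
        raise ValueError("FLDA needs exactly two classes")
    y = np.asarray([str(v) for v in y])
    Xn = X[y == classes[0]]
    Xp = X[y == classes[1]]
    if len(Xn) < 2 or len(Xp) < 2:
        raise ValueError("need >= 2 samples per class")
    return classes, Xn, Xp


def flda_fit(X: np.ndarray, y, shrinkage: float = 0.5) -> FLDAModel:
    """Fit the shrinkage discriminant; the second class (sorted) projects higher."""
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    classes, Xn, Xp = _class_split(X, y)
    mu_n, mu_p = Xn.mean(axis=0), Xp.mean(axis=0)
    Sn = np.cov(Xn, rowvar=False, ddof=1)
    Sp = np.cov(Xp, rowvar=False, ddof=1)
    n0, n1 = len(Xn), len(Xp)
    S = ((n0 - 1) * Sn + (n1 - 1) * Sp) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    Slam = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    diff = mu_p - mu_n
    used_pinv = False
    try:
        w = np.linalg.solve(Slam, diff)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(Slam) @ diff
        used_pinv = True
    threshold = float(w @ (mu_n + mu_p) / 2.0)
    return FLDAModel(w=w, threshold=threshold, classes=classes, mu_neg=mu_n,
                     mu_pos=mu_p, pooled_sd=np.sqrt(np.maximum(np.diag(S), 0.0)),
                     shrinkage=shrinkage, used_pinv=used_pinv)


def flda_predict(model: FLDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    proj = X @ model.w
    return np.where(proj > model.threshold, model.classes[1], model.classes[0])


def accuracy_by_class(y_true, y_pred) -> dict:
    y_true = np.asarray([str(v) for v in y_true])
    y_pred = np.asarray(y_pred)
    out = {"total": float(np.mean(y_true == y_pred))}
    for c in sorted(set(y_true)):
        sel = y_true == c
        out[c] = float(np.mean(y_pred[sel] == c))
    return out


def loocv(X: np.ndarray, y, shrinkage: float = 0.5,
          groups=None) -> dict:
    """Leave-one-out (or leave-one-group-out) cross-validated accuracy.

    ``groups`` optionally names a provenance unit per row; rows sharing a unit
    are held out together (both dyads of one participant group).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    n = len(y)
    units = np.arange(n) if groups is None else np.asarray(groups)
    preds = np.empty(n, dtype=object)
    for u in np.unique(units):
        test = units == u
        model = flda_fit(X[~test], y[~test], shrinkage=shrinkage)
        preds[test] = flda_predict(model, X[test])
    res = accuracy_by_class(y, preds)
    res["predictions"] = preds
    return res


def feature_contributions(model: FLDAModel) -> np.ndarray:
    """Feature indices ranked by |standardized weight| (descending)."""
    std_w = np.abs(model.w) * model.pooled_sd
    return np.argsort(-std_w, kind="stable")


def cross_task_transfer(model: FLDAModel, X_other: np.ndarray, y_other) -> dict:
    """Apply a fitted discriminant to another task's features, no refit."""
    preds = flda_predict(model, X_other)
    return accuracy_by_class(y_other, preds)
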