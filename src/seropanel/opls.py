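"""OPLS-DA by NIPALS with VIP scoring.

Orthogonal projections to latent structures discriminant analysis splits the
predictive variation (correlated with the class contrast) from structured
variation orthogonal to it, then scores each variable by its importance in
the projection (VIP).  With a single response and a single predictive
component the classical VIP sum collapses to

    VIP_j = sqrt(p) * |w_j|,

where ``w`` is the unit-norm predictive weight vector and ``p`` the number
of retained variables, so mean squared VIP is exactly 1 and VIP > 1 marks
above-average contributors.  The pipeline uses VIP > 1 to pre-select
candidate terms for the logistic panel.

Columns are mean-centered and unit-variance scaled before fitting
(autoscaling, the standard chemometrics choice for mixed-magnitude omics
blocks); the class vector is coded +/-1 and centered.  The algorithm is
deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .products import ExpandedFeatureTable

__all__ = ["OplsModel", "fit_oplsda", "vip_scores", "select_by_vip"]


@dataclasses.dataclass
class OplsModel:
    feature_names: list[str]  # retained (non-constant) columns
    w: np.ndarray             # predictive weights, unit norm
    t: np.ndarray             # predictive scores
    p_load: np.ndarray        # predictive loadings
    w_orth: np.ndarray        # (n_orth, p)
    t_orth: np.ndarray        # (n, n_orth)
    p_orth: np.ndarray        # (n_orth, p)
    n_orth: int
    column_means: np.ndarray
    column_scales: np.ndarray
    vip: np.ndarray
    r2x: float
    r2y: float
    dropped_constant: list[str]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ExpandedFeatureTable):
        return X.values, list(X.column_names)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_oplsda(X, y, n_orth: int = 1) -> OplsModel:
    """Fit OPLS-DA with ``n_orth`` orthogonal components (NIPALS).

    ``y`` is a binary label vector (0/1 or +/-1).  Requires at least two
    samples per class and two non-constant features.  Constant columns are
    dropped with a warning before autoscaling.
    """
    X, names = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_oplsda requires exactly two classes in y")
    if min((y == classes[0]).sum(), (y == classes[1]).sum()) < 2:
        raise ValueError("fit_oplsda requires >= 2 samples per class")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant column(s)")
    names = [n for n, k in zip(names, keep) if k]
    if len(names) < 2:
        raise ValueError("need >= 2 non-constant features")
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    yc = np.where(y == classes.max(), 1.0, -1.0)
    yc = yc - yc.mean()

    n, p = Xs.shape
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    rank_bound = min(n - 1, p)
    if n_orth >= rank_bound:
        raise ValueError(f"n_orth={n_orth} >= effective rank bound {rank_bound}")

    ssx_total = float((Xs**2).sum())
    ssy_total = float((yc**2).sum())

    Xf = Xs
    w_orth_list, t_orth_list, p_orth_list = [], [], []
    for _ in range(n_orth):
        w = Xf.T @ yc
        w /= np.linalg.norm(w)
        t = Xf @ w
        p_load = Xf.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:  # no orthogonal variation left
            break
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        w_orth_list.append(w_o)
        t_orth_list.append(t_o)
        p_orth_list.append(p_o)

    # final predictive component on the orthogonal-filtered matrix
    w = Xf.T @ yc
    w /= np.linalg.norm(w)
    t = Xf @ w
    p_load = Xf.T @ t / (t @ t)

    vip = np.sqrt(p) * np.abs(w)

    resid = Xf - np.outer(t, p_load)
    r2x = 1.0 - float((resid**2).sum()) / ssx_total
    b = (t @ yc) / (t @ t)
    r2y = 1.0 - float(((yc - b * t) ** 2).sum()) / ssy_total

    k = len(w_orth_list)
    return OplsModel(
        feature_names=names,
        w=w,
        t=t,
        p_load=p_load,
        w_orth=np.array(w_orth_list).reshape(k, p),
        t_orth=np.array(t_orth_list).T.reshape(n, k) if k else np.zeros((n, 0)),
        p_orth=np.array(p_orth_list).reshape(k, p),
        n_orth=k,
        column_means=mu[keep],
        column_scales=sd[keep],
        vip=vip,
        r2x=min(max(r2x, 0.0), 1.0),
        r2y=min(max(r2y, 0.0), 1.0),
        dropped_constant=dropped,
    )


def vip_scores(m: OplsModel) -> np.ndarray:
    """Per-feature VIP on the predictive component: sqrt(p) * |w_j|."""
    return m.vip.copy()


def select_by_vip(m: OplsModel, threshold: float = 1.0) -> list[str]:
    """Features with VIP strictly above ``threshold``, descending VIP.

    Ties are broken stably by base-table column order.
    """
    order = np.argsort(-m.vip, kind="stable")
    return [m.feature_names[j] for j in order if m.vip[j] > threshold]
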