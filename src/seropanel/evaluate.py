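"""Leave-one-out cross-validation, ROC construction, and threshold choice.

The panel's term set is selected once; LOOCV then refits the coefficients on
every n-1 subset and predicts the held-out sample, giving one out-of-fold
probability per sample.  The ROC is built on the pooled out-of-fold
probabilities with the decision rule "predict metastatic iff prob >=
threshold"; the operating threshold maximizes sensitivity + specificity
(Youden), taking the smallest threshold on ties.  AUC is the trapezoidal
area, identical to the Mann-Whitney U statistic scaled by n1*n0.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .logistic import fit_logistic
from .products import ExpandedFeatureTable

__all__ = [
    "EvaluationResult",
    "loocv_probabilities",
    "roc_curve",
    "auc",
    "optimal_threshold",
    "evaluate_panel",
]


@dataclasses.dataclass
class EvaluationResult:
    oof_probs: np.ndarray
    roc: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    threshold_star: float
    sensitivity: float
    specificity: float
    accuracy: float
    in_sample_probs: np.ndarray | None = None
    in_sample_accuracy: float | None = None

    def metrics_frame(self) -> pd.DataFrame:
        row = {
            "auc": self.auc,
            "threshold": self.threshold_star,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        if self.in_sample_accuracy is not None:
            row["in_sample_accuracy"] = self.in_sample_accuracy
        return pd.DataFrame([row])


def loocv_probabilities(
    terms: list[str], table: ExpandedFeatureTable, y: np.ndarray
) -> np.ndarray:
    """Out-of-fold probability per sample for a fixed term set."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("LOOCV requires n >= 10")
    X = table.design_matrix(terms)
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i}: single-class training labels")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(X[mask], y_tr, term_names=terms)
        if not fit.converged:
            warnings.warn(f"fold {i}: non-convergent refit; using last iterate")
        probs[i] = float(fit.predict_proba(X[i : i + 1])[0])
    return probs


def nested_loocv_probabilities(
    table: ExpandedFeatureTable, y: np.ndarray, selector
) -> np.ndarray:
    """Fully nested LOOCV: re-run term selection inside every fold.

    ``selector(sub_table, y_sub) -> list of term names`` is the whole
    selection stage (e.g. OPLS-DA VIP + constrained stepwise) applied to the
    n-1 training samples; an empty selection predicts the training class
    rate.  Fixed-set LOOCV (``loocv_probabilities``) is optimistically
    biased whenever selection saw the held-out sample; this variant is the
    honest null-calibrated alternative, at the cost of refitting the
    selection per fold.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("LOOCV requires n >= 10")
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i}: single-class training labels")
        sub = table.subset_samples(mask)
        terms = selector(sub, y_tr)
        if not terms:
            # a non-informative 0.5, not the training rate: with leave-one-out
            # the training prevalence always tilts against the held-out class,
            # and the rate would encode that artifact as anti-signal
            probs[i] = 0.5
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(sub.design_matrix(terms), y_tr, term_names=terms)
        X_i = table.design_matrix(terms)[i : i + 1]
        probs[i] = float(fit.predict_proba(X_i)[0])
    return probs


def roc_curve(probs: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """ROC points over thresholds = unique probabilities plus sentinels.

    Positive class is y == 1 (metastatic); a sample is called positive when
    its probability is >= the threshold, so the sub-minimum sentinel yields
    (Se, Sp) = (1, 0) and the supra-maximum sentinel (0, 1).
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("roc_curve requires both classes")
    uniq = np.unique(probs)
    eps = 1e-9
    thresholds = np.concatenate([[uniq[0] - eps], uniq, [uniq[-1] + eps]])
    n1 = float((y == 1).sum())
    n0 = float((y == 0).sum())
    rows = []
    for thr in thresholds:
        pred = probs >= thr
        tp = float(np.sum(pred & (y == 1)))
        tn = float(np.sum(~pred & (y == 0)))
        rows.append((float(thr), tp / n1, tn / n0))
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def auc(probs: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal area under the ROC; ties contribute 1/2.

    Equals the two-sample U statistic over n1*n0 exactly.
    """
    roc = roc_curve(probs, y)
    fpr = 1.0 - roc["specificity"].to_numpy()
    tpr = roc["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))  # vertical segments traversed upward
    return float(np.trapezoid(tpr[order], fpr[order]))


def optimal_threshold(roc: pd.DataFrame) -> tuple[float, float, float]:
    """(threshold, Se, Sp) maximizing Se+Sp over the evaluated grid.

    Ties take the smallest threshold (deterministic).
    """
    if len(roc) == 0:
        raise ValueError("empty ROC")
    j = (roc["sensitivity"] + roc["specificity"]).to_numpy()
    thr = roc["threshold"].to_numpy()
    best = int(np.lexsort((thr, -j))[0])
    return (
        float(thr[best]),
        float(roc["sensitivity"].iloc[best]),
        float(roc["specificity"].iloc[best]),
    )


def evaluate_panel(
    terms: list[str], table: ExpandedFeatureTable, y: np.ndarray
) -> EvaluationResult:
    """LOOCV -> ROC -> AUC -> Youden threshold, with accuracy at threshold.

    Also reports in-sample (refit-on-all) accuracy at the same style of
    threshold, labelled separately, since resubstitution and out-of-fold
    figures answer different questions.
    """
    y = np.asarray(y, dtype=float).ravel()
    probs = loocv_probabilities(terms, table, y)
    roc = roc_curve(probs, y)
    _check_roc_monotone(roc)
    area = auc(probs, y)
    thr, se, sp = optimal_threshold(roc)
    acc = float(np.mean((probs >= thr) == (y == 1)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_fit = fit_logistic(table.design_matrix(terms), y, term_names=terms)
    ins = full_fit.predict_proba(table.design_matrix(terms))
    ins_roc = roc_curve(ins, y)
    ins_thr, _, _ = optimal_threshold(ins_roc)
    ins_acc = float(np.mean((ins >= ins_thr) == (y == 1)))

    return EvaluationResult(
        oof_probs=probs,
        roc=roc,
        auc=area,
        threshold_star=thr,
        sensitivity=se,
        specificity=sp,
        accuracy=acc,
        in_sample_probs=ins,
        in_sample_accuracy=ins_acc,
    )


def _check_roc_monotone(roc: pd.DataFrame) -> None:
    se = roc["sensitivity"].to_numpy()
    sp = roc["specificity"].to_numpy()
    if np.any(np.diff(se) > 1e-12) or np.any(np.diff(sp) < -1e-12):
        raise AssertionError("ROC monotonicity violated")
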