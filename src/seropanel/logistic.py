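"""Maximum-likelihood logistic regression and constrained stepwise panels.

The panel-building procedure couples forward AIC minimization with a Wald
significance constraint: starting from the intercept-only model, candidate
terms are added one at a time, keeping only additions for which every
non-intercept coefficient stays significant (two-sided Wald p < alpha) and
choosing the admissible addition with the lowest AIC, until no admissible
addition lowers AIC.  A backward phase then removes, one at a time, the term
with the largest Wald p until all non-intercept p < alpha.  The final model
therefore satisfies the zero-probability constraint by construction.

Fitting is iteratively reweighted least squares on internally standardized
columns (an exact reparametrization, required for conditioning when design
columns are raw-scale abundance products spanning many orders of magnitude);
reported coefficients, standard errors and covariances are transformed back
to the raw measurement scale.  Confidence intervals default to profile
likelihood (deviance increase of the chi-square(1) quantile), with Wald
intervals as fallback.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .products import ExpandedFeatureTable

__all__ = [
    "LogisticFit",
    "SelectionTrace",
    "fit_logistic",
    "profile_ci",
    "stepwise_select",
    "report_model",
]

MAX_ITER = 100
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
SEPARATION_BOUND = 15.0  # |beta| on the standardized scale
CHI2_1_95 = float(stats.chi2.ppf(0.95, 1))  # 3.841...


@dataclasses.dataclass
class LogisticFit:
    term_names: list[str]  # ["Intercept", ...]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    aic: float
    converged: bool
    separation_flag: bool
    cov: np.ndarray
    ci_method: str = "wald"
    # retained for profile CIs and prediction
    _X: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _y: np.ndarray | None = dataclasses.field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.beta)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for raw-scale design rows."""
        X = np.asarray(X, dtype=float)
        eta = self.beta[0] + X @ self.beta[1:]
        return _sigmoid(eta)


@dataclasses.dataclass
class SelectionTrace:
    steps: list[dict]  # {action, term, aic_before, aic_after, worst_p}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log p = -log(1+exp(-eta)) for y=1; log(1-p) = -log(1+exp(eta)) for y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta))))


def _irls(
    Z: np.ndarray, y: np.ndarray, offset: np.ndarray | float = 0.0
) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    """IRLS on a (already well-conditioned) design with intercept column.

    Returns (beta, cov, loglik, converged, separated).
    """
    n, k = Z.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    separated = False
    improving = True
    cov = np.full((k, k), np.nan)
    for _ in range(MAX_ITER):
        eta = Z @ beta + offset
        mu = _sigmoid(eta)
        score = Z.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (Z * w[:, None]).T @ Z
        ll = _loglik(y, eta)
        improving = ll > ll_old
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        if ll_old > -np.inf and abs(ll - ll_old) <= LOGLIK_RTOL * (abs(ll_old) + 1e-30):
            converged = True
            break
        ll_old = ll
        # damped Newton: halve the step until the likelihood does not decrease
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(k), score)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            if _loglik(y, Z @ cand + offset) >= ll - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
    eta = Z @ beta + offset
    ll = _loglik(y, eta)
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    H = (Z * w[:, None]).T @ Z
    # separation: either diverging estimates with still-improving likelihood,
    # or numerically perfect prediction (score -> 0 while beta -> inf); a
    # converged score with imperfect prediction is a genuine finite MLE
    if np.max(np.abs(beta)) > SEPARATION_BOUND:
        if np.all(np.abs(y - mu) < 1e-6) or (not converged and improving):
            separated = True
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return beta, cov, ll, converged, separated


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    term_names: list[str] | None = None,
    ci: str = "wald",
) -> LogisticFit:
    """Fit logistic regression of binary ``y`` on raw-scale columns ``X``.

    An intercept is always included (and exempt from downstream
    significance constraints).  ``ci`` selects "wald" or "profile"
    95% intervals.  Raises on single-class labels and on rank-deficient
    designs (naming the collinear terms).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("y has a single class")
    n, m = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(m)]
    if len(term_names) != m:
        raise ValueError("term_names length mismatch")
    if n <= m + 1:
        raise ValueError(f"n={n} too small for {m} terms plus intercept")

    mu_x = X.mean(axis=0)
    s_x = X.std(axis=0, ddof=0)
    zero_var = s_x == 0
    if zero_var.any():
        bad = [term_names[j] for j in np.flatnonzero(zero_var)]
        raise ValueError(f"constant design columns: {bad}")
    Zc = (X - mu_x) / s_x
    Z = np.column_stack([np.ones(n), Zc])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        bad = _collinear_terms(Zc, term_names)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")

    beta_s, cov_s, ll, converged, separated = _irls(Z, y)
    if separated:
        warnings.warn("possible complete separation; estimates diverge")

    # back-transform to raw scale: beta_raw = A @ beta_std
    A = np.zeros((m + 1, m + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -mu_x / s_x
    A[1:, 1:] = np.diag(1.0 / s_x)
    beta = A @ beta_s
    cov = A @ cov_s @ A.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    fit = LogisticFit(
        term_names=["Intercept"] + list(term_names),
        beta=beta,
        se=se,
        z=z,
        p=p,
        ci_low=beta - zc * se,
        ci_high=beta + zc * se,
        loglik=ll,
        aic=2.0 * (m + 1) - 2.0 * ll,
        converged=converged,
        separation_flag=separated,
        cov=cov,
        _X=X,
        _y=y,
    )
    if ci == "profile":
        profile_ci(fit)
    return fit


def _collinear_terms(Zc: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(Zc)
    diag = np.abs(np.diag(r))
    tol = max(Zc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in range(len(names)) if j < len(diag) and diag[j] <= tol]


def profile_ci(fit: LogisticFit, level: float = 0.95) -> LogisticFit:
    """Replace Wald CIs with profile-likelihood intervals (in place).

    Each bound solves: profile deviance (coefficient fixed, others refit)
    exceeds the minimum deviance by the chi-square(1) quantile.  When the
    profile deviance never reaches the cutoff on one side (flat likelihood
    under separation), that bound is left one-sided at +/-inf.
    """
    if fit._X is None or fit._y is None:
        raise ValueError("fit lacks retained data; refit with fit_logistic")
    if fit.separation_flag:
        warnings.warn("profile CI on a separated fit; bounds may be one-sided")
    X, y = fit._X, fit._y
    n, m = X.shape
    mu_x = X.mean(axis=0)
    s_x = X.std(axis=0, ddof=0)
    Z_full = np.column_stack([np.ones(n), (X - mu_x) / s_x])
    cutoff = float(stats.chi2.ppf(level, 1))
    dev_min = -2.0 * fit.loglik

    # fixing the standardized coefficient b_j_std = c is the same constraint
    # as fixing the raw coefficient at c/s_j (the other parameters freely
    # reparametrize), so slope bounds profile on the standardized scale and
    # divide by s_j afterwards; the intercept is profiled on the raw scale
    # directly (offset on the ones column, slopes on uncentered scaled X).
    beta_std = fit.beta[1:] * s_x
    se_std = fit.se[1:] * s_x

    lo = np.empty(m + 1)
    hi = np.empty(m + 1)
    U = X / s_x  # uncentered, scaled: free slopes with the raw intercept fixed

    def excess_intercept(c: float) -> float:
        _, _, ll, _, _ = _irls(U, y, offset=c)
        return (-2.0 * ll) - dev_min - cutoff

    lo[0] = _profile_bound(excess_intercept, fit.beta[0], fit.se[0], direction=-1)
    hi[0] = _profile_bound(excess_intercept, fit.beta[0], fit.se[0], direction=+1)

    for j in range(1, m + 1):
        others = [c for c in range(m + 1) if c != j]
        Zo = Z_full[:, others]
        xj = Z_full[:, j]

        def excess(c: float) -> float:
            _, _, ll, _, _ = _irls(Zo, y, offset=c * xj)
            return (-2.0 * ll) - dev_min - cutoff

        lo[j] = _profile_bound(excess, beta_std[j - 1], se_std[j - 1], direction=-1)
        hi[j] = _profile_bound(excess, beta_std[j - 1], se_std[j - 1], direction=+1)

    fit.ci_low = np.empty(m + 1)
    fit.ci_high = np.empty(m + 1)
    fit.ci_low[0], fit.ci_high[0] = lo[0], hi[0]
    fit.ci_low[1:] = lo[1:] / s_x
    fit.ci_high[1:] = hi[1:] / s_x
    fit.ci_method = "profile"
    return fit


def _profile_bound(excess, center: float, se: float, direction: int) -> float:
    """Bracket and solve excess(c)=0 moving from the MLE in ``direction``."""
    if not np.isfinite(se) or se <= 0:
        se = max(abs(center), 1.0)
    step = 1.96 * se
    inner = center
    f_inner = excess(inner)  # negative at the MLE by construction
    if f_inner > 0:  # numerically degenerate profile
        return center
    for _ in range(40):
        outer = inner + direction * step
        f_outer = excess(outer)
        if f_outer > 0:
            return float(
                optimize.brentq(excess, min(inner, outer), max(inner, outer), xtol=1e-8)
            )
        inner, f_inner = outer, f_outer
        step *= 1.6
    warnings.warn("profile deviance did not reach the cutoff; one-sided bound")
    return direction * np.inf


def _batch_candidate_stats(
    Z: np.ndarray, y: np.ndarray, cand_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton fits of (current design + one candidate) for every candidate.

    ``Z`` is the standardized current design including the intercept column,
    ``cand_cols`` an (n, C) block of standardized candidate columns.  Returns
    (aic, worst_p, ok) per candidate, where ok marks converged,
    non-separated, full-rank fits.  Used only to rank candidates inside the
    forward phase; the winning term is refitted through fit_logistic.
    """
    n, k0 = Z.shape
    C = cand_cols.shape[1]
    k = k0 + 1
    # designs: (C, n, k)
    designs = np.empty((C, n, k))
    designs[:, :, :k0] = Z[None, :, :]
    designs[:, :, k0] = cand_cols.T
    beta = np.zeros((C, k))
    eye = 1e-10 * np.eye(k)
    active = np.ones(C, dtype=bool)
    for _ in range(40):
        eta = np.einsum("cnk,ck->cn", designs, beta)
        mu = _sigmoid(eta)
        resid = y[None, :] - mu
        score = np.einsum("cnk,cn->ck", designs, resid)
        if not np.any(np.abs(score[active]).max(axis=1) > SCORE_TOL):
            break
        w = mu * (1.0 - mu)
        H = np.einsum("cnk,cn,cnl->ckl", designs, w, designs) + eye
        try:
            step = np.linalg.solve(H, score[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        # freeze diverged fits rather than chase them
        step = np.clip(step, -4.0, 4.0)
        beta = np.where(active[:, None], beta + step, beta)
        active = active & (np.abs(beta).max(axis=1) <= 2 * SEPARATION_BOUND)
    eta = np.einsum("cnk,ck->cn", designs, beta)
    mu = _sigmoid(eta)
    ll = -np.sum(np.logaddexp(0.0, np.where(y[None, :] == 1, -eta, eta)), axis=1)
    score = np.einsum("cnk,cn->ck", designs, y[None, :] - mu)
    w = mu * (1.0 - mu)
    H = np.einsum("cnk,cn,cnl->ckl", designs, w, designs)
    ok = np.abs(score).max(axis=1) < 1e-6
    ok &= ~np.all(np.abs(y[None, :] - mu) < 1e-6, axis=1)  # perfect prediction
    aic = 2.0 * k - 2.0 * ll
    worst_p = np.full(C, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            cov = np.linalg.inv(H + eye)
        except np.linalg.LinAlgError:
            return aic, worst_p, np.zeros(C, dtype=bool)
        var = np.einsum("ckk->ck", cov)
        ok &= np.all(var > 0, axis=1)
        se = np.sqrt(np.maximum(var, 1e-300))
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    worst_p = np.where(ok, pvals[:, 1:].max(axis=1), np.nan)
    return aic, worst_p, ok


def _admissible(fit: LogisticFit, alpha: float) -> bool:
    if not fit.converged or fit.separation_flag:
        return False
    if fit.k == 1:
        return True
    return bool(np.all(fit.p[1:] < alpha))


def _worst_p(fit: LogisticFit) -> float:
    return float(np.max(fit.p[1:])) if fit.k > 1 else 0.0


def _fit_intercept_only(y: np.ndarray) -> LogisticFit:
    y = np.asarray(y, dtype=float).ravel()
    n1 = float(y.sum())
    n0 = float(y.size - n1)
    if n0 == 0 or n1 == 0:
        raise ValueError("y has a single class")
    b0 = np.log(n1 / n0)
    pbar = n1 / y.size
    ll = n1 * np.log(pbar) + n0 * np.log(1 - pbar)
    se = np.sqrt(1.0 / (y.size * pbar * (1 - pbar)))
    z = b0 / se
    zc = stats.norm.ppf(0.975)
    return LogisticFit(
        term_names=["Intercept"],
        beta=np.array([b0]),
        se=np.array([se]),
        z=np.array([z]),
        p=np.array([2 * stats.norm.sf(abs(z))]),
        ci_low=np.array([b0 - zc * se]),
        ci_high=np.array([b0 + zc * se]),
        loglik=ll,
        aic=2.0 - 2.0 * ll,
        converged=True,
        separation_flag=False,
        cov=np.array([[se**2]]),
        _X=np.empty((y.size, 0)),
        _y=y,
    )


def stepwise_select(
    table: ExpandedFeatureTable,
    candidates: list[str],
    y: np.ndarray,
    alpha: float = 0.05,
    constraint_phase: str = "forward_and_backward",
    max_terms: int = 12,
) -> tuple[LogisticFit, SelectionTrace]:
    """Constrained stepwise panel building over VIP candidate terms.

    Forward: add the admissible term minimizing AIC while it lowers AIC
    (admissible = converged, non-separated and, under
    ``constraint_phase='forward_and_backward'``, all non-intercept Wald
    p < alpha).  Backward: drop the largest-p term until all non-intercept
    p < alpha.  Ties in forward AIC break by smaller worst-case p, then by
    candidate order.  Returns the final fit and the full trace.
    """
    if constraint_phase not in ("forward_and_backward", "backward_only"):
        raise ValueError(f"unknown constraint_phase {constraint_phase!r}")
    y = np.asarray(y, dtype=float).ravel()
    current: list[str] = []
    fit = _fit_intercept_only(y)
    trace: list[dict] = []
    enforce_forward = constraint_phase == "forward_and_backward"

    # standardized columns once, for the batched forward-step ranking
    n = y.size
    pool = [t for t in candidates if t in set(table.column_names)]
    if len(pool) < len(candidates):
        missing = [t for t in candidates if t not in set(table.column_names)]
        raise KeyError(f"unknown candidate terms: {missing[:5]}")
    pool_X = table.design_matrix(pool)
    mu = pool_X.mean(axis=0)
    sd = pool_X.std(axis=0)
    usable = sd > 0
    pool_Z = np.zeros_like(pool_X)
    pool_Z[:, usable] = (pool_X[:, usable] - mu[usable]) / sd[usable]
    col_of = {t: j for j, t in enumerate(pool)}

    while len(current) < max_terms:
        free = [t for t in pool if t not in current and usable[col_of[t]]]
        if not free:
            break
        Z_cur = np.column_stack(
            [np.ones(n)] + [pool_Z[:, col_of[t]] for t in current]
        )
        cand_block = pool_Z[:, [col_of[t] for t in free]]
        aic, worst_p, ok = _batch_candidate_stats(Z_cur, y, cand_block)
        admissible = ok & (aic < fit.aic - 1e-12)
        if enforce_forward:
            with np.errstate(invalid="ignore"):
                admissible &= worst_p < alpha
        if not admissible.any():
            break
        ranked = sorted(
            np.flatnonzero(admissible), key=lambda c: (aic[c], worst_p[c], c)
        )
        # refit the winner exactly; fall through the ranking if the careful
        # fit disagrees with the batched screen near the admissibility edge
        best = None
        for c in ranked:
            terms_try = current + [free[c]]
            try:
                cand_fit = fit_logistic(
                    table.design_matrix(terms_try), y, term_names=terms_try
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not cand_fit.converged or cand_fit.separation_flag:
                continue
            if enforce_forward and not np.all(cand_fit.p[1:] < alpha):
                continue
            if cand_fit.aic >= fit.aic:
                continue
            best = (free[c], cand_fit)
            break
        if best is None:
            break
        term, new_fit = best
        trace.append(
            {
                "action": "add",
                "term": term,
                "aic_before": fit.aic,
                "aic_after": new_fit.aic,
                "worst_p": _worst_p(new_fit),
            }
        )
        current.append(term)
        fit = new_fit

    if not current:
        warnings.warn("no admissible first addition; returning intercept-only model")
        return fit, SelectionTrace(trace)

    # backward elimination of non-significant terms
    while fit.k > 1 and np.max(fit.p[1:]) >= alpha:
        worst_idx = int(np.argmax(fit.p[1:]))
        term = fit.term_names[1:][worst_idx]
        aic_before = fit.aic
        current = [t for t in current if t != term]
        if current:
            X = table.design_matrix(current)
            fit = fit_logistic(X, y, term_names=current)
        else:
            fit = _fit_intercept_only(y)
        trace.append(
            {
                "action": "remove",
                "term": term,
                "aic_before": aic_before,
                "aic_after": fit.aic,
                "worst_p": _worst_p(fit),
            }
        )
    return fit, SelectionTrace(trace)


def report_model(fit: LogisticFit) -> pd.DataFrame:
    """Model report with the panel-table schema: Variable, beta, CI, Z, p."""
    return pd.DataFrame(
        {
            "Variable": fit.term_names,
            "beta": fit.beta,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "Z": fit.z,
            "p": fit.p,
        }
    )
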