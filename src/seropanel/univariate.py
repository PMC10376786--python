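"""Univariate screening toolbox: rank tests, categorical tests, correlations.

All group comparisons are nonparametric (Mann-Whitney for two groups,
Kruskal-Wallis for more), categorical comparisons use chi-square (Yates
continuity correction on 2x2 by default) or Fisher's exact test, and
monotone association uses Spearman rank correlation.  The marker screen
combines these: a feature is called differential at raw p < alpha and
count-correlated when its Spearman correlation with the lymph-node
metastasis count passes both p < alpha and |rho| > rho_min.

The computational kernels are scipy.stats; this module fixes the pipeline's
conventions (exact vs. normal-approximation switching, tie handling,
continuity corrections, effect sizes) and the screening-report schema.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ClinicalTable, ContingencyTable, FeatureTable

__all__ = [
    "TestResult",
    "CorrelationResult",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square_test",
    "fisher_exact_2x2",
    "spearman",
    "bh_adjust",
    "screen_markers",
]

#: largest pooled sample size for which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 16


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    effect_size: float | None = None


@dataclasses.dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses the exact null when the pooled sample is small
    (n1+n2 <= 16) and tie-free, otherwise the normal approximation with tie
    and continuity corrections.  The effect size is the rank-biserial
    correlation 2U/(n1*n2) - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both groups; p = 1")
        u = x.size * y.size / 2.0
        return TestResult(u, 1.0, "mann-whitney", effect_size=0.0)
    if mode == "auto":
        method = "exact" if (pooled.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    elif mode == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney p is undefined with ties")
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u = float(res.statistic)
    rb = 2.0 * u / (x.size * y.size) - 1.0
    return TestResult(u, float(res.pvalue), f"mann-whitney ({method})", effect_size=rb)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected), p from chi-square with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis: empty group")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", df=len(groups) - 1)
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis", df=len(groups) - 1)


def chi_square_test(t: ContingencyTable, yates: str = "auto") -> TestResult:
    """Pearson chi-square on an r x c contingency table.

    ``yates='auto'`` applies the continuity correction iff the table is 2x2
    (the convention that reproduces the study's printed clinical-table
    p-values); ``'on'``/``'off'`` force it.
    """
    counts = t.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero marginal row/column")
    if yates == "auto":
        correction = counts.shape == (2, 2)
    elif yates in ("on", "off"):
        correction = yates == "on"
    else:
        raise ValueError(f"unknown yates mode {yates!r}")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return TestResult(max(float(chi2), 0.0), float(p), "chi-square", df=int(df))


def fisher_exact_2x2(t: ContingencyTable) -> TestResult:
    """Fisher's exact test, two-sided by the sum-of-smaller-probability rule.

    The statistic is the sample odds ratio ad/bc (inf allowed).
    """
    if t.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 requires a 2x2 table, got {t.shape}")
    a, b = t.counts[0]
    c, d = t.counts[1]
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(t.counts, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation; p from the t-approximation, |rho|=1 => p=0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("spearman requires equal-length vectors")
    n = int(x.size)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(np.nan, np.nan, n, defined=False)
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    return CorrelationResult(float(rho), float(p), n)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_markers(
    ft: FeatureTable,
    ct: ClinicalTable,
    alpha: float = 0.05,
    rho_min: float = 0.3,
    adjust: bool = False,
) -> pd.DataFrame:
    """Univariate marker screen over every feature.

    Per feature: Mann-Whitney p metastatic vs non-metastatic, Kruskal-Wallis
    p across biological subtype and across grade (when those columns exist),
    and Spearman correlation with the metastasis count.  Flags:

    - ``differential``: group-test p < alpha (raw, as the screen is defined)
    - ``count_pos`` / ``count_neg``: Spearman p < alpha and rho beyond
      +/- rho_min

    With ``adjust`` an extra BH-adjusted column ``p_group_bh`` is added.
    """
    ct.check_companion(ft)
    if "group" not in ct.data.columns:
        raise KeyError("clinical table lacks 'group'")
    # align clinical rows to feature-table sample order
    clin = ct.data.loc[ft.sample_ids]
    is_met = (clin["group"] == "metastatic").to_numpy()
    if is_met.all() or not is_met.any():
        raise ValueError("screen requires both metastatic and non-metastatic samples")
    X = ft.values
    n_met = np.asarray(clin["n_metastases"], dtype=float)

    # vectorized Mann-Whitney across feature columns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mw = stats.mannwhitneyu(
            X[is_met], X[~is_met], alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=0,
        )
    p_group = np.asarray(mw.pvalue, dtype=float)
    u_stat = np.asarray(mw.statistic, dtype=float)
    constant = np.array([np.unique(col).size == 1 for col in X.T])
    p_group[constant] = 1.0

    rho = np.full(X.shape[1], np.nan)
    p_rho = np.full(X.shape[1], np.nan)
    if np.unique(n_met).size > 1:
        # vectorized Spearman: Pearson correlation of midranks, t-approx p
        rx = stats.rankdata(X, axis=0)
        ry = stats.rankdata(n_met)
        rx = rx - rx.mean(axis=0)
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, rx.T @ ry / np.where(denom > 0, denom, 1.0), np.nan)
            nn = X.shape[0]
            t = rho * np.sqrt((nn - 2) / np.maximum(1 - rho**2, 1e-300))
            p_rho = 2.0 * stats.t.sf(np.abs(t), nn - 2)
        p_rho = np.where(np.abs(rho) >= 1 - 1e-15, 0.0, p_rho)
        rho = np.where(constant, np.nan, rho)
        p_rho = np.where(constant, np.nan, p_rho)

    report = pd.DataFrame(
        {
            "feature": ft.feature_ids,
            "analyte_class": ft.feature_meta["analyte_class"].to_numpy(),
            "U": u_stat,
            "p_group": p_group,
            "rho_count": rho,
            "p_count": p_rho,
        }
    )
    for col, name in (("subtype", "p_subtype"), ("grade", "p_grade")):
        if col in clin.columns and clin[col].notna().all():
            levels = clin[col].unique()
            if len(levels) >= 2:
                pvals = []
                groups_idx = [np.asarray(clin[col] == lv) for lv in levels]
                for j in range(X.shape[1]):
                    groups = [X[g, j] for g in groups_idx]
                    try:
                        pvals.append(kruskal_wallis(groups).p_value)
                    except ValueError:
                        pvals.append(np.nan)
                report[name] = pvals
    report["differential"] = report["p_group"] < alpha
    report["count_pos"] = (report["p_count"] < alpha) & (report["rho_count"] > rho_min)
    report["count_neg"] = (report["p_count"] < alpha) & (report["rho_count"] < -rho_min)
    if adjust:
        report["p_group_bh"] = bh_adjust(report["p_group"].to_numpy())
    return report
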