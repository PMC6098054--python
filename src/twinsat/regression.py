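"""Pair-robust multiple regression, multiple-testing control, facet selection.

The regression stage mirrors a GEE-with-independence-working-correlation
analysis of clustered twin data: point estimates are ordinary least squares
on z-scored variables (so coefficients are standardized betas) and standard
errors are cluster-robust sandwich estimates over twin pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}


def adjust_pvalues(pvals, method):
    """Adjust p-values for multiple testing.

    ``method`` is ``"bonferroni"`` (min(1, m*p)) or ``"bh_fdr"``
    (Benjamini-Hochberg step-up with monotonicity enforcement).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(pvals, method=ADJUST_METHODS[method])[1]


@dataclass
class RegressionResult:
    """Standardized betas with pair-robust inference.

    ``table`` is indexed by predictor with columns ``beta, se, p,
    p_bonferroni, p_fdr``; covariates (if any) are reported separately in
    ``covariate_table`` and excluded from the multiplicity adjustment.
    """

    table: pd.DataFrame
    r2: float
    r2_adj: float
    nobs: int
    n_clusters: int
    outcome: str = ""
    covariate_table: pd.DataFrame = None

    def summary(self):
        lines = [f"Pair-robust regression of {self.outcome}",
                 f"n = {self.nobs} individuals in {self.n_clusters} pairs",
                 f"R2 = {self.r2:.4f}   adjusted R2 = {self.r2_adj:.4f}", ""]
        lines.append(self.table.to_string(float_format=lambda x: f"{x: .4f}"))
        return "\n".join(lines)


def _zscore(x):
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def _collinear_columns(X, names, tol=1e-8):
    q, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    bad = d < tol * d.max()
    return [names[i] for i in np.nonzero(bad)[0]]


def pair_robust_regression(data, outcome, predictors, cluster="pair_id",
                           covariates=()):
    """OLS on z-scored variables with pair-clustered sandwich SEs.

    ``data`` is a long table (one row per twin) containing the outcome,
    predictors, optional covariates and the cluster (pair) identifier.  Rows
    with any missing value among the modelled columns are dropped; clusters
    whose outcome is entirely missing therefore vanish.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    predictors = list(predictors)
    covariates = list(covariates)
    cols = [outcome] + predictors + covariates + [cluster]
    sub = data[cols].dropna().reset_index(drop=True)
    if len(sub) < len(predictors) + len(covariates) + 2:
        raise ValueError("too few complete observations for the requested model")
    y = _zscore(sub[outcome].to_numpy(dtype=float))
    Xcols = predictors + covariates
    X = np.column_stack([_zscore(sub[c].to_numpy(dtype=float)) for c in Xcols])
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = _collinear_columns(Xc, ["const"] + Xcols)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    groups = sub[cluster].to_numpy()
    fit = sm.OLS(y, Xc).fit(cov_type="cluster", cov_kwds={"groups": groups})
    k = len(predictors)
    beta = fit.params[1:1 + k]
    se = fit.bse[1:1 + k]
    p = fit.pvalues[1:1 + k]
    table = pd.DataFrame({
        "beta": beta, "se": se, "p": p,
        "p_bonferroni": adjust_pvalues(p, "bonferroni"),
        "p_fdr": adjust_pvalues(p, "bh_fdr"),
    }, index=predictors)
    cov_table = None
    if covariates:
        cov_table = pd.DataFrame({
            "beta": fit.params[1 + k:], "se": fit.bse[1 + k:],
            "p": fit.pvalues[1 + k:]}, index=covariates)
    return RegressionResult(
        table=table, r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj),
        nobs=int(fit.nobs), n_clusters=int(len(np.unique(groups))),
        outcome=outcome, covariate_table=cov_table)


def select_facets(result, beta_threshold=0.10, p_threshold=0.01,
                  p_column="p_fdr"):
    """Facets with ``|beta| > beta_threshold`` and ``p < p_threshold``.

    ``result`` is a :class:`RegressionResult` or its table.  ``p_column``
    chooses which p-value the rule is applied to (raw ``"p"``,
    ``"p_bonferroni"`` or ``"p_fdr"``).  Returns the retained facet names
    ordered by descending ``|beta|``; an empty selection is allowed.
    """
    table = result.table if hasattr(result, "table") else result
    keep = table[(table["beta"].abs() > beta_threshold)
                 & (table[p_column] < p_threshold)]
    keep = keep.reindex(keep["beta"].abs().sort_values(ascending=False).index)
    return list(keep.index)


def selection_report(result, beta_threshold=0.10, p_threshold=0.01):
    """Selection decisions under raw, Bonferroni and FDR p-values."""
    table = result.table if hasattr(result, "table") else result
    rep = table.copy()
    for col, label in (("p", "raw"), ("p_bonferroni", "bonferroni"),
                       ("p_fdr", "fdr")):
        rep[f"selected_{label}"] = ((rep["beta"].abs() > beta_threshold)
                                    & (rep[col] < p_threshold))
    return rep
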