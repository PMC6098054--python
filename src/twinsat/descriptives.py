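"""Phenotypic and twin-cotwin correlations, and the Falconer moment estimator.

Twin-cotwin correlations are computed on double-entered pairs: every complete
pair contributes both (twin1, twin2) and (twin2, twin1), which makes the
estimate invariant to the arbitrary labelling of twins within a pair.
P-values for double-entered correlations use the number of *pairs* as the
effective sample size.  Phenotypic correlations pool all responding
individuals (including single responders) and report pair-clustered robust
p-values, since twins within a pair are not independent observations.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import to_long

GROUP_KEYS = (("MZ", None), ("DZ", None), ("MZ", "M"), ("DZ", "M"),
              ("MZ", "F"), ("DZ", "F"))


def double_entry_correlation(x1, x2):
    """Double-entered Pearson correlation of co-twin scores.

    Returns ``(r, n_pairs, p)``; ``r`` and ``p`` are NaN with fewer than
    three complete pairs.  The p-value is a two-sided t-test with
    ``n_pairs - 2`` degrees of freedom.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    ok = ~(np.isnan(x1) | np.isnan(x2))
    n = int(ok.sum())
    if n < 3:
        return np.nan, n, np.nan
    a = np.concatenate([x1[ok], x2[ok]])
    b = np.concatenate([x2[ok], x1[ok]])
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan, n, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, n, float(p)


def twin_cotwin_correlations(pairs, variables):
    """Per-variable MZ/DZ co-twin correlations, overall and by sex.

    Returns a DataFrame indexed by variable with columns ``rMZ, nMZ, pMZ,
    rDZ, ..., rMZ_M, ..., rDZ_F`` mirroring a zygosity-by-sex correlation
    table.  Groups with fewer than three complete pairs yield NaN entries.
    """
    rows = {}
    for v in variables:
        row = {}
        for zyg, sex in GROUP_KEYS:
            sel = pairs["zygosity"] == zyg
            if sex is not None:
                sel &= pairs["sex"] == sex
            label = f"{zyg}" if sex is None else f"{zyg}_{sex}"
            r, n, p = double_entry_correlation(pairs.loc[sel, f"{v}_t1"],
                                               pairs.loc[sel, f"{v}_t2"])
            row[f"r{label}"] = r
            row[f"n{label}"] = n
            row[f"p{label}"] = p
        rows[v] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def phenotypic_correlations(data, variables, cluster="pair_id"):
    """Pairwise Pearson correlations with pair-clustered robust p-values.

    ``data`` may be a long table (one row per twin, variables as columns) or
    a wide pair table (converted internally).  Returns ``(r, p, flags)``
    where ``flags`` lists variables with zero variance (correlations
    involving them are NaN).
    """
    if f"{variables[0]}_t1" in data.columns:
        data = to_long(data, variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    R = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    P = pd.DataFrame(np.zeros((len(variables), len(variables))),
                     index=variables, columns=variables)
    flags = [v for v in variables
             if np.nanstd(data[v].to_numpy(dtype=float)) == 0]
    for i, vi in enumerate(variables):
        for j in range(i + 1, len(variables)):
            vj = variables[j]
            sub = data[[vi, vj, cluster]].dropna()
            if len(sub) < 4 or vi in flags or vj in flags:
                r = p = np.nan
            else:
                x = stats.zscore(sub[vi].to_numpy(dtype=float), ddof=1)
                y = stats.zscore(sub[vj].to_numpy(dtype=float), ddof=1)
                r = float(np.corrcoef(x, y)[0, 1])
                fit = sm.OLS(y, sm.add_constant(x)).fit(
                    cov_type="cluster",
                    cov_kwds={"groups": sub[cluster].to_numpy()})
                p = float(fit.pvalues[1])
            R.loc[vi, vj] = R.loc[vj, vi] = r
            P.loc[vi, vj] = P.loc[vj, vi] = p
    return R, P, flags


class FalconerEstimate(NamedTuple):
    value: float
    clipped: bool


def falconer_heritability(rmz, rdz):
    """Falconer's moment estimator h2 = 2 (rMZ - rDZ).

    ``clipped`` flags estimates falling outside [0, 1]; the raw value is
    always returned.
    """
    for r in (rmz, rdz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("twin correlations must lie in [-1, 1]")
    value = 2.0 * (rmz - rdz)
    return FalconerEstimate(value=value, clipped=not 0.0 <= value <= 1.0)


def descriptives_table(pairs, variables, outcome=None):
    """Means/SDs over responding individuals, optionally with correlations
    against a designated outcome (pair-clustered p-values)."""
    long = to_long(pairs, variables)
    out = pd.DataFrame({
        "mean": [np.nanmean(long[v]) for v in variables],
        "sd": [np.nanstd(long[v], ddof=1) for v in variables],
        "n": [int(long[v].notna().sum()) for v in variables],
    }, index=list(variables))
    if outcome is not None:
        R, P, _ = phenotypic_correlations(long, list(variables), cluster="pair_id")
        out[f"r_{outcome}"] = R[outcome]
        out[f"p_{outcome}"] = P[outcome]
        out.loc[outcome, f"p_{outcome}"] = 0.0
    return out
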