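"""Variance decomposition of a fitted Cholesky twin model.

Turns estimated path matrices into the quantities a twin study reports:
standardized variance components (heritabilities), genetic/environmental
correlation matrices, and — for a designated target phenotype placed last in
the Cholesky order — the split of its variance into personality-related
versus unique genetic and environmental parts, optionally adjusted for
random measurement error via the scale's reliability (Cronbach's alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _resolve(fit_or_params, sex="M"):
    """Accept a CholeskyTwinResults or a plain {comp: L} mapping."""
    if hasattr(fit_or_params, "params"):
        fit = fit_or_params
        if hasattr(fit, "converged") and not fit.converged:
            import warnings
            warnings.warn("decomposing a fit that did not report convergence")
        return {c: np.asarray(fit.params[sex][c], dtype=float)
                for c in ("A", "C", "E")}, tuple(fit.spec.variables)
    params = {c: np.asarray(L, dtype=float)
              for c, L in fit_or_params.items() if L is not None}
    p = next(iter(params.values())).shape[0]
    for c in ("A", "C", "E"):
        params.setdefault(c, np.zeros((p, p)))
    return params, tuple(f"v{i + 1}" for i in range(p))


def _covariances(params):
    return {c: L @ L.T for c, L in params.items()}


def standardized_components(fit, sex="M", variables=None):
    """Per-variable standardized a2, c2, e2 (each row sums to one)."""
    params, names = _resolve(fit, sex)
    if variables is not None:
        names = tuple(variables)
    cov = _covariances(params)
    total = sum(np.diag(M) for M in cov.values())
    if np.any(total <= 0):
        raise ValueError("zero implied variance for at least one variable")
    tab = pd.DataFrame({
        "a2": np.diag(cov["A"]) / total,
        "c2": np.diag(cov["C"]) / total,
        "e2": np.diag(cov["E"]) / total,
    }, index=list(names))
    return tab


def component_correlations(fit, component="A", sex="M", variables=None):
    """Correlations among the latent influences of one component.

    ``r(i, j) = M_ij / sqrt(M_ii M_jj)`` with ``M = L L^T``.  Variables with
    zero component variance give NaN rows/columns (flagged via the returned
    frame's attrs).
    """
    params, names = _resolve(fit, sex)
    if variables is not None:
        names = tuple(variables)
    M = params[component] @ params[component].T
    d = np.diag(M).copy()
    zero = d <= 1e-12
    d[zero] = np.nan
    R = M / np.sqrt(np.outer(d, d))
    np.fill_diagonal(R, np.where(zero, np.nan, 1.0))
    out = pd.DataFrame(R, index=list(names), columns=list(names))
    out.attrs["zero_variance"] = [n for n, z in zip(names, zero) if z]
    return out


def partition_target_variance(fit, target=None, sex="M", variables=None):
    """Split the target variable's variance along the Cholesky order.

    The target must be the *last* variable: its cross-paths from preceding
    (personality) latent factors give the personality-related shares, its own
    factor the unique shares.  Returns a dict with keys
    ``personality_genetic, unique_genetic, personality_environmental,
    unique_environmental`` summing to one; shared-environment (C) paths, when
    present, are folded into the environmental shares.
    """
    params, names = _resolve(fit, sex)
    if variables is not None:
        names = tuple(variables)
    p = len(names)
    if target is None:
        target = names[-1]
    if names.index(target) != p - 1:
        raise ValueError(
            f"target {target!r} must be last in the Cholesky order "
            f"{names}; refit with the variables reordered (cross-paths are "
            "order-dependent)")
    t = p - 1
    cov = _covariances(params)
    vt = sum(M[t, t] for M in cov.values())
    if vt <= 0:
        raise ValueError("zero implied variance for the target variable")
    LA, LC, LE = params["A"], params["C"], params["E"]
    shares = {
        "personality_genetic": float((LA[t, :t] ** 2).sum() / vt),
        "unique_genetic": float(LA[t, t] ** 2 / vt),
        "personality_environmental": float(
            ((LE[t, :t] ** 2).sum() + (LC[t, :t] ** 2).sum()) / vt),
        "unique_environmental": float(
            (LE[t, t] ** 2 + LC[t, t] ** 2) / vt),
    }
    return shares


def adjust_error_share(unique_env_share_pct, alpha):
    """Remove random measurement error from the unique-environment share.

    ``unique_env_share_pct`` is in percent; the error share is
    ``(1 - alpha) * 100``, so the 'true' unique-environment share is
    ``share - (1 - alpha) * 100``.  Raises if the share is below the error
    floor (a model/reliability inconsistency).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    error_pct = (1.0 - alpha) * 100.0
    if unique_env_share_pct < error_pct:
        raise ValueError(
            f"unique-environment share ({unique_env_share_pct}%) is below "
            f"the measurement-error floor ({error_pct}%)")
    return unique_env_share_pct - error_pct


@dataclass
class DecompositionResult:
    """Full derived-quantity bundle for one fitted model."""

    components: pd.DataFrame            # a2 / c2 / e2 per variable
    genetic_correlations: pd.DataFrame
    environmental_correlations: pd.DataFrame
    target: str = None
    target_shares: dict = None
    error_share_pct: float = None       # (1 - alpha) * 100
    true_unique_env_pct: float = None

    def shares_percent(self, digits=0):
        """Target shares in (rounded) percent, as reported in figures."""
        return {k: round(100.0 * v, digits) if digits else round(100.0 * v)
                for k, v in self.target_shares.items()}

    def summary(self):
        lines = ["Variance decomposition", "",
                 self.components.to_string(float_format=lambda x: f"{x: .3f}"),
                 "", "genetic correlations:",
                 self.genetic_correlations.to_string(
                     float_format=lambda x: f"{x: .3f}")]
        if self.target_shares:
            lines += ["", f"target variable: {self.target}"]
            for k, v in self.target_shares.items():
                lines.append(f"  {k}: {100 * v:.1f}%")
            if self.true_unique_env_pct is not None:
                lines.append(f"  measurement error (1 - alpha): "
                             f"{self.error_share_pct:.1f}%")
                lines.append(f"  true unique environment: "
                             f"{self.true_unique_env_pct:.1f}%")
        return "\n".join(lines)


def decompose(fit, target=None, alpha=None, sex="M"):
    """Standardized components, r_g/r_e matrices and the target partition."""
    comps = standardized_components(fit, sex=sex)
    rg = component_correlations(fit, "A", sex=sex)
    re = component_correlations(fit, "E", sex=sex)
    target = comps.index[-1] if target is None else target
    shares = partition_target_variance(fit, target=target, sex=sex)
    err = true_e = None
    if alpha is not None:
        err = (1.0 - alpha) * 100.0
        true_e = adjust_error_share(100.0 * shares["unique_environmental"],
                                    alpha)
    return DecompositionResult(
        components=comps, genetic_correlations=rg,
        environmental_correlations=re, target=target, target_shares=shares,
        error_share_pct=err, true_unique_env_pct=true_e)


def correlation_panel(result):
    """Matrix with genetic correlations above and environmental below the
    diagonal (the usual figure layout)."""
    rg = result.genetic_correlations
    re = result.environmental_correlations
    out = rg.copy()
    n = len(out)
    vals = out.to_numpy()
    revals = re.to_numpy()
    for i in range(n):
        for j in range(i):
            vals[i, j] = revals[i, j]
    np.fill_diagonal(vals, 1.0)
    return pd.DataFrame(vals, index=rg.index, columns=rg.columns)
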