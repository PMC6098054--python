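"""Simulation of same-sex twin cohorts with known A/C/E architecture.

Cohorts are held as wide-format :class:`pandas.DataFrame` tables, one row per
pair, with columns ``pair_id, zygosity, sex, age`` and ``<var>_t1, <var>_t2``
per phenotype (``NaN`` = missing).  The three generation stages — covariance
structure, single-responder missingness and measurement error — consume
independent random streams so that toggling one stage does not perturb the
others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .truth import GROUPS, SEXES

ID_COLS = ("pair_id", "zygosity", "sex", "age")


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def phenotype_columns(variables):
    return [f"{v}_t{t}" for v in variables for t in (1, 2)]


def _twin_cols(variables, twin):
    return [f"{v}_t{twin}" for v in variables]


def simulate_cohort(truth, design, seed=None):
    """Draw complete twin pairs from a :class:`GeneratingTruth`.

    Each pair's stacked phenotype vector (twin 1 then twin 2) is multivariate
    normal with within-twin covariance ``V = A + C + E`` and cross-twin
    covariance ``A + C`` (MZ) or ``0.5 A + C`` (DZ); per-sex means and
    optional linear age effects are added afterwards.  Deterministic given
    the seed (``design.seed`` unless overridden).
    """
    rng = _rng(design.seed if seed is None else seed)
    p = truth.n_variables
    lo, hi = design.age_range
    frames = []
    for zyg, sex in GROUPS:
        n = design.n_pairs(zyg, sex)
        if n == 0:
            continue
        V = truth.implied_covariance(sex)
        X = truth.cross_twin_covariance(zyg, sex)
        sigma = np.block([[V, X], [X, V]])
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"implied pair covariance for zygosity {zyg!r}, sex {sex!r} "
                "is not positive definite (check L_A/L_C/L_E)") from None
        ages = rng.uniform(lo, hi, size=n)
        Y = rng.standard_normal((n, 2 * p)) @ chol.T
        mu = np.tile(truth.means[sex], 2)
        Y += mu
        if truth.age_slopes is not None:
            Y += np.tile(truth.age_slopes, 2) * (ages - truth.age_center)[:, None]
        df = pd.DataFrame({
            "pair_id": [f"{zyg}{sex}-{i:05d}" for i in range(n)],
            "zygosity": zyg, "sex": sex, "age": ages,
        })
        for j, v in enumerate(truth.variables):
            df[f"{v}_t1"] = Y[:, j]
            df[f"{v}_t2"] = Y[:, p + j]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def apply_single_responders(pairs, variables, rate, seed=0):
    """Blank one twin's phenotypes in a random Bernoulli(``rate``) pair subset.

    Within each selected pair the missing twin is chosen with probability 1/2,
    so individual-level marginal distributions are unchanged in expectation.
    ``rate`` must lie in [0, 1): fully empty pairs are not allowed.
    """
    if not (0 <= rate < 1):
        raise ValueError("single-responder rate must lie in [0, 1)")
    out = pairs.copy()
    if rate == 0:
        return out
    rng = _rng(seed)
    n = len(out)
    hit = rng.random(n) < rate
    which = rng.integers(1, 3, size=n)  # twin blanked if hit
    for twin in (1, 2):
        rows = hit & (which == twin)
        out.loc[rows, _twin_cols(variables, twin)] = np.nan
    return out


def inject_measurement_error(pairs, variables, reliability, seed=0,
                             true_variances=None):
    """Add independent noise so observed-score reliability equals alpha.

    Noise variance per variable is ``var_true * (1 - alpha) / alpha``, which
    makes the observed score's reliability (true variance over total) exactly
    ``alpha``.  ``true_variances`` defaults to the empirical per-variable
    variance of the input scores (both twins pooled).  Noise is independent
    across twins and variables.
    """
    alpha = np.broadcast_to(np.asarray(reliability, dtype=float),
                            (len(variables),)).copy()
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValueError("reliability (alpha) must lie in (0, 1]")
    out = pairs.copy()
    if np.all(alpha == 1):
        return out
    rng = _rng(seed)
    if true_variances is None:
        true_variances = np.array([
            np.nanvar(np.concatenate([out[f"{v}_t1"], out[f"{v}_t2"]]), ddof=1)
            for v in variables])
    else:
        true_variances = np.asarray(true_variances, dtype=float)
    noise_sd = np.sqrt(true_variances * (1.0 - alpha) / alpha)
    n = len(out)
    for j, v in enumerate(variables):
        for twin in (1, 2):
            col = f"{v}_t{twin}"
            out[col] = out[col] + rng.normal(0.0, noise_sd[j], size=n)
    return out


def generate_cohort(truth, design):
    """Full generation: structure, single responders, measurement error.

    The three stages draw from independent child streams of ``design.seed``.
    """
    s_struct, s_miss, s_noise = np.random.SeedSequence(design.seed).spawn(3)
    df = simulate_cohort(truth, design, seed=np.random.default_rng(s_struct))
    df = apply_single_responders(df, truth.variables,
                                 design.single_responder_rate,
                                 seed=np.random.default_rng(s_miss))
    true_var = {s: np.diag(truth.implied_covariance(s)) for s in SEXES}
    # pooled implied variance (sexes share the scale in the default truths)
    pooled = (true_var["M"] + true_var["F"]) / 2.0
    df = inject_measurement_error(df, truth.variables, truth.reliability,
                                  seed=np.random.default_rng(s_noise),
                                  true_variances=pooled)
    return df


# ---------------------------------------------------------------------------
# long/wide conversion and CSV round-trip
# ---------------------------------------------------------------------------

def to_long(pairs, variables):
    """One row per twin: pair_id, twin (1/2), zygosity, sex, age, <vars>."""
    frames = []
    for twin in (1, 2):
        cols = {f"{v}_t{twin}": v for v in variables}
        sub = pairs[list(ID_COLS) + list(cols)].rename(columns=cols)
        sub.insert(1, "twin", twin)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pair_id", "twin"], kind="stable").reset_index(drop=True)


def from_long(long, variables):
    """Inverse of :func:`to_long`."""
    wide = None
    for twin in (1, 2):
        sub = long[long["twin"] == twin].drop(columns="twin")
        sub = sub.rename(columns={v: f"{v}_t{twin}" for v in variables})
        if wide is None:
            wide = sub
        else:
            wide = wide.merge(sub[["pair_id"] + _twin_cols(variables, twin)],
                              on="pair_id", how="outer")
    return wide.reset_index(drop=True)


def drop_empty_pairs(pairs, variables):
    """Remove pairs where both twins are fully missing on all variables."""
    cols = phenotype_columns(variables)
    keep = ~pairs[cols].isna().all(axis=1)
    return pairs.loc[keep].reset_index(drop=True)


def responders(pairs, variables):
    """Long table restricted to twins with at least one observed score."""
    long = to_long(pairs, variables)
    return long.loc[~long[list(variables)].isna().all(axis=1)].reset_index(drop=True)


def write_cohort_csv(pairs, path):
    pairs.to_csv(path, index=False)


def read_cohort_csv(path, variables=None):
    df = pd.read_csv(path, dtype={"pair_id": str, "zygosity": str, "sex": str})
    if variables is not None:
        missing = [c for c in phenotype_columns(variables) if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV lacks phenotype columns: {missing}")
    return df
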