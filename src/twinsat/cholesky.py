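"""Multivariate Cholesky twin models fitted by full-information ML.

The central objects follow the statsmodels convention: a
:class:`CholeskyTwinModel` is built from a wide-format pair table and a
:class:`CholeskyModelSpec`; :meth:`CholeskyTwinModel.fit` returns a
:class:`CholeskyTwinResults` carrying the estimated path matrices, the
-2 log-likelihood, degrees of freedom, AIC, convergence diagnostics and
profile-likelihood confidence intervals.

Model
-----
Each phenotype loads on its own latent additive-genetic (A), shared-
environment (C) and non-shared-environment (E) factor plus the factors of
all preceding phenotypes, giving lower-triangular path matrices ``L_A``,
``L_C``, ``L_E`` per component.  Latent A factors correlate 1 across MZ
co-twins and 0.5 across DZ co-twins; C factors correlate 1 in both zygosity
groups; E factors are uncorrelated across twins.  The implied covariance of
a pair's stacked 2p-vector is therefore

    [[ A + C + E,  w A + C ],
     [ w A + C,    A + C + E ]],   w = 1 (MZ) or 0.5 (DZ).

Sex-limitation regimes: ``common_sex_limitation`` frees all path matrices
per sex; ``scalar_sex_limitation`` shares the standardized solution across
sexes but frees one positive scale factor per variable for females (total
SDs may differ, standardized parameters may not); ``equal_across_sex`` uses
a single parameter set.  Means are free per sex and variable; a linear age
effect is optional.

Likelihood
----------
Every pair contributes the multivariate-normal density of its *observed*
subvector (single responders contribute the p-dimensional marginal of the
responding twin), i.e. full-information maximum likelihood.  The Cholesky
parameterization keeps all component matrices positive semi-definite by
construction, and a small lower bound on the diagonal of ``L_E`` keeps the
implied pair covariance positive definite throughout optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .truth import GROUPS, SEXES

LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12
_E_DIAG_FLOOR = 1e-6

SEX_MODES = ("common_sex_limitation", "scalar_sex_limitation",
             "equal_across_sex")

MODE_LABELS = {"common_sex_limitation": "Common sex-lim",
               "scalar_sex_limitation": "Scalar sex-lim",
               "equal_across_sex": "Equal across sex"}


class ConvergenceError(RuntimeError):
    """All optimizer restarts failed to produce a finite likelihood."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class CholeskyModelSpec:
    """Which variables, which components, which sex-limitation regime.

    ``components`` is a subset of {"A", "C", "E"} with "E" mandatory.  The
    variable order is fixed and meaningful: Cholesky paths are
    order-dependent even though the fit and implied covariances are not.
    """

    variables: tuple
    components: tuple = ("A", "E")
    sex_mode: str = "equal_across_sex"
    age_slope: bool = False

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "components", tuple(self.components))
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        if "E" not in self.components:
            raise ValueError("the E component is mandatory")
        if any(c not in ("A", "C", "E") for c in self.components):
            raise ValueError("components must be a subset of {'A','C','E'}")
        if self.sex_mode not in SEX_MODES:
            raise ValueError(f"unknown sex_mode {self.sex_mode!r}; "
                             f"expected one of {SEX_MODES}")

    @property
    def p(self):
        return len(self.variables)

    @property
    def label(self):
        return f"{MODE_LABELS[self.sex_mode]} {''.join(self.components)}"


# ---------------------------------------------------------------------------
# parameter layout (the sex-limitation machinery)
# ---------------------------------------------------------------------------

class ParameterLayout:
    """Mapping between the flat parameter vector and structured parameters.

    ``unpack`` returns ``{"M": {comp: L, ...}, "F": {...}, "means": {"M":
    vec, "F": vec}, "slopes": vec or None}``.  Free-parameter counts per
    sex-limitation mode drive the model's statistical degrees of freedom.
    """

    def __init__(self, spec):
        self.spec = spec
        p = spec.p
        self.tril = np.tril_indices(p)
        t = len(self.tril[0])
        self.t = t
        self.segments = {}
        self.names = []
        self.bounds = []
        pos = 0

        def add(name, size, elem_names, elem_bounds):
            nonlocal pos
            self.segments[name] = slice(pos, pos + size)
            self.names.extend(elem_names)
            self.bounds.extend(elem_bounds)
            pos += size

        def tri_names(comp, sex_tag):
            out = []
            for r, c in zip(*self.tril):
                tag = f"_{sex_tag}" if sex_tag else ""
                out.append(f"{comp.lower()}{tag}[{spec.variables[r]},"
                           f"{spec.variables[c]}]")
            return out

        def tri_bounds(comp):
            floor = _E_DIAG_FLOOR if comp == "E" else 0.0
            return [(floor, None) if r == c else (None, None)
                    for r, c in zip(*self.tril)]

        if spec.sex_mode == "common_sex_limitation":
            for sex in SEXES:
                for comp in spec.components:
                    add(f"L_{comp}_{sex}", t, tri_names(comp, sex),
                        tri_bounds(comp))
        else:
            for comp in spec.components:
                add(f"L_{comp}", t, tri_names(comp, ""), tri_bounds(comp))
            if spec.sex_mode == "scalar_sex_limitation":
                add("scale_F", p, [f"scale_F[{v}]" for v in spec.variables],
                    [(1e-3, None)] * p)
        for sex in SEXES:
            add(f"means_{sex}", p, [f"mean_{sex}[{v}]" for v in spec.variables],
                [(None, None)] * p)
        if spec.age_slope:
            add("slopes", p, [f"age_slope[{v}]" for v in spec.variables],
                [(None, None)] * p)
        self.n_free = pos

    def _tri(self, seg):
        p = self.spec.p
        L = np.zeros((p, p))
        L[self.tril] = seg
        return L

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        spec = self.spec
        out = {"M": {}, "F": {}}
        if spec.sex_mode == "common_sex_limitation":
            for sex in SEXES:
                for comp in spec.components:
                    out[sex][comp] = self._tri(
                        theta[self.segments[f"L_{comp}_{sex}"]])
        else:
            shared = {comp: self._tri(theta[self.segments[f"L_{comp}"]])
                      for comp in spec.components}
            if spec.sex_mode == "scalar_sex_limitation":
                s = theta[self.segments["scale_F"]]
                out["M"] = shared
                out["F"] = {comp: s[:, None] * L for comp, L in shared.items()}
            else:
                out["M"] = shared
                out["F"] = shared
        for comp in ("A", "C", "E"):
            for sex in SEXES:
                out[sex].setdefault(comp, np.zeros((spec.p, spec.p)))
        out["means"] = {sex: theta[self.segments[f"means_{sex}"]]
                        for sex in SEXES}
        out["slopes"] = (theta[self.segments["slopes"]]
                         if spec.age_slope else None)
        return out

    def pack(self, sex_params, means, slopes=None, scale_F=None):
        """Build a flat vector from per-sex L matrices and mean vectors."""
        theta = np.zeros(self.n_free)
        spec = self.spec
        if spec.sex_mode == "common_sex_limitation":
            for sex in SEXES:
                for comp in spec.components:
                    theta[self.segments[f"L_{comp}_{sex}"]] = \
                        sex_params[sex][comp][self.tril]
        else:
            for comp in spec.components:
                theta[self.segments[f"L_{comp}"]] = \
                    sex_params["M"][comp][self.tril]
            if spec.sex_mode == "scalar_sex_limitation":
                theta[self.segments["scale_F"]] = (
                    np.ones(spec.p) if scale_F is None else scale_F)
        for sex in SEXES:
            theta[self.segments[f"means_{sex}"]] = means[sex]
        if spec.age_slope:
            theta[self.segments["slopes"]] = (
                np.zeros(spec.p) if slopes is None else slopes)
        return theta


def build_sex_limitation(spec):
    """Parameter layout for the spec's sex-limitation regime."""
    return ParameterLayout(spec)


def expected_pair_covariance(params, zygosity, sex=None):
    """2p x 2p expected covariance of a pair's stacked phenotype vector.

    ``params`` is either ``{"A": L_A, "C": L_C, "E": L_E}`` (any subset,
    matrices are Cholesky paths) or the full unpacked structure, in which
    case ``sex`` selects the branch.  Cross-twin block is ``A + C`` for MZ
    and ``0.5 A + C`` for DZ.
    """
    if sex is not None and sex in params:
        params = params[sex]
    p = None
    comps = {}
    for name in ("A", "C", "E"):
        L = params.get(name)
        if L is None:
            continue
        L = np.asarray(L, dtype=float)
        comps[name] = L @ L.T
        p = L.shape[0]
    zero = np.zeros((p, p))
    A = comps.get("A", zero)
    C = comps.get("C", zero)
    E = comps.get("E", zero)
    within = A + C + E
    w = 1.0 if zygosity == "MZ" else 0.5
    cross = w * A + C
    return np.block([[within, cross], [cross, within]])


# ---------------------------------------------------------------------------
# data blocks
# ---------------------------------------------------------------------------

class _PatternBlock:
    """Rows of one zygosity-sex group sharing a missingness pattern."""

    __slots__ = ("zygosity", "sex", "idx", "Y", "ages", "n", "k")

    def __init__(self, zygosity, sex, idx, Y, ages):
        self.zygosity = zygosity
        self.sex = sex
        self.idx = idx
        self.Y = Y
        self.ages = ages
        self.n = Y.shape[0]
        self.k = Y.shape[1]


class CholeskyTwinModel:
    """FIML Cholesky twin model over zygosity-by-sex groups.

    Parameters
    ----------
    data : wide pair table with ``pair_id, zygosity, sex, age`` and
        ``<var>_t1 / <var>_t2`` columns.
    spec : :class:`CholeskyModelSpec`.
    zscore : z-score each variable over all twins before fitting (default);
        path estimates are then near-standardized, and standardized
        quantities are always recomputed from implied variances anyway.
    """

    def __init__(self, data, spec, zscore=True, age_center=57.5):
        self.spec = spec
        self.layout = build_sex_limitation(spec)
        self.age_center = age_center
        self.zscore = zscore
        p = spec.p
        cols = [f"{v}_t{t}" for t in (1, 2) for v in spec.variables]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks phenotype columns: {missing}")
        zygs = set(data["zygosity"])
        if not {"MZ", "DZ"} <= zygs:
            raise ValueError("data must contain both MZ and DZ pairs")

        raw = data[cols].to_numpy(dtype=float)
        if zscore:
            stacked = np.concatenate([raw[:, :p], raw[:, p:]])
            self._scale_mean = np.nanmean(stacked, axis=0)
            self._scale_sd = np.nanstd(stacked, axis=0, ddof=1)
            if np.any(self._scale_sd == 0):
                bad = [spec.variables[i]
                       for i in np.nonzero(self._scale_sd == 0)[0]]
                raise ValueError(f"zero-variance variables: {bad}")
            raw = (raw - np.tile(self._scale_mean, 2)) / np.tile(self._scale_sd, 2)
        else:
            self._scale_mean = np.zeros(p)
            self._scale_sd = np.ones(p)

        ages = data["age"].to_numpy(dtype=float) if "age" in data else np.zeros(len(data))
        self._blocks = []
        n_points = 0
        self.group_sizes = {}
        for zyg, sex in GROUPS:
            sel = ((data["zygosity"] == zyg) & (data["sex"] == sex)).to_numpy()
            Y = raw[sel]
            ga = ages[sel]
            obs = ~np.isnan(Y)
            keep = obs.any(axis=1)
            Y, ga, obs = Y[keep], ga[keep], obs[keep]
            self.group_sizes[(zyg, sex)] = Y.shape[0]
            n_points += int(obs.sum())
            if Y.shape[0] == 0:
                continue
            # group rows by missingness pattern
            codes = obs @ (1 << np.arange(2 * p))
            for code in np.unique(codes):
                rows = codes == code
                idx = np.nonzero(obs[np.argmax(rows)])[0]
                self._blocks.append(_PatternBlock(
                    zyg, sex, idx, np.ascontiguousarray(Y[rows][:, idx]),
                    ga[rows]))
        self.n_obs_points = n_points
        self.n_pairs = sum(self.group_sizes.values())

    @classmethod
    def from_dataframe(cls, data, variables, components=("A", "E"),
                       sex_mode="equal_across_sex", **kwargs):
        spec = CholeskyModelSpec(tuple(variables), tuple(components), sex_mode)
        return cls(data, spec, **kwargs)

    # -- likelihood --------------------------------------------------------

    def minus2ll(self, theta_or_params):
        """FIML -2 log-likelihood at a parameter vector (or unpacked dict)."""
        if isinstance(theta_or_params, dict):
            params = theta_or_params
        else:
            params = self.layout.unpack(theta_or_params)
        sigma = {}
        chol_cache = {}
        for sex in SEXES:
            for zyg in ("MZ", "DZ"):
                sigma[(zyg, sex)] = expected_pair_covariance(params[sex], zyg)
        means = params["means"]
        slopes = params["slopes"]
        p = self.spec.p
        total = 0.0
        for b in self._blocks:
            key = (b.zygosity, b.sex, tuple(b.idx))
            fac = chol_cache.get(key)
            if fac is None:
                S = sigma[(b.zygosity, b.sex)][np.ix_(b.idx, b.idx)]
                try:
                    cfac = linalg.cholesky(S, lower=True)
                except linalg.LinAlgError:
                    return _BIG
                fac = (cfac, 2.0 * np.log(np.diag(cfac)).sum())
                chol_cache[key] = fac
            cfac, logdet = fac
            mu = np.tile(means[b.sex], 2)[b.idx]
            if slopes is not None:
                shift = np.tile(slopes, 2)[b.idx]
                resid = b.Y - mu - (b.ages - self.age_center)[:, None] * shift
            else:
                resid = b.Y - mu
            z = linalg.solve_triangular(cfac, resid.T, lower=True,
                                        check_finite=False)
            total += b.n * (b.k * LOG2PI + logdet) + float((z * z).sum())
        if not np.isfinite(total):
            return _BIG
        return total

    # -- starting values ---------------------------------------------------

    def _moment_matrices(self):
        """Double-entered within- and cross-twin covariances (complete pairs)."""
        p = self.spec.p
        within_rows = []
        cross = {}
        for zyg in ("MZ", "DZ"):
            xs = []
            for b in self._blocks:
                if b.zygosity != zyg or b.k != 2 * p:
                    continue
                xs.append(b.Y)
            if xs:
                Y = np.concatenate(xs)
                t1, t2 = Y[:, :p], Y[:, p:]
                de1 = np.concatenate([t1, t2])
                de2 = np.concatenate([t2, t1])
                within_rows.append(de1)
                if len(de1) >= p + 2:
                    d1 = de1 - de1.mean(axis=0)
                    d2 = de2 - de2.mean(axis=0)
                    cross[zyg] = d1.T @ d2 / len(de1)
        if not within_rows or set(cross) != {"MZ", "DZ"}:
            return None
        allrows = np.concatenate(within_rows)
        V = np.cov(allrows.T).reshape(p, p)
        return V, cross["MZ"], cross["DZ"]

    def _psd_chol(self, M, floor):
        M = (M + M.T) / 2.0
        w, U = np.linalg.eigh(M)
        w = np.maximum(w, floor)
        return np.linalg.cholesky((U * w) @ U.T)

    def _start_theta(self):
        p = self.spec.p
        mm = self._moment_matrices()
        if mm is None:
            V = np.eye(p)
            A = 0.4 * V
            C = np.zeros((p, p))
        else:
            V, Cmz, Cdz = mm
            A = 2.0 * (Cmz - Cdz)
            C = Cdz * 2.0 - Cmz if "C" in self.spec.components else np.zeros((p, p))
        if "C" not in self.spec.components:
            C = np.zeros((p, p))
        scale = float(np.trace(V)) / p
        L_A = self._psd_chol(A, 0.02 * scale)
        L_C = (self._psd_chol(C, 0.02 * scale) if "C" in self.spec.components
               else np.zeros((p, p)))
        E = V - L_A @ L_A.T - L_C @ L_C.T
        L_E = self._psd_chol(E, 0.05 * scale)
        sex_params = {s: {"A": L_A, "C": L_C, "E": L_E} for s in SEXES}
        means = {}
        for sex in SEXES:
            num = np.zeros(p)
            den = np.zeros(p)
            for b in self._blocks:
                if b.sex != sex:
                    continue
                for pos, j in enumerate(b.idx):
                    num[j % p] += b.Y[:, pos].sum()
                    den[j % p] += b.n
            means[sex] = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        return self.layout.pack(sex_params, means)

    # -- fitting -----------------------------------------------------------

    def fit(self, start=None, n_restarts=5, jitter=0.05, maxiter=2000,
            seed=0, name=None):
        """Minimize the FIML -2LL with multi-start L-BFGS-B.

        The first start is moment-based (Falconer-informed); the remaining
        ``n_restarts - 1`` starts are jittered copies.  The best restart is
        returned; boundary solutions (a diagonal path at zero) are flagged
        in the results, not treated as errors.
        """
        layout = self.layout
        theta0 = np.asarray(start, dtype=float) if start is not None \
            else self._start_theta()
        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(max(0, n_restarts - 1)):
            th = theta0.copy()
            th += jitter * np.maximum(np.abs(th), 0.2) * rng.standard_normal(len(th))
            starts.append(th)
        lb = np.array([-np.inf if b[0] is None else b[0] for b in layout.bounds])
        results = []
        for th in starts:
            th = np.maximum(th, lb)
            res = optimize.minimize(
                self.minus2ll, th, method="L-BFGS-B", bounds=layout.bounds,
                options={"maxiter": maxiter,
                         "maxfun": max(50 * maxiter, 300 * len(th)),
                         "ftol": 1e-11, "gtol": 1e-7})
            results.append(res)
        finite = [r for r in results if np.isfinite(r.fun) and r.fun < _BIG / 2]
        if not finite:
            raise ConvergenceError(
                "no optimizer restart reached a finite likelihood",
                diagnostics=[{"status": r.status, "message": str(r.message),
                              "fun": float(r.fun)} for r in results])
        best = min(finite, key=lambda r: r.fun)
        params = layout.unpack(best.x)
        boundary = []
        for i, (nm, (lo, _hi)) in enumerate(zip(layout.names, layout.bounds)):
            if lo is not None and lo >= 0 and abs(best.x[i] - lo) < 1e-4 \
                    and not nm.startswith("mean"):
                boundary.append(nm)
        n_free = layout.n_free
        df = self.n_obs_points - n_free
        m2ll = float(best.fun)
        return CholeskyTwinResults(
            model=self, spec=self.spec, theta=best.x.copy(), params=params,
            minus2ll=m2ll, n_free=n_free, n_obs_points=self.n_obs_points,
            df=df, aic=m2ll - 2.0 * df, converged=bool(best.success),
            boundary_params=boundary, name=name or self.spec.label,
            optimizer={"status": int(best.status), "message": str(best.message),
                       "nit": int(best.nit), "n_restarts": len(starts),
                       "restart_funs": [float(r.fun) for r in results]})

    def saturated_minus2ll(self):
        """-2LL of the saturated model (free mean/covariance per group).

        Closed form requires complete pairs; raises if any pair in a
        non-empty group is incomplete.
        """
        p2 = 2 * self.spec.p
        total = 0.0
        for zyg, sex in GROUPS:
            blocks = [b for b in self._blocks
                      if b.zygosity == zyg and b.sex == sex]
            if not blocks:
                continue
            if any(b.k != p2 for b in blocks):
                raise ValueError("saturated -2LL requires complete pairs")
            Y = np.concatenate([b.Y for b in blocks])
            n = Y.shape[0]
            if n <= p2:
                raise ValueError("too few pairs for a saturated group fit")
            S = np.cov(Y.T, bias=True)
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                raise ValueError("singular saturated covariance")
            total += n * (p2 * LOG2PI + logdet + p2)
        return total


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class ProfileCI(tuple):
    """(lower, upper) profile-likelihood interval with boundary flags."""

    def __new__(cls, lower, upper, level, lower_at_bound=False,
                upper_at_bound=False):
        self = super().__new__(cls, (lower, upper))
        self.level = level
        self.lower_at_bound = lower_at_bound
        self.upper_at_bound = upper_at_bound
        return self

    lower = property(lambda self: self[0])
    upper = property(lambda self: self[1])


@dataclass
class CholeskyTwinResults:
    """Fitted Cholesky twin model.

    ``params`` is the unpacked structure ``{"M": {"A": L, ...}, "F": ...,
    "means": ..., "slopes": ...}``; ``df`` is the number of non-missing
    observed data points minus the number of free parameters, and
    ``aic = minus2ll - 2 * df``.
    """

    model: CholeskyTwinModel
    spec: CholeskyModelSpec
    theta: np.ndarray
    params: dict
    minus2ll: float
    n_free: int
    n_obs_points: int
    df: int
    aic: float
    converged: bool
    boundary_params: list
    name: str = ""
    optimizer: dict = field(default_factory=dict)

    # -- derived matrices --------------------------------------------------

    def paths(self, component, sex="M"):
        return self.params[sex][component]

    def component_covariance(self, component, sex="M"):
        L = self.paths(component, sex)
        return L @ L.T

    def implied_within_covariance(self, sex="M"):
        return sum(self.component_covariance(c, sex) for c in ("A", "C", "E"))

    def implied_pair_covariance(self, zygosity, sex="M"):
        return expected_pair_covariance(self.params[sex], zygosity)

    # -- derived quantities (delegated to the decomposition module) --------

    def standardized_components(self, sex="M"):
        from .decompose import standardized_components
        return standardized_components(self, sex=sex)

    def component_correlations(self, component="A", sex="M"):
        from .decompose import component_correlations
        return component_correlations(self, component, sex=sex)

    def partition_target_variance(self, target=None, sex="M"):
        from .decompose import partition_target_variance
        return partition_target_variance(self, target=target, sex=sex)

    def decompose(self, target=None, alpha=None, sex="M"):
        from .decompose import decompose
        return decompose(self, target=target, alpha=alpha, sex=sex)

    def h2(self, variable, sex="M"):
        tab = self.standardized_components(sex=sex)
        return float(tab.loc[variable, "a2"])

    # -- profile confidence intervals --------------------------------------

    def _quantity(self, quantity, sex="M"):
        """Resolve a named quantity to a function of the parameter vector."""
        if callable(quantity):
            layout = self.model.layout
            return lambda th: float(quantity(layout.unpack(th))), (None, None)
        kind, _, rest = quantity.partition(":")
        layout = self.model.layout
        variables = list(self.spec.variables)
        if kind == "h2":
            j = variables.index(rest)

            def f(th):
                prm = layout.unpack(th)[sex]
                a = prm["A"][j] @ prm["A"][j]
                tot = sum((prm[c][j] @ prm[c][j]) for c in ("A", "C", "E"))
                return a / tot
            return f, (0.0, 1.0)
        if kind in ("rg", "rc", "re"):
            comp = {"rg": "A", "rc": "C", "re": "E"}[kind]
            v1, v2 = (s.strip() for s in rest.split(","))
            i, j = variables.index(v1), variables.index(v2)

            def f(th):
                L = layout.unpack(th)[sex][comp]
                M = L @ L.T
                return M[i, j] / np.sqrt(max(M[i, i] * M[j, j], 1e-24))
            return f, (-1.0, 1.0)
        raise ValueError(f"unknown profile quantity {quantity!r}")

    def profile_ci(self, quantity, level=0.95, sex="M", step=None, xtol=2e-3,
                   max_expand=40):
        """Profile-likelihood confidence interval for a scalar quantity.

        ``quantity`` is ``"h2:<var>"``, ``"rg:<v1>,<v2>"`` (``rc``/``re``
        analogous) or a callable of the unpacked parameters.  Bounds are the
        points where the profile -2LL exceeds the optimum by the chi-square(1)
        quantile; a bound at the edge of the quantity's natural range is
        returned one-sided and flagged.
        """
        f, (nat_lo, nat_hi) = self._quantity(quantity, sex=sex)
        model = self.model
        crit = stats.chi2.ppf(level, 1)
        target = self.minus2ll + crit
        ghat = f(self.theta)
        if step is None:
            span = (nat_hi - nat_lo) if nat_lo is not None else max(abs(ghat), 1.0)
            step = 0.04 * span
        bounds = model.layout.bounds

        def profile(c, warm):
            cons = [{"type": "eq", "fun": lambda th, c=c: f(th) - c}]
            best = None
            for x0 in warm:
                res = optimize.minimize(
                    model.minus2ll, x0, method="SLSQP", bounds=bounds,
                    constraints=cons,
                    options={"maxiter": 300, "ftol": 1e-9})
                if np.isfinite(res.fun) and abs(f(res.x) - c) < 1e-5:
                    if best is None or res.fun < best[0]:
                        best = (float(res.fun), res.x)
            if best is None:
                return np.inf, None
            return best

        out = {}
        flags = {}
        for side, sgn, nat in (("lower", -1.0, nat_lo), ("upper", +1.0, nat_hi)):
            warm_x = self.theta
            prev_c = ghat
            bound = None
            at_nat = False
            for k in range(1, max_expand + 1):
                c = ghat + sgn * k * step
                clipped = False
                if nat is not None and (sgn < 0 and c <= nat or sgn > 0 and c >= nat):
                    # evaluate just inside the natural edge
                    c = nat - sgn * 1e-6 * max(1.0, abs(nat))
                    clipped = True
                val, x = profile(c, [warm_x, self.theta])
                if val >= target:
                    lo_c, hi_c = (c, prev_c) if sgn < 0 else (prev_c, c)

                    def g(cc):
                        v, _ = profile(cc, [warm_x, self.theta])
                        return v - target
                    bound = optimize.brentq(g, lo_c, hi_c, xtol=xtol)
                    break
                if x is not None:
                    warm_x = x
                prev_c = c
                if clipped:
                    bound = nat
                    at_nat = True
                    break
            if bound is None:
                bound = prev_c
                at_nat = True
            out[side] = float(bound)
            flags[side] = at_nat
        return ProfileCI(out["lower"], out["upper"], level,
                         lower_at_bound=flags["lower"],
                         upper_at_bound=flags["upper"])

    # -- reporting ---------------------------------------------------------

    def path_table(self):
        """Path estimates as a long edge list (component, sex, from, to, value)."""
        rows = []
        tril = zip(*np.tril_indices(self.spec.p))
        tril = list(tril)
        for sex in SEXES:
            for comp in self.spec.components:
                L = self.paths(comp, sex)
                for r, c in tril:
                    rows.append({"component": comp, "sex": sex,
                                 "factor": f"{comp}{c + 1}",
                                 "variable": self.spec.variables[r],
                                 "value": L[r, c]})
        return pd.DataFrame(rows)

    def summary(self):
        spec = self.spec
        lines = [
            f"Cholesky twin model: {self.name}",
            f"variables: {', '.join(spec.variables)}",
            f"components: {''.join(spec.components)}   "
            f"sex mode: {spec.sex_mode}",
            f"pairs: {self.model.n_pairs}   observed data points: "
            f"{self.n_obs_points}",
            f"-2LL = {self.minus2ll:.2f}   df = {self.df}   "
            f"AIC = {self.aic:.2f}",
            f"free parameters: {self.n_free}   converged: {self.converged}",
        ]
        if self.boundary_params:
            lines.append(f"boundary solutions: {', '.join(self.boundary_params)}")
        lines.append("")
        tab = self.standardized_components()
        lines.append("standardized variance components (male branch):")
        lines.append(tab.to_string(float_format=lambda x: f"{x: .3f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def lrt_arithmetic(m2ll_nested, m2ll_base, df_nested, df_base):
    """Delta -2LL, delta df and chi-square p for one nested comparison."""
    delta = m2ll_nested - m2ll_base
    ddf = df_nested - df_base
    if ddf < 0:
        raise ValueError("nested model must have no more free parameters "
                         "than the base model")
    if ddf == 0:
        p = 1.0 if delta <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(max(delta, 0.0), ddf))
    return delta, ddf, p


def aic_from_fit(minus2ll, df):
    """AIC = -2LL - 2 df (degrees-of-freedom convention)."""
    return minus2ll - 2.0 * df


def compare_models(fits, base=None, tol=1e-6):
    """Nested-model comparison table with the best model flagged by AIC.

    ``fits`` is a sequence of :class:`CholeskyTwinResults` (or objects with
    ``name, minus2ll, df, n_free, aic``); ``base`` defaults to the first.
    Negative Δ-2LL beyond optimizer tolerance and non-nested comparisons
    (nested model with more free parameters than the base) are flagged with
    warnings and a NaN p-value.
    """
    fits = list(fits)
    if base is None:
        base = fits[0]
    rows = []
    for fit in fits:
        delta = fit.minus2ll - base.minus2ll
        ddf = fit.df - base.df
        if ddf < 0 and fit is not base:
            warnings.warn(f"{fit.name}: more free parameters than the base "
                          "model; LRT skipped, AIC-only comparison")
            p = np.nan
        elif ddf == 0:
            p = 1.0 if abs(delta) <= tol else np.nan
        else:
            if delta < -tol:
                warnings.warn(f"{fit.name}: -2LL below the base model's "
                              f"({delta:.3g}); check convergence")
            p = float(stats.chi2.sf(max(delta, 0.0), ddf))
        rows.append({"model": fit.name, "minus2ll": fit.minus2ll,
                     "df": fit.df, "n_free": fit.n_free,
                     "delta_minus2ll": delta, "delta_df": ddf, "p": p,
                     "aic": fit.aic})
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["aic"].idxmin(), "best"] = True
    return table
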