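"""Parameter-recovery studies on replicate synthetic cohorts.

Each study simulates cohorts with the study-like design (759 same-sex pairs
in four zygosity-by-sex groups, ~16% single responders) from a generating
truth anchored to the published multivariate AE solutions, fits the AE
Cholesky model by FIML, and averages the recovered standardized quantities
across replicates.  Used both by the acceptance script and by the test
suite's recovery checks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cholesky import CholeskyModelSpec, CholeskyTwinModel
from .simulate import generate_cohort
from .truth import (FIVE_FACET_TARGETS, TRIVARIATE_TARGETS, CohortDesign,
                    five_facet_truth, study_design, trivariate_truth)

_TRUTHS = {"trivariate": (trivariate_truth, TRIVARIATE_TARGETS),
           "five_facet": (five_facet_truth, FIVE_FACET_TARGETS)}


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def fit_replicates(truth, design, spec, n_replicates, seed, n_restarts=2):
    """Simulate ``n_replicates`` cohorts and fit ``spec`` to each."""
    fits = []
    for child in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(truth, replace(design, seed=child))
        model = CholeskyTwinModel(cohort, spec)
        fits.append(model.fit(n_restarts=n_restarts, seed=child))
    return fits


def recovery_study(which, n_replicates=20, seed=1, design=None, n_restarts=2):
    """Run one recovery study ("trivariate" or "five_facet").

    Returns a dict with per-replicate and mean recovered heritabilities,
    genetic correlations and (for the five-facet study) the target-variable
    variance partition, alongside the generating values.
    """
    make_truth, targets = _TRUTHS[which]
    truth = make_truth()
    if design is None:
        design = study_design()
    spec = CholeskyModelSpec(truth.variables, ("A", "E"), "equal_across_sex")
    fits = fit_replicates(truth, design, spec, n_replicates, seed,
                          n_restarts=n_restarts)
    h2 = {v: [] for v in truth.variables}
    rg = []
    shares = []
    for fit in fits:
        comp = fit.standardized_components()
        for v in truth.variables:
            h2[v].append(float(comp.loc[v, "a2"]))
        rg.append(fit.component_correlations("A"))
        shares.append(fit.partition_target_variance())
    out = {
        "which": which,
        "n_replicates": n_replicates,
        "n_pairs": design.total_pairs,
        "generating": targets,
        "h2_mean": {v: float(np.mean(h2[v])) for v in truth.variables},
        "h2_replicates": {v: h2[v] for v in truth.variables},
        "converged": [f.converged for f in fits],
    }
    if which == "trivariate":
        vals = [float(m.loc["N", "LS"]) for m in rg]
        out["rg_N_LS_mean"] = float(np.mean(vals))
        out["rg_N_LS_replicates"] = vals
    else:
        keys = shares[0].keys()
        out["ls_shares_mean"] = {k: float(np.mean([s[k] for s in shares]))
                                 for k in keys}
    return out
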