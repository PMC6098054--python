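"""One-command orchestration of the full analysis chain.

simulate (or load) a twin cohort -> descriptives -> pair-robust regression
with facet selection -> biometric model ladder (six sex-limitation/component
variants per variable block) -> variance decomposition, with CSV reports and
a machine-readable run manifest.  A single YAML config drives everything;
all randomness flows from one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cholesky import (CholeskyModelSpec, CholeskyTwinModel, ConvergenceError,
                       compare_models)
from .decompose import correlation_panel, decompose
from .descriptives import (descriptives_table, falconer_heritability,
                           twin_cotwin_correlations)
from .regression import pair_robust_regression, select_facets, selection_report
from .simulate import generate_cohort, read_cohort_csv, to_long
from .truth import (NAMED_TRUTHS, CohortDesign, design_from_yaml,
                    truth_from_yaml)

log = logging.getLogger("twinsat")


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


#: The Table-4-style model ladder: six specs per variable block.
DEFAULT_LADDER = (
    ("common_sex_limitation", ("A", "C", "E")),
    ("common_sex_limitation", ("A", "E")),
    ("scalar_sex_limitation", ("A", "C", "E")),
    ("scalar_sex_limitation", ("A", "E")),
    ("equal_across_sex", ("A", "C", "E")),
    ("equal_across_sex", ("A", "E")),
)


@dataclass
class BlockConfig:
    name: str
    variables: tuple
    target: str = None          # defaults to last variable
    ladder: tuple = DEFAULT_LADDER
    alpha: float = None         # target-scale reliability for error adjustment


@dataclass
class PipelineConfig:
    seed: int = 0
    truth: object = "study"           # named truth, GeneratingTruth, or None
    design: CohortDesign = field(default_factory=CohortDesign)
    cohort_csv: str = None            # load instead of simulating
    variables: tuple = None           # defaults to truth variables
    outcome: str = "LS"
    facet_predictors: tuple = None    # defaults to all non-outcome variables
    covariates: tuple = ()
    beta_threshold: float = 0.10
    p_threshold: float = 0.01
    p_column: str = "p_fdr"
    blocks: tuple = None              # None -> selection-driven block
    ci_level: float = 0.95
    n_restarts: int = 5
    maxiter: int = 2000
    out_dir: str = "twinsat_out"

    @classmethod
    def from_yaml(cls, source):
        try:
            if hasattr(source, "read"):
                doc = yaml.safe_load(source)
            else:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc):
        doc = dict(doc)
        if "design" in doc and isinstance(doc["design"], dict):
            dd = dict(doc["design"])
            if "age_range" in dd:
                dd["age_range"] = tuple(dd["age_range"])
            doc["design"] = CohortDesign(**dd)
        if "blocks" in doc and doc["blocks"] is not None:
            blocks = []
            for b in doc["blocks"]:
                b = dict(b)
                b["variables"] = tuple(b["variables"])
                if "ladder" in b:
                    b["ladder"] = tuple((m, tuple(c)) for m, c in b["ladder"])
                blocks.append(BlockConfig(**b))
            doc["blocks"] = tuple(blocks)
        if isinstance(doc.get("truth"), dict):
            doc["truth"] = truth_from_yaml(
                yaml.safe_dump(doc["truth"]))
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**doc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def resolve_truth(self):
        if self.truth is None:
            return None
        if isinstance(self.truth, str):
            if self.truth not in NAMED_TRUTHS:
                raise ConfigError(f"unknown named truth {self.truth!r}; "
                                  f"choose from {sorted(NAMED_TRUTHS)}")
            return NAMED_TRUTHS[self.truth]()
        return self.truth

    def config_hash(self):
        doc = {k: repr(getattr(self, k)) for k in self.__dataclass_fields__}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()


def _csv(df, out_dir, name, index=True):
    path = Path(out_dir) / name
    df.to_csv(path, index=index, float_format="%.10g")
    return str(path)


def _validate_report(comparison, shares_list):
    """Post-hoc arithmetic validation of the emitted tables."""
    aic = comparison["minus2ll"] - 2.0 * comparison["df"]
    if not np.allclose(aic, comparison["aic"], atol=1e-8):
        raise StageError("validate", ValueError("AIC identity violated"))
    for shares in shares_list:
        if abs(sum(shares.values()) - 1.0) > 1e-6:
            raise StageError("validate",
                             ValueError("target shares do not sum to 1"))


def run_pipeline(config, stages=("simulate", "describe", "regress", "fit",
                                 "decompose")):
    """Run the configured stages; returns a dict of artifacts and paths.

    Deterministic given config and seed.  Any stage failure raises a
    :class:`StageError` naming the stage; artifacts produced by earlier
    stages remain on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = {"paths": {}}
    manifest = {
        "package": "twinsat", "version": __version__,
        "seed": config.seed, "config_sha256": config.config_hash(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "stages": [],
    }

    truth = None
    variables = config.variables

    # -- data --------------------------------------------------------------
    stage = "simulate"
    try:
        if config.cohort_csv is not None:
            cohort = read_cohort_csv(config.cohort_csv, variables)
            if variables is None:
                raise ConfigError("variables must be listed when loading a "
                                  "cohort CSV")
            log.info("loaded cohort from %s (%d pairs)", config.cohort_csv,
                     len(cohort))
        else:
            truth = config.resolve_truth()
            if truth is None:
                raise ConfigError("either cohort_csv or a truth is required")
            design = replace(config.design, seed=config.seed)
            cohort = generate_cohort(truth, design)
            if variables is None:
                variables = truth.variables
            log.info("simulated cohort: %d pairs, %d variables",
                     len(cohort), len(variables))
        variables = tuple(variables)
        artifacts["cohort"] = cohort
        artifacts["variables"] = variables
        if "simulate" in stages:
            artifacts["paths"]["cohort"] = _csv(cohort, out_dir, "cohort.csv",
                                                index=False)
        manifest["stages"].append(stage)
    except (ConfigError, DataError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- descriptives ------------------------------------------------------
    if "describe" in stages:
        stage = "describe"
        try:
            desc = descriptives_table(cohort, variables, outcome=config.outcome)
            twin_corr = twin_cotwin_correlations(cohort, variables)
            falc = pd.DataFrame({
                "falconer_h2": [
                    falconer_heritability(twin_corr.loc[v, "rMZ"],
                                          twin_corr.loc[v, "rDZ"]).value
                    for v in variables]}, index=list(variables))
            artifacts["descriptives"] = desc
            artifacts["twin_correlations"] = twin_corr
            artifacts["paths"]["descriptives"] = _csv(desc, out_dir,
                                                      "descriptives.csv")
            artifacts["paths"]["twin_correlations"] = _csv(
                twin_corr.join(falc), out_dir, "twin_correlations.csv")
            manifest["stages"].append(stage)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # -- regression / selection -------------------------------------------
    selected = None
    if "regress" in stages:
        stage = "regress"
        try:
            predictors = config.facet_predictors
            if predictors is None:
                predictors = tuple(v for v in variables if v != config.outcome)
            long = to_long(cohort, variables)
            reg = pair_robust_regression(
                long, config.outcome, list(predictors),
                covariates=list(config.covariates))
            report = selection_report(reg, config.beta_threshold,
                                      config.p_threshold)
            selected = select_facets(reg, config.beta_threshold,
                                     config.p_threshold, config.p_column)
            log.info("regression R2=%.3f adjR2=%.3f; selected %s",
                     reg.r2, reg.r2_adj, selected)
            artifacts["regression"] = reg
            artifacts["selected"] = selected
            report["r2"] = reg.r2
            report["r2_adj"] = reg.r2_adj
            artifacts["paths"]["regression"] = _csv(report, out_dir,
                                                    "facet_regression.csv")
            (out_dir / "selected_facets.txt").write_text(
                "\n".join(selected) + "\n")
            manifest["stages"].append(stage)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # -- biometric ladder --------------------------------------------------
    best_fits = {}
    if "fit" in stages or "decompose" in stages:
        stage = "fit"
        try:
            blocks = config.blocks
            if blocks is None:
                if selected:
                    bvars = tuple(selected[::-1]) + (config.outcome,)
                else:
                    bvars = variables
                blocks = (BlockConfig(name="main", variables=bvars),)
            comparisons = {}
            for block in blocks:
                fits = []
                for mode, comps in block.ladder:
                    spec = CholeskyModelSpec(block.variables, comps, mode)
                    model = CholeskyTwinModel(cohort, spec)
                    fit = model.fit(n_restarts=config.n_restarts,
                                    maxiter=config.maxiter, seed=config.seed)
                    log.info("block %s: %s -2LL=%.2f df=%d AIC=%.2f",
                             block.name, fit.name, fit.minus2ll, fit.df,
                             fit.aic)
                    fits.append(fit)
                comparison = compare_models(fits)
                comparisons[block.name] = comparison
                best = fits[int(comparison["aic"].idxmin())]
                best_fits[block.name] = best
                if "fit" in stages:
                    artifacts["paths"][f"comparison_{block.name}"] = _csv(
                        comparison, out_dir,
                        f"model_comparison_{block.name}.csv", index=False)
                    artifacts["paths"][f"paths_{block.name}"] = _csv(
                        best.path_table(), out_dir,
                        f"paths_{block.name}.csv", index=False)
            artifacts["comparisons"] = comparisons
            artifacts["best_fits"] = best_fits
            artifacts["blocks"] = blocks
            manifest["stages"].append("fit")
        except ConvergenceError as exc:
            raise StageError(stage, exc) from exc
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # -- decomposition -----------------------------------------------------
    if "decompose" in stages and best_fits:
        stage = "decompose"
        try:
            shares_list = []
            decomps = {}
            for block in artifacts["blocks"]:
                fit = best_fits[block.name]
                dec = decompose(fit, target=block.target, alpha=block.alpha)
                decomps[block.name] = dec
                shares_list.append(dec.target_shares)
                artifacts["paths"][f"components_{block.name}"] = _csv(
                    dec.components, out_dir, f"components_{block.name}.csv")
                artifacts["paths"][f"correlations_{block.name}"] = _csv(
                    correlation_panel(dec), out_dir,
                    f"correlations_{block.name}.csv")
                shares = pd.DataFrame([dec.target_shares])
                shares.insert(0, "target", dec.target)
                if dec.true_unique_env_pct is not None:
                    shares["error_share_pct"] = dec.error_share_pct
                    shares["true_unique_env_pct"] = dec.true_unique_env_pct
                artifacts["paths"][f"decomposition_{block.name}"] = _csv(
                    shares, out_dir, f"decomposition_{block.name}.csv",
                    index=False)
            artifacts["decompositions"] = decomps
            for name, comparison in artifacts["comparisons"].items():
                _validate_report(comparison, shares_list)
            manifest["stages"].append(stage)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    artifacts["paths"]["manifest"] = str(manifest_path)
    artifacts["manifest"] = manifest
    return artifacts
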