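"""End-to-end workflow: describe, fit the four families, select, report.

Mirrors the analysis sequence for clustered death-count data: outcome
summary and category tables first, then marginal ML fits of ZIP, ZINB,
Poisson-hurdle and NB-hurdle with enumeration-area random intercepts,
AIC-based selection, and rate-ratio / odds-ratio reporting for the
selected family.  Everything is written as TSV/JSON with the configuration
echoed for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import descriptives as desc
from . import inference, io
from .models import ModelSpec

log = logging.getLogger("mlcount")


class ConvergenceError(RuntimeError):
    """A model fit failed to converge."""


@dataclass
class ReportBundle:
    config: io.PipelineConfig
    summary: desc.OutcomeSummary
    tables: list
    fits: dict
    comparison: pd.DataFrame | None
    selected: str | None
    effects: pd.DataFrame | None
    variances: pd.DataFrame | None
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(config: io.PipelineConfig, df: pd.DataFrame | None = None,
                 write: bool = True) -> ReportBundle:
    """Run describe -> fit -> select -> report.

    ``df`` may be passed directly (already-validated mother-level frame);
    otherwise ``config.input`` is read.  Failures in a stage are recorded
    and later stages that depend on it are skipped, so a partial bundle is
    always returned.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    if df is None:
        if config.input is None:
            raise io.ConfigError("no input path and no dataframe given")
        df = io.read_dataset(config.input, config)

    covars = list(dict.fromkeys(list(config.count_covariates)
                                + list(config.zero_covariates)))
    cat_covars = [c for c in covars
                  if c in config.categories or df[c].dtype == object]
    summary = desc.summarize_outcome(df[config.outcome_col].to_numpy())
    tables = [desc.association_test(desc.crosstab_from_data(df, v,
                                                            config.outcome_col))
              for v in cat_covars]
    log.info("described %d mothers, %.1f%% zero, mean %.3f, variance %.3f",
             summary.n, summary.percent_zero, summary.mean, summary.variance)

    data = io.make_model_data(df, config)
    fits: dict = {}
    errors: list = []
    warm_from = {"ZINB": "ZIP", "NBH": "PH"}
    for family in config.families:
        spec = ModelSpec(family,
                         count_covariates=tuple(config.count_covariates),
                         zero_covariates=tuple(config.zero_covariates))
        start = None
        src = warm_from.get(family)
        if src in fits:
            p = fits[src].params_hat
            start = inference.ParameterVector(
                p.beta, p.gamma, alpha=0.3,
                sigma2_u=max(p.sigma2_u, 1e-4),
                sigma2_w=max(p.sigma2_w, 1e-4))
        try:
            fr = inference.fit(data, spec, quad_points=config.quad_points,
                               start=start)
            fits[family] = fr
            log.info("%s: loglik %.3f in %d trace points, quad_points=%d, "
                     "converged=%s", family, fr.loglik, len(fr.trace),
                     config.quad_points, fr.converged)
            if not fr.converged:
                errors.append(ConvergenceError(f"{family} did not converge: "
                                               f"{fr.message}"))
        except Exception as e:  # record and continue with other families
            log.error("fit of %s failed: %s", family, e)
            errors.append(e)

    comparison = selected = effects = variances = None
    if fits:
        comparison = inference.model_comparison(list(fits.values()))
        selected = comparison.attrs["selected"]
        best = fits[selected]
        if best.converged:
            effects = inference.effect_frame(best)
            variances = inference.variance_frame(best)

    bundle = ReportBundle(config, summary, tables, fits, comparison, selected,
                          effects, variances, errors)
    if write:
        _write_bundle(bundle)
    return bundle


def _write_bundle(b: ReportBundle) -> None:
    out = Path(b.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(b.config.to_dict(), out / "config.json")
    io.write_json(
        {
            "n_mothers": b.summary.n,
            "n_zero": b.summary.n_zero,
            "percent_zero": b.summary.percent_zero,
            "mean": b.summary.mean,
            "variance": b.summary.variance,
            "histogram": b.summary.histogram,
        },
        out / "outcome_summary.json",
    )
    if b.tables:
        frames = []
        for t in b.tables:
            f = desc.percent_table(t)
            f["chi2"] = t.chi2
            f["df"] = t.df
            f["p_value"] = t.p_value
            frames.append(f)
        io.write_tsv(pd.concat(frames, ignore_index=True),
                     out / "descriptives.tsv")
    if b.comparison is not None:
        io.write_tsv(b.comparison, out / "model_comparison.tsv")
    fitrows = []
    for fam, fr in b.fits.items():
        fitrows.append({"family": fam, "loglik": fr.loglik,
                        "deviance": fr.deviance, "aic": fr.aic, "bic": fr.bic,
                        "k": fr.k, "converged": fr.converged,
                        "grad_norm": fr.grad_norm})
    if fitrows:
        io.write_tsv(pd.DataFrame(fitrows), out / "fits.tsv")
    if b.effects is not None:
        io.write_tsv(b.effects, out / f"effects_{b.selected}.tsv")
    if b.variances is not None:
        io.write_tsv(b.variances, out / f"variances_{b.selected}.tsv")
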