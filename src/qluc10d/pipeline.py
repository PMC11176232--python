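"""End-to-end orchestration: simulate/load -> QC -> fits -> value set.

The pipeline reproduces the full valuation workflow on either simulated
or supplied choice data: quality diagnostics, the unweighted conditional
logit, raking weights and the weighted refit, variance inflation,
monotonicity checking with level merging where needed, delta-method
preference weights, and export of the coefficient table and the 40-row
value set.  All randomness is spawned from one seed, so a config maps to
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import reference
from .design import DCEDesign, generate_design
from .dimensions import AttributeSpec
from .model import ChoiceData, ModelSpec, coefficient_table, fit
from .qc import qc_report
from .simulate import (
    SyntheticCohort,
    TrueModel,
    demographics_to_long,
    simulate_cohort,
)
from .valueset import ValueSet, check_monotonicity, export_valueset, merge_and_refit
from .weights import rake, variance_inflation, write_weights

log = logging.getLogger("qluc10d.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Defaults mirror the study conditions: a 960-set overlap-4 design,
    2,435 respondents answering 16 sets each, choices generated from the
    published unweighted Model 1 coefficients, raking on income,
    education, health status and psychological distress.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    # simulation block (ignored when choices_csv is given)
    n_sets: int = reference.STUDY_N_SETS
    overlap: int = reference.STUDY_OVERLAP
    design_n_iter: int = 300
    n_respondents: int = reference.STUDY_N_COMPLETERS
    per_respondent: int = reference.STUDY_SETS_PER_RESPONDENT
    straightliner_rate: float = 0.0
    time_noise_gamma: Optional[float] = None
    truth: str = "table_unweighted_model1"
    # or load observed data
    choices_csv: Optional[str] = None
    demographics_csv: Optional[str] = None
    design_csv: Optional[str] = None
    # analysis options
    raking_variables: Tuple[str, ...] = reference.RAKING_VARIABLES
    weighted: bool = True
    monotonicity_repair: bool = True
    exclude_straightliners: bool = False
    completers_only: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("choices_csv", "demographics_csv", "design_csv"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return cfg


def _truth(name: str) -> TrueModel:
    if name == "table_unweighted_model1":
        return TrueModel.from_reference()
    if name == "table_weighted_model1":
        return TrueModel.from_reference(weighted=True)
    raise ValueError(f"unknown truth {name!r}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Returns the artifact directory.  Stage failures abort with the stage
    name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_design, s_cohort = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]

    stage = "design"
    try:
        if config.design_csv:
            design = DCEDesign.load(config.design_csv)
            log.info("loaded design with %d sets", len(design))
        else:
            design = generate_design(
                n_sets=config.n_sets,
                overlap=config.overlap,
                n_iter=config.design_n_iter,
                seed=s_design,
            )
            log.info("generated design: %d sets, D-error %.5g (seed %d)",
                     len(design), design.d_error, s_design)
        design.save(out / "design.csv")

        stage = "data"
        if config.choices_csv:
            data = ChoiceData.from_csv(config.choices_csv)
            demographics = (
                pd.read_csv(config.demographics_csv)
                if config.demographics_csv
                else None
            )
            times = None
            log.info("loaded %d choice rows", len(data.df))
        else:
            cohort = simulate_cohort(
                design,
                n_respondents=config.n_respondents,
                per_respondent=config.per_respondent,
                truth=_truth(config.truth),
                straightliner_rate=config.straightliner_rate,
                time_noise_gamma=config.time_noise_gamma,
                seed=s_cohort,
            )
            data, demographics, times = cohort.choices, cohort.demographics, \
                cohort.completion_times
            data.to_csv(out / "choices.csv")
            demographics_to_long(demographics).to_csv(
                out / "demographics.csv", index=False
            )
            times.reset_index().to_csv(out / "completion_times.csv", index=False)
            log.info("simulated cohort: %d respondents x %d sets (seed %d)",
                     config.n_respondents, config.per_respondent, s_cohort)

        stage = "qc"
        report = qc_report(data, completion_times=times)
        qc_json = {
            "n_straightliners": report.n_straightliners,
            "straightliner_ids": list(report.straightliner_ids),
            "sensitivity_max_abs_diff": report.sensitivity.max_abs_diff,
            "sensitivity_mean_diff": report.sensitivity.mean_diff,
        }
        (out / "qc_report.json").write_text(json.dumps(qc_json, indent=2))
        if report.decile_table is not None:
            report.decile_table.to_csv(out / "qc_deciles.csv", index=False)
        log.info("QC: %d straightliners, sensitivity max |diff| %.4g",
                 report.n_straightliners, report.sensitivity.max_abs_diff)
        if config.exclude_straightliners and report.straightliner_ids:
            keep = ~data.df["respondent_id"].isin(report.straightliner_ids)
            data = ChoiceData(data.df.loc[keep].reset_index(drop=True), data.spec)

        stage = "fit unweighted Model 1"
        spec = ModelSpec(design.spec)
        fit_u = fit(data, spec)
        tbl_u = coefficient_table(fit_u)
        log.info("unweighted M1: alpha=%.4f, pseudo-R2=%.4f",
                 fit_u.alpha, fit_u.pseudo_r2)

        fit_w = None
        if config.weighted and demographics is not None:
            stage = "raking"
            sample = demographics[
                ["respondent_id", *config.raking_variables]
            ]
            targets = {
                v: reference.POPULATION_MARGINS[v] for v in config.raking_variables
            }
            raking = rake(sample, targets)
            write_weights(raking, out / "weights.csv")
            log.info("raking: %d iterations, max margin error %.2g",
                     raking.iterations, raking.max_margin_error)

            stage = "fit weighted Model 1"
            fit_w = fit(data, spec, weights=raking.weights)
            infl = variance_inflation(fit_u, fit_w)
            tbl_u["weighted_estimate"] = fit_w.params
            tbl_u["weighted_se"] = fit_w.se("clustered")
            tbl_u["inflation_pct"] = infl.rounded()
            log.info("variance inflation: mean %.0f%%, max %.0f%%",
                     infl.summary["mean"], infl.summary["max"])

        tbl_u.rename_axis("coefficient").to_csv(out / "coefficients_m1.csv")

        stage = "monotonicity"
        violations = check_monotonicity(fit_u)
        (out / "monotonicity.json").write_text(json.dumps(
            [asdict_violation(v) for v in violations], indent=2))
        selected_fit = fit_u
        if violations and config.monotonicity_repair:
            stage = "Model 2 merge"
            mspec2, fit_m2 = merge_and_refit(data, spec, fit=fit_u)
            coefficient_table(fit_m2).rename_axis("coefficient").to_csv(
                out / "coefficients_m2.csv"
            )
            selected_fit = fit_m2
            log.info("Model 2: %d parameters after merging", fit_m2.k)

        stage = "value set"
        vs = ValueSet.from_fit(selected_fit, seed=config.seed,
                               weighting="unweighted")
        export_valueset(vs, out / "valueset.csv")
        worst = vs.utility("4" * len(design.spec.dimensions))
        summary = {
            "alpha": fit_u.alpha,
            "pseudo_r2": fit_u.pseudo_r2,
            "aic": fit_u.aic,
            "bic": fit_u.bic,
            "loglik": fit_u.loglik,
            "n_respondents": fit_u.n_respondents,
            "n_sets": fit_u.n_sets,
            "worst_state_utility": worst,
            "n_monotonicity_violations": len(violations),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("value set written; utility(worst state)=%.4f", worst)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def asdict_violation(v) -> Dict:
    return {
        "dimension": v.dimension,
        "level_low": v.level_low,
        "level_high": v.level_high,
        "coef_low": v.coef_low,
        "coef_high": v.coef_high,
    }
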