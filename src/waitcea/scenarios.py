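"""Sensitivity-analysis grid and the end-to-end analysis driver.

Each named scenario varies one dimension of the main analysis: the
estimator (difference-in-differences, baseline adjustment, single-arm
pre-post), the handling of attrition and item missingness (complete cases,
best/worst-case percentile imputation, multiple imputation), the costing
scope (including privately funded care), the population size (value-of-
information totals only) or the per-user app cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .cea_plane import IncrementalResult, prob_cost_effective, prob_dominant
from .errors import EstimationError
from .effect_estimation import (
    CumulativeEffects,
    EffectEstimates,
    aggregate_auc,
    apply_attrition_scenario,
    build_outcome_matrix,
    chain_waitlist_effects,
    estimate_ancova,
    estimate_did,
    estimate_prepost,
    fit_joint_cell_means,
    impute_pmm,
    incremental_summary,
)
from .trial_data import AnalysisConfig, CostingTables
from .value_of_information import PopulationModel, voi_result


@dataclass(frozen=True)
class ScenarioDef:
    estimator: str = "main"  # main | did | ancova | prepost
    attrition: str | None = None  # best | worst | complete_case
    multiple_imputation: bool = False
    scope: str = "public"  # public | all
    app_cost: float | None = None
    users_per_year: float | None = None


SCENARIOS: dict[str, ScenarioDef] = {
    "main": ScenarioDef(),
    "did": ScenarioDef(estimator="did"),
    "ancova": ScenarioDef(estimator="ancova"),
    "prepost": ScenarioDef(estimator="prepost"),
    "complete_cases": ScenarioDef(attrition="complete_case"),
    "attrition_negative": ScenarioDef(attrition="worst"),
    "attrition_positive": ScenarioDef(attrition="best"),
    "multiple_imputation": ScenarioDef(multiple_imputation=True),
    "include_private": ScenarioDef(scope="all"),
    "more_users": ScenarioDef(users_per_year=3586.0),
    "higher_app_cost": ScenarioDef(app_cost=111.0),
}


@dataclass
class ScenarioResult:
    name: str
    inc: IncrementalResult
    prob_ce: float
    prob_dominant: float
    evpi_total: float
    joint_p: float | None = None

    def row(self) -> dict:
        lo_e, hi_e = self.inc.ci_e()
        lo_c, hi_c = self.inc.ci_c()
        return {
            "scenario": self.name,
            "delta_e": self.inc.mean_e,
            "delta_e_lo": lo_e,
            "delta_e_hi": hi_e,
            "delta_c": self.inc.mean_c,
            "delta_c_lo": lo_c,
            "delta_c_hi": hi_c,
            "prob_ce": self.prob_ce,
            "prob_dominant": self.prob_dominant,
            "evpi_total": self.evpi_total,
        }


def analyze(
    trial: pd.DataFrame,
    drugs: pd.DataFrame,
    tables: CostingTables,
    config: AnalysisConfig,
    estimator: str = "main",
    attrition: str | None = None,
    multiple_imputation: bool = False,
    scope: str = "public",
) -> tuple[EffectEstimates, CumulativeEffects, IncrementalResult]:
    """Run outcome assembly -> estimation -> AUC -> incremental summary."""
    om = build_outcome_matrix(trial, drugs, tables)
    if attrition is not None:
        om = apply_attrition_scenario(om, attrition)
    if multiple_imputation:
        _, est = impute_pmm(om, seed=config.seed)
    elif estimator == "main":
        est = chain_waitlist_effects(fit_joint_cell_means(om))
    elif estimator == "did":
        est = estimate_did(om)
    elif estimator == "ancova":
        est = estimate_ancova(om)
    elif estimator == "prepost":
        est = estimate_prepost(om)
    else:
        raise EstimationError(f"unknown estimator {estimator!r}")
    cum = aggregate_auc(est, config)
    inc = incremental_summary(cum, tables, config, scope=scope)
    return est, cum, inc


def run_scenario(
    name: str,
    trial: pd.DataFrame,
    drugs: pd.DataFrame,
    tables: CostingTables,
    config: AnalysisConfig,
) -> ScenarioResult:
    """Dispatch one named sensitivity scenario."""
    if name not in SCENARIOS:
        raise EstimationError(
            f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}"
        )
    sdef = SCENARIOS[name]
    cfg = config
    if sdef.app_cost is not None:
        cfg = dataclasses.replace(cfg, app_cost_per_user=sdef.app_cost)
    if sdef.users_per_year is not None:
        cfg = dataclasses.replace(cfg, users_per_year=sdef.users_per_year)
    _, cum, inc = analyze(
        trial, drugs, tables, cfg,
        estimator=sdef.estimator,
        attrition=sdef.attrition,
        multiple_imputation=sdef.multiple_imputation,
        scope=sdef.scope,
    )
    pop = PopulationModel(
        users_per_year=cfg.users_per_year,
        horizon_years=cfg.horizon_years,
        discount_rate=cfg.discount_rate,
        timing=cfg.user_timing,
    )
    voi = voi_result(inc, cfg.lambda_base, pop)
    return ScenarioResult(
        name=name,
        inc=inc,
        prob_ce=prob_cost_effective(inc, cfg.lambda_base),
        prob_dominant=prob_dominant(inc),
        evpi_total=voi.evpi_total,
    )


def run_all_scenarios(
    trial: pd.DataFrame,
    drugs: pd.DataFrame,
    tables: CostingTables,
    config: AnalysisConfig,
    names: list[str] | None = None,
) -> list[ScenarioResult]:
    return [
        run_scenario(name, trial, drugs, tables, config)
        for name in (names or list(SCENARIOS))
    ]


def collate(results: list[ScenarioResult]) -> pd.DataFrame:
    """One row per scenario: point estimates, CIs and CE probabilities."""
    return pd.DataFrame([r.row() for r in results])
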