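"""Joint cell-means fit, waitlist chaining, AUC aggregation and the
sensitivity estimators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import waitcea as w
from waitcea.effect_estimation import (
    CELLS,
    HORIZONS,
    OUTCOMES,
    _stacked_cluster_ols,
)
from waitcea.errors import EstimationError
from waitcea.trial_data import ITEMS


def _om_from_values(values_by_arm_wave, n_per_cell=2, jitter=None):
    """Outcome matrix with exact cell means for hrqol; all other outcomes 0.

    values_by_arm_wave: {(arm, wave): mean}. With jitter=eps the two records
    per cell are mean +/- eps, preserving the mean exactly.
    """
    rows = []
    pid = 0
    for arm in ("intervention", "waitlist"):
        for p in range(n_per_cell):
            pid += 1
            for wave in (0, 3, 6, 9):
                mean = values_by_arm_wave[(arm, wave)]
                off = (jitter or 0.0) * (1 if p % 2 == 0 else -1)
                row = {
                    "participant_id": f"S{pid:03d}",
                    "arm": arm,
                    "wave": wave,
                    "responded": True,
                    "hrqol": mean + off,
                }
                row.update({f"item_{i}": 0.0 for i in ITEMS})
                row.update({"drug_related": 0.0, "drug_unrelated": 0.0})
                rows.append(row)
    return pd.DataFrame(rows)


def test_cell_means_equal_sample_means():
    vals = {("intervention", 0): 0.5, ("intervention", 3): 0.6,
            ("intervention", 6): 0.62, ("intervention", 9): 0.63,
            ("waitlist", 0): 0.5, ("waitlist", 3): 0.55,
            ("waitlist", 6): 0.6, ("waitlist", 9): 0.62}
    om = _om_from_values(vals, jitter=0.01)
    est = w.fit_joint_cell_means(om)
    for (arm, wave), mean in vals.items():
        assert est.cell_means.loc["hrqol", (arm, wave)] == pytest.approx(mean)


def test_singleton_clusters_reduce_to_classic_se():
    """With one record per cluster, the cluster sandwich for a cell mean is
    exactly s^2/n (ddof=1), the classic standard error of a mean."""
    rng = np.random.default_rng(0)
    y = rng.normal(0.0, 1.0, 40)
    X = np.ones((40, 1))
    beta, vcov = _stacked_cluster_ols([(y, X, np.arange(40))], 40)
    assert beta[0] == pytest.approx(y.mean())
    assert vcov[0, 0] == pytest.approx(y.var(ddof=1) / 40)


def test_cross_outcome_covariance_exact_for_singletons():
    """Two outcomes sharing noise: the cross-outcome block of the sandwich
    equals the sample covariance over n for independent observations."""
    rng = np.random.default_rng(1)
    z = rng.normal(0, 1, 60)
    y1, y2 = z, z + rng.normal(0, 0.5, 60)
    X = np.ones((60, 1))
    _, vcov = _stacked_cluster_ols(
        [(y1, X, np.arange(60)), (y2, X, np.arange(60))], 60
    )
    expected = np.cov(y1, y2, ddof=1)[0, 1] / 60
    assert vcov[0, 1] == pytest.approx(expected)


def test_cluster_sandwich_matches_statsmodels():
    """Single-outcome cell-means fit agrees with the statsmodels
    cluster-robust OLS sandwich (same small-sample convention)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    n_part, waves = 30, 4
    cl = np.repeat(np.arange(n_part), waves)
    cell = np.tile(np.arange(waves), n_part)
    re = np.repeat(rng.normal(0, 1, n_part), waves)
    y = 0.5 * cell + re + rng.normal(0, 1, n_part * waves)
    X = np.zeros((len(y), waves))
    X[np.arange(len(y)), cell] = 1.0
    beta, vcov = _stacked_cluster_ols([(y, X, cl)], n_part)
    fit = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": cl, "use_correction": True},
        use_t=False,
    )
    np.testing.assert_allclose(beta, fit.params, rtol=1e-10)
    # statsmodels applies an extra (N-1)/(N-K) to G/(G-1)
    extra = (len(y) - 1) / (len(y) - waves)
    np.testing.assert_allclose(vcov * extra, fit.cov_params(), rtol=1e-8)


def test_chaining_arithmetic_example():
    vals = {("intervention", 0): 0.5, ("intervention", 3): 0.60,
            ("intervention", 6): 0.62, ("intervention", 9): 0.63,
            ("waitlist", 0): 0.5, ("waitlist", 3): 0.55,
            ("waitlist", 6): 0.60, ("waitlist", 9): 0.62}
    est = w.chain_waitlist_effects(w.fit_joint_cell_means(_om_from_values(vals)))
    d = est.delta.loc["hrqol"]
    assert d[3] == pytest.approx(0.05)
    assert d[6] == pytest.approx(0.07)  # 0.62 - (0.60 - 0.05)
    assert d[9] == pytest.approx(0.08)  # 0.63 - (0.62 - 0.07)


def test_chaining_null_case():
    vals = {(arm, wave): 0.6 for arm in ("intervention", "waitlist")
            for wave in (0, 3, 6, 9)}
    est = w.chain_waitlist_effects(w.fit_joint_cell_means(_om_from_values(vals, jitter=0.01)))
    np.testing.assert_allclose(est.delta.loc["hrqol"].to_numpy(), 0.0, atol=1e-12)


def test_noiseless_constant_effect_recovered_exactly():
    """A constant effect switched on at exposure chains to d3=d6=d9=d with
    zero error when the generator is noiseless."""
    d = 0.04
    spec = w.SimulationSpec(
        seed=11, hrqol_between_sd=0.0, hrqol_within_sd=0.0,
        retention=(179, 179, 179, 179), complete_case_target=179,
        item_missing_rate=0.0,
        treatment_effect_hrqol={3: d, 6: d, 9: d},
    )
    trial, drugs = w.simulate_frames(spec)
    tables = w.default_costing_tables()
    om = w.build_outcome_matrix(trial, drugs, tables)
    est = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    np.testing.assert_allclose(est.delta.loc["hrqol"].to_numpy(), d, atol=1e-12)


def test_empty_cell_raises_named_error():
    vals = {(arm, wave): 0.6 for arm in ("intervention", "waitlist")
            for wave in (0, 3, 6, 9)}
    om = _om_from_values(vals)
    om.loc[(om["arm"] == "waitlist") & (om["wave"] == 6), "hrqol"] = np.nan
    with pytest.raises(EstimationError, match="waitlist.*wave=6"):
        w.fit_joint_cell_means(om)


# ---------------------------------------------------------------------------
# AUC aggregation
# ---------------------------------------------------------------------------


def _estimates_with_delta(delta_by_outcome):
    n = len(OUTCOMES)
    delta = pd.DataFrame(0.0, index=list(OUTCOMES), columns=list(HORIZONS))
    for outcome, values in delta_by_outcome.items():
        delta.loc[outcome] = values
    return w.EffectEstimates(
        outcomes=OUTCOMES, cell_means=None, vcov_cells=None, n_clusters=100,
        delta=delta, vcov_delta=np.eye(3 * n),
    )


def test_qaly_auc_closed_form_no_discount():
    d = 0.0104
    est = _estimates_with_delta({"hrqol": [d, d, d]})
    cum = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    assert cum.auc["hrqol"] == pytest.approx(0.625 * d)
    assert cum.auc["hrqol"] == pytest.approx(0.0065, rel=1e-4)


def test_recall_window_auc_closed_forms():
    est = _estimates_with_delta({"item_1": [2.0, 2.0, 2.0],  # 1mo recall
                                 "item_7": [2.0, 2.0, 2.0]})  # 3mo recall
    cum = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    assert cum.auc["item_1"] == pytest.approx(18.0)  # 3 quarters x 3 x delta
    assert cum.auc["item_7"] == pytest.approx(6.0)  # sum of per-wave deltas


def test_discounting_against_independent_factors():
    est = _estimates_with_delta({"drug_related": [300.0, 300.0, 300.0]})
    cum0 = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    cum3 = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.03))
    assert cum0.auc["drug_related"] == pytest.approx(900.0)
    factors = [(1.03) ** (-m / 12.0) for m in (3, 6, 9)]
    assert cum3.auc["drug_related"] == pytest.approx(300.0 * sum(factors))
    assert cum3.auc["drug_related"] < 900.0


def test_all_zero_deltas_give_zero_auc(config):
    est = _estimates_with_delta({})
    cum = w.aggregate_auc(est, config)
    assert (cum.auc == 0).all()


def test_incremental_summary_app_cost_floor(tables):
    est = _estimates_with_delta({})
    cum = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    inc = w.incremental_summary(cum, tables, w.AnalysisConfig(app_cost_per_user=12.0))
    assert inc.mean_e == 0.0
    assert inc.mean_c == pytest.approx(12.0)


def test_incremental_summary_arithmetic(tables):
    # one public item with cumulative effect -2 at its unit cost, plus app cost
    est = _estimates_with_delta({"item_9": [-2.0 / 3.0] * 3})
    cum = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    inc = w.incremental_summary(cum, tables, w.AnalysisConfig(app_cost_per_user=12.0))
    assert inc.mean_c == pytest.approx(-2.0 * tables.unit_costs[9].sek_per_unit + 12.0)


def test_private_items_excluded_from_public_scope(tables):
    est = _estimates_with_delta({"item_3": [1.0, 1.0, 1.0]})
    cum = w.aggregate_auc(est, w.AnalysisConfig(discount_rate=0.0))
    pub = w.incremental_summary(cum, tables, w.AnalysisConfig(), scope="public")
    allc = w.incremental_summary(cum, tables, w.AnalysisConfig(), scope="all")
    assert pub.mean_c == pytest.approx(12.0)
    assert allc.mean_c > pub.mean_c


# ---------------------------------------------------------------------------
# Joint test
# ---------------------------------------------------------------------------


def test_joint_test_trivial_cases(config, tables):
    est = _estimates_with_delta({})
    cum = w.aggregate_auc(est, config)
    assert w.joint_null_test(cum).pvalue == pytest.approx(1.0)
    est = _estimates_with_delta({"hrqol": [50.0, 50.0, 50.0]})
    cum = w.aggregate_auc(est, config)
    assert w.joint_null_test(cum).pvalue < 1e-6


# ---------------------------------------------------------------------------
# Alternative estimators
# ---------------------------------------------------------------------------


def _noiseless_biased_om(b, d):
    vals = {("intervention", 0): 0.5 + b, ("intervention", 3): 0.5 + b + d,
            ("intervention", 6): 0.5 + b + d, ("intervention", 9): 0.5 + b + d,
            ("waitlist", 0): 0.5, ("waitlist", 3): 0.5,
            ("waitlist", 6): 0.5 + d, ("waitlist", 9): 0.5 + d}
    return _om_from_values(vals)


def test_did_removes_baseline_imbalance():
    b, d = 0.07, 0.02
    om = _noiseless_biased_om(b, d)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    did = w.estimate_did(om)
    assert plain.delta.loc["hrqol", 3] == pytest.approx(b + d)
    np.testing.assert_allclose(did.delta.loc["hrqol"].to_numpy(), d, atol=1e-12)


def test_did_matches_plain_when_baselines_balanced():
    om = _noiseless_biased_om(0.0, 0.02)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    did = w.estimate_did(om)
    pd.testing.assert_frame_equal(plain.delta, did.delta)


def test_prepost_arithmetic():
    vals = {("intervention", 0): 0.55, ("intervention", 3): 0.58,
            ("intervention", 6): 0.58, ("intervention", 9): 0.59,
            ("waitlist", 0): 0.55, ("waitlist", 3): 0.55,
            ("waitlist", 6): 0.55, ("waitlist", 9): 0.55}
    est = w.estimate_prepost(_om_from_values(vals))
    assert est.single_arm
    d = est.delta.loc["hrqol"]
    assert d[3] == pytest.approx(0.03)
    assert d[6] == pytest.approx(0.03)
    assert d[9] == pytest.approx(0.04)


def test_prepost_zero_for_unchanged_outcomes():
    vals = {(arm, wave): 0.6 for arm in ("intervention", "waitlist")
            for wave in (0, 3, 6, 9)}
    est = w.estimate_prepost(_om_from_values(vals, jitter=0.01))
    np.testing.assert_allclose(est.delta.loc["hrqol"].to_numpy(), 0.0, atol=1e-12)


def test_prepost_equals_plain_when_constructed_comparator_flat():
    """When the chained comparator means all sit at the baseline level (the
    waitlist arm tracks the intervention's effect trajectory exactly), the
    pre-post and chained estimators coincide."""
    om = _noiseless_biased_om(0.0, 0.03)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    pre = w.estimate_prepost(om)
    np.testing.assert_allclose(
        pre.delta.loc["hrqol"].to_numpy(), plain.delta.loc["hrqol"].to_numpy(),
        atol=1e-12,
    )


def test_ancova_with_balanced_linear_baselines_matches_plain():
    rows = []
    d = 0.02
    pid = 0
    for arm in ("intervention", "waitlist"):
        for y0 in (0.45, 0.55):
            pid += 1
            for wave in (0, 3, 6, 9):
                exposed = wave >= 3 if arm == "intervention" else wave >= 6
                val = y0 + (d if exposed else 0.0)
                row = {"participant_id": f"A{pid}", "arm": arm, "wave": wave,
                       "responded": True, "hrqol": val if wave else y0}
                row.update({f"item_{i}": 0.0 for i in ITEMS})
                row.update({"drug_related": 0.0, "drug_unrelated": 0.0})
                rows.append(row)
    om = pd.DataFrame(rows)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    anc = w.estimate_ancova(om)
    np.testing.assert_allclose(
        anc.delta.loc["hrqol"].to_numpy(), plain.delta.loc["hrqol"].to_numpy(),
        atol=1e-10,
    )
    np.testing.assert_allclose(anc.delta.loc["hrqol"].to_numpy(), d, atol=1e-10)


def test_ancova_shrinks_se_under_baseline_dependence(tables, config):
    """With strongly baseline-dependent outcomes, adjustment gives a
    strictly smaller standard error for the 3-month HRQoL effect."""
    spec = w.SimulationSpec(seed=12, hrqol_between_sd=0.09, hrqol_within_sd=0.02,
                            item_missing_rate=0.0)
    trial, drugs = w.simulate_frames(spec)
    om = w.build_outcome_matrix(trial, drugs, tables)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    anc = w.estimate_ancova(om)
    i = list(OUTCOMES).index("hrqol") * 3
    assert np.sqrt(anc.vcov_delta[i, i]) < np.sqrt(plain.vcov_delta[i, i])


def test_chained_matches_itt_with_unexposed_control(tables, config):
    """The chained 6/9-month effects from the waitlist design agree in
    expectation with direct ITT contrasts from a parallel design whose
    control arm is never exposed (both target the same estimand)."""
    d = 0.03
    kwargs = dict(
        n_intervention=4000, n_waitlist=4000,
        retention=(8000, 8000, 8000, 8000), complete_case_target=8000,
        item_missing_rate=0.0, treatment_effect_hrqol={3: d, 6: d, 9: d},
    )
    trial_w, drugs_w = w.simulate_frames(w.SimulationSpec(seed=13, **kwargs))
    om = w.build_outcome_matrix(trial_w, drugs_w, tables)
    est = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    trial_c, _ = w.simulate_frames(
        w.SimulationSpec(seed=14, waitlist_exposed=False, **kwargs)
    )
    means = trial_c.groupby(["arm", "wave"])["hrqol"].mean()
    for h in (6, 9):
        itt = means["intervention", h] - means["waitlist", h]
        assert est.delta.loc["hrqol", h] == pytest.approx(itt, abs=0.01)
        assert est.delta.loc["hrqol", h] == pytest.approx(d, abs=0.01)


# ---------------------------------------------------------------------------
# Attrition and multiple imputation
# ---------------------------------------------------------------------------


def test_attrition_scenario_identity_on_fully_observed():
    vals = {(arm, wave): 0.6 for arm in ("intervention", "waitlist")
            for wave in (0, 3, 6, 9)}
    om = _om_from_values(vals, jitter=0.01)
    for scenario in ("best", "worst"):
        pd.testing.assert_frame_equal(w.apply_attrition_scenario(om, scenario), om)


def test_worst_case_uses_pooled_percentiles(sim_default, tables):
    trial, drugs = sim_default
    om = w.build_outcome_matrix(trial, drugs, tables)
    worst = w.apply_attrition_scenario(om, "worst")
    assert not worst[list(OUTCOMES)].isna().any().any()
    hr = om["hrqol"].dropna()
    p5 = np.percentile(hr, 5)
    filled = worst.loc[om["hrqol"].isna(), "hrqol"]
    np.testing.assert_allclose(filled, p5)
    item = om["item_13"].dropna()
    p95 = np.percentile(item, 95)
    filled13 = worst.loc[om["item_13"].isna(), "item_13"]
    np.testing.assert_allclose(filled13, p95)


def test_best_case_reverses_percentiles(sim_default, tables):
    trial, drugs = sim_default
    om = w.build_outcome_matrix(trial, drugs, tables)
    best = w.apply_attrition_scenario(om, "best")
    hr = om["hrqol"].dropna()
    filled = best.loc[om["hrqol"].isna(), "hrqol"]
    np.testing.assert_allclose(filled, np.percentile(hr, 95))


def test_complete_case_keeps_104_of_179(sim_default, tables):
    trial, drugs = sim_default
    om = w.build_outcome_matrix(trial, drugs, tables)
    cc = w.apply_attrition_scenario(om, "complete_case")
    assert cc["participant_id"].nunique() == 104


def test_pmm_no_missing_is_identity():
    vals = {("intervention", 0): 0.5, ("intervention", 3): 0.6,
            ("intervention", 6): 0.62, ("intervention", 9): 0.63,
            ("waitlist", 0): 0.5, ("waitlist", 3): 0.55,
            ("waitlist", 6): 0.6, ("waitlist", 9): 0.62}
    om = _om_from_values(vals, jitter=0.01, n_per_cell=4)
    completed, pooled = w.impute_pmm(om, m=3, seed=0)
    plain = w.chain_waitlist_effects(w.fit_joint_cell_means(om))
    for comp in completed:
        pd.testing.assert_frame_equal(
            comp[list(OUTCOMES)], om[list(OUTCOMES)], check_dtype=False
        )
    np.testing.assert_allclose(
        pooled.delta_vector(), plain.delta_vector(), atol=1e-12
    )


def test_pmm_imputes_from_observed_support(sim_default, tables):
    trial, drugs = sim_default
    om = w.build_outcome_matrix(trial, drugs, tables)
    completed, _ = w.impute_pmm(om, m=2, seed=3)
    for outcome in ("hrqol", "item_1", "drug_related"):
        observed = set(om[outcome].dropna())
        was_missing = om[outcome].isna()
        for comp in completed:
            imputed = set(comp.loc[was_missing, outcome])
            assert imputed <= observed
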