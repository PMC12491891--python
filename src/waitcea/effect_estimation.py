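"""Treatment-effect estimation for the waitlist design.

Sixteen outcomes are analyzed per participant-wave: the HRQoL index, the 13
TiC-P use counts and the two drug-cost classes.  Each outcome is regressed
on saturated arm-by-wave indicators (a cell-means model), all equations
estimated as one stacked system so the joint covariance of every
coefficient — across outcomes as well as cells — is available from a single
participant-clustered sandwich.

Identification beyond the randomized horizon uses the waitlist chaining
rule.  With E(m)/W(m) the intervention/waitlist means at follow-up month m
(the waitlist arm is exposed from month 3):

    d3 = E(3) - W(3)
    d6 = E(6) - [W(6) - d3]        (waitlist at month 6 is 3 months exposed)
    d9 = E(9) - [W(9) - d6]

The chained effects are exactly linear in the cell means, so covariance
propagation is exact.  Cumulative 9-month effects are discounted
area-under-the-curve aggregates: a trapezoid anchored at zero effect at
randomization for HRQoL (QALYs), the sum of per-wave effects for
3-month-recall outcomes (each wave covers its preceding quarter) and three
times the per-wave effects for 1-month-recall outcomes (the reported month
proxies its quarter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cea_plane import IncrementalResult
from .errors import EstimationError, ValidationError
from .trial_data import (
    ARMS,
    ITEM_COLUMNS,
    ITEMS,
    RECALL_1MO_ITEMS,
    WAVES,
    AnalysisConfig,
    CostingTables,
)
from .costing import impute_items_frame

logger = logging.getLogger(__name__)

HORIZONS = (3, 6, 9)
OUTCOMES: tuple[str, ...] = ("hrqol",) + ITEM_COLUMNS + ("drug_related", "drug_unrelated")
CELLS: tuple[tuple[str, int], ...] = tuple((arm, w) for arm in ARMS for w in WAVES)

#: AUC aggregation family per outcome
RECALL: dict[str, str] = {"hrqol": "qaly"}
RECALL.update({f"item_{i}": ("1mo" if i in RECALL_1MO_ITEMS else "3mo") for i in ITEMS})
RECALL.update({"drug_related": "3mo", "drug_unrelated": "3mo"})


# ---------------------------------------------------------------------------
# Outcome matrix
# ---------------------------------------------------------------------------


def build_outcome_matrix(
    trial: pd.DataFrame,
    drugs: pd.DataFrame,
    tables: CostingTables,
    impute: bool = True,
) -> pd.DataFrame:
    """Assemble the per-(participant, wave) analysis outcomes.

    Applies item-level LOCF/NOCB imputation, prices drug entries into the
    related/unrelated SEK columns, and leaves every outcome absent in
    non-responded waves.
    """
    om = impute_items_frame(trial) if impute else trial.copy()
    om = om.sort_values(["participant_id", "wave"], kind="stable", ignore_index=True)

    drug_cost = pd.DataFrame(
        0.0,
        index=pd.MultiIndex.from_frame(om[["participant_id", "wave"]]),
        columns=["drug_related", "drug_unrelated"],
    )
    if drugs is not None and len(drugs):
        unknown = sorted(set(drugs["drug_code"]) - set(tables.drug_prices))
        if unknown:
            raise ValidationError(f"no price for drug codes {unknown}")
        priced = drugs.copy()
        priced["cost"] = [
            u * tables.drug_prices[c].sek_per_unit
            for c, u in zip(priced["drug_code"], priced["units"])
        ]
        priced["drug_class"] = [
            tables.drug_prices[c].drug_class for c in priced["drug_code"]
        ]
        sums = priced.pivot_table(
            index=["participant_id", "wave"],
            columns="drug_class",
            values="cost",
            aggfunc="sum",
            fill_value=0.0,
        )
        for cls in ("related", "unrelated"):
            if cls in sums.columns:
                drug_cost.loc[sums.index, f"drug_{cls}"] = sums[cls].to_numpy()
    om["drug_related"] = drug_cost["drug_related"].to_numpy()
    om["drug_unrelated"] = drug_cost["drug_unrelated"].to_numpy()
    resp = om["responded"].astype(bool)
    om.loc[~resp, ["drug_related", "drug_unrelated"]] = np.nan
    return om[["participant_id", "arm", "wave", "responded", *OUTCOMES]]


# ---------------------------------------------------------------------------
# Stacked cluster-robust least squares
# ---------------------------------------------------------------------------


def _stacked_cluster_ols(
    equations: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_clusters: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit each (y, X, cluster-code) equation by OLS and return the stacked
    coefficient vector with its joint cluster-robust (CR1) covariance.

    Cross-equation covariance comes from summing each cluster's score
    contributions across equations before taking the outer product.
    """
    betas, influences = [], []
    for y, X, cl in equations:
        XtX = X.T @ X
        bread = np.linalg.pinv(XtX)
        beta = bread @ (X.T @ y)
        u = y - X @ beta
        scores = np.zeros((n_clusters, X.shape[1]))
        np.add.at(scores, cl, X * u[:, None])
        betas.append(beta)
        influences.append(scores @ bread.T)
    beta = np.concatenate(betas)
    infl = np.hstack(influences)
    correction = n_clusters / (n_clusters - 1) if n_clusters > 1 else 1.0
    vcov = correction * (infl.T @ infl)
    return beta, vcov


@dataclass
class EffectEstimates:
    """Per-outcome treatment effects and their joint covariance.

    ``cell_means``/``vcov_cells`` hold the arm-by-wave means (flattened
    outcome-major, cells ordered as in :data:`CELLS`); ``delta``/
    ``vcov_delta`` hold the chained 3/6/9-month effects (flattened
    outcome-major over horizons) once chaining has been applied.
    """

    outcomes: tuple[str, ...]
    cell_means: pd.DataFrame | None
    vcov_cells: np.ndarray | None
    n_clusters: int
    estimator: str = "main"
    single_arm: bool = False
    delta: pd.DataFrame | None = None
    vcov_delta: np.ndarray | None = None

    def delta_vector(self) -> np.ndarray:
        if self.delta is None:
            raise EstimationError("chaining has not been applied")
        return self.delta.to_numpy().ravel()


def fit_joint_cell_means(om: pd.DataFrame) -> EffectEstimates:
    """Saturated arm-by-wave cell-means fit, all outcomes jointly.

    Point estimates equal per-cell sample means; the covariance is the
    participant-clustered sandwich across all outcome equations.
    """
    pids = om["participant_id"].astype(str)
    cluster_index = pd.factorize(pids)[0]
    n_clusters = int(cluster_index.max()) + 1
    cell_code = np.full(len(om), -1)
    for c, (arm, wave) in enumerate(CELLS):
        cell_code[(om["arm"] == arm).to_numpy() & (om["wave"] == wave).to_numpy()] = c
    if (cell_code < 0).any():
        bad = om.loc[cell_code < 0, ["arm", "wave"]].drop_duplicates()
        raise EstimationError(f"records outside the arm-wave design: {bad.to_dict('records')}")

    equations = []
    for outcome in OUTCOMES:
        y_all = om[outcome].to_numpy(dtype=float)
        obs = ~np.isnan(y_all)
        for c, (arm, wave) in enumerate(CELLS):
            if not np.any(obs & (cell_code == c)):
                raise EstimationError(
                    f"empty cell for outcome {outcome!r}: arm={arm} wave={wave}"
                )
        X = np.zeros((int(obs.sum()), len(CELLS)))
        X[np.arange(X.shape[0]), cell_code[obs]] = 1.0
        equations.append((y_all[obs], X, cluster_index[obs]))
    beta, vcov = _stacked_cluster_ols(equations, n_clusters)
    cell_means = pd.DataFrame(
        beta.reshape(len(OUTCOMES), len(CELLS)),
        index=list(OUTCOMES),
        columns=pd.MultiIndex.from_tuples(CELLS, names=["arm", "wave"]),
    )
    return EffectEstimates(
        outcomes=OUTCOMES,
        cell_means=cell_means,
        vcov_cells=vcov,
        n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# Chaining (exactly linear in cell means)
# ---------------------------------------------------------------------------


def _chain_block(mode: str) -> np.ndarray:
    """3x8 map from one outcome's cell means (E0,E3,E6,E9,W0,W3,W6,W9) to
    (d3, d6, d9)."""
    L = np.zeros((3, 8))
    if mode in ("main", "did"):
        for h in range(3):  # telescoped chaining
            L[h, 1 : 2 + h] = 1.0
            L[h, 5 : 6 + h] = -1.0
        if mode == "did":
            for h in range(3):
                L[h, 0] = -(h + 1)
                L[h, 4] = h + 1
    elif mode == "prepost":
        for h in range(3):
            L[h, 0] = -1.0
            L[h, 1 + h] = 1.0
    else:
        raise EstimationError(f"unknown chaining mode {mode!r}")
    return L


def chain_waitlist_effects(est: EffectEstimates, mode: str = "main") -> EffectEstimates:
    """Apply the waitlist chaining rule (or a sensitivity variant) to cell
    means, propagating the covariance exactly."""
    if est.cell_means is None or est.vcov_cells is None:
        raise EstimationError("cell means unavailable")
    n_out, n_cell = len(est.outcomes), len(CELLS)
    block = _chain_block(mode)
    L = np.kron(np.eye(n_out), block)
    delta = L @ est.cell_means.to_numpy().ravel()
    vcov_delta = L @ est.vcov_cells @ L.T
    return replace(
        est,
        estimator=mode if mode != "main" else est.estimator,
        single_arm=(mode == "prepost"),
        delta=pd.DataFrame(
            delta.reshape(n_out, 3), index=list(est.outcomes), columns=list(HORIZONS)
        ),
        vcov_delta=vcov_delta,
    )


def estimate_did(om: pd.DataFrame) -> EffectEstimates:
    """Difference-in-differences variant: arm means are replaced by changes
    from baseline before chaining."""
    est = fit_joint_cell_means(om)
    est = chain_waitlist_effects(est, mode="did")
    return replace(est, estimator="did")


def estimate_prepost(om: pd.DataFrame) -> EffectEstimates:
    """Single-arm pre-post variant: the intervention arm's change from
    baseline, no comparator."""
    est = fit_joint_cell_means(om)
    est = chain_waitlist_effects(est, mode="prepost")
    return replace(est, estimator="prepost")


def estimate_ancova(om: pd.DataFrame) -> EffectEstimates:
    """Baseline-adjusted variant: each outcome's post-exposure equations
    include its wave-0 value as a covariate; chaining is applied to the
    adjusted arm contrasts (d3 = c3, d6 = c3 + c6, d9 = c3 + c6 + c9)."""
    pids = om["participant_id"].astype(str)
    cluster_index = pd.factorize(pids)[0]
    n_clusters = int(cluster_index.max()) + 1
    base = om[om["wave"] == 0].set_index("participant_id")

    equations = []
    coef_index = []  # (outcome, wave) -> position of the arm coefficient
    pos = 0
    for outcome in OUTCOMES:
        y0 = base[outcome]
        for wave in HORIZONS:
            sub = om[om["wave"] == wave].copy()
            sub["y0"] = y0.reindex(sub["participant_id"]).to_numpy()
            y = sub[outcome].to_numpy(dtype=float)
            keep = ~np.isnan(y) & ~np.isnan(sub["y0"].to_numpy(dtype=float))
            sub = sub[keep]
            if sub.empty or sub["arm"].nunique() < 2:
                raise EstimationError(
                    f"cannot adjust outcome {outcome!r} at wave {wave}: "
                    "need both arms observed with baselines"
                )
            X = np.column_stack(
                [
                    np.ones(len(sub)),
                    (sub["arm"] == "intervention").to_numpy(dtype=float),
                    sub["y0"].to_numpy(dtype=float),
                ]
            )
            equations.append((y[keep], X, cluster_index[om["wave"] == wave][keep]))
            coef_index.append(pos + 1)  # arm coefficient
            pos += 3
    beta, vcov = _stacked_cluster_ols(equations, n_clusters)

    # select arm contrasts, then cumulative-sum within outcome
    S = np.zeros((len(OUTCOMES) * 3, len(beta)))
    for row, col in enumerate(coef_index):
        S[row, col] = 1.0
    C = np.kron(np.eye(len(OUTCOMES)), np.tril(np.ones((3, 3))))
    M = C @ S
    delta = M @ beta
    vcov_delta = M @ vcov @ M.T
    return EffectEstimates(
        outcomes=OUTCOMES,
        cell_means=None,
        vcov_cells=None,
        n_clusters=n_clusters,
        estimator="ancova",
        delta=pd.DataFrame(
            delta.reshape(len(OUTCOMES), 3), index=list(OUTCOMES), columns=list(HORIZONS)
        ),
        vcov_delta=vcov_delta,
    )


# ---------------------------------------------------------------------------
# Discounted AUC aggregation
# ---------------------------------------------------------------------------


@dataclass
class CumulativeEffects:
    """Discounted cumulative 9-month effects (QALYs / counts / SEK) with
    their joint covariance; linear images of the chained deltas."""

    auc: pd.Series
    vcov_auc: np.ndarray
    n_clusters: int
    estimator: str
    single_arm: bool = False


def _auc_weights(outcome: str, config: AnalysisConfig) -> np.ndarray:
    """Weights w such that AUC = w . (d3, d6, d9)."""
    r = config.discount_rate
    d = {m: (1.0 + r) ** (-m / 12.0) for m in HORIZONS}
    family = RECALL[outcome]
    if family == "qaly":
        if config.hrqol_auc == "trapezoid":
            # quarter-year trapezoids anchored at zero effect at randomization
            return np.array(
                [0.125 * (d[3] + d[6]), 0.125 * (d[6] + d[9]), 0.125 * d[9]]
            )
        return np.array([0.25 * d[3], 0.25 * d[6], 0.25 * d[9]])
    if family == "3mo":
        return np.array([d[3], d[6], d[9]])
    if family == "1mo":
        return np.array([3.0 * d[3], 3.0 * d[6], 3.0 * d[9]])
    raise EstimationError(f"unknown recall family {family!r} for {outcome!r}")


def aggregate_auc(est: EffectEstimates, config: AnalysisConfig) -> CumulativeEffects:
    """Aggregate chained per-wave effects into discounted cumulative effects."""
    if est.delta is None or est.vcov_delta is None:
        raise EstimationError("chained deltas required; run chaining first")
    n_out = len(est.outcomes)
    W = np.zeros((n_out, n_out * 3))
    for j, outcome in enumerate(est.outcomes):
        W[j, 3 * j : 3 * j + 3] = _auc_weights(outcome, config)
    auc = W @ est.delta_vector()
    vcov_auc = W @ est.vcov_delta @ W.T
    return CumulativeEffects(
        auc=pd.Series(auc, index=list(est.outcomes)),
        vcov_auc=vcov_auc,
        n_clusters=est.n_clusters,
        estimator=est.estimator,
        single_arm=est.single_arm,
    )


def incremental_summary(
    cum: CumulativeEffects,
    tables: CostingTables,
    config: AnalysisConfig,
    scope: str = "public",
) -> IncrementalResult:
    """Map cumulative effects to (dE, dC) with SEs and correlation.

    dC = sum over in-scope items of (unit cost x discounted count AUC)
    + both drug-cost AUCs + the app cost per user (a constant).
    """
    outcomes = list(cum.auc.index)
    scope_items = tables.scope_items(scope)
    w_e = np.zeros(len(outcomes))
    w_c = np.zeros(len(outcomes))
    w_e[outcomes.index("hrqol")] = 1.0
    for i in ITEMS:
        if i in scope_items:
            w_c[outcomes.index(f"item_{i}")] = tables.unit_costs[i].sek_per_unit
    w_c[outcomes.index("drug_related")] = 1.0
    w_c[outcomes.index("drug_unrelated")] = 1.0

    auc = cum.auc.to_numpy()
    mean_e = float(w_e @ auc)
    mean_c = float(w_c @ auc + config.app_cost_per_user)
    var_e = float(w_e @ cum.vcov_auc @ w_e)
    var_c = float(w_c @ cum.vcov_auc @ w_c)
    cov_ec = float(w_e @ cum.vcov_auc @ w_c)
    se_e, se_c = np.sqrt(max(var_e, 0.0)), np.sqrt(max(var_c, 0.0))
    rho = cov_ec / (se_e * se_c) if se_e > 0 and se_c > 0 else 0.0
    return IncrementalResult(
        mean_e=mean_e, mean_c=mean_c, se_e=float(se_e), se_c=float(se_c),
        rho=float(np.clip(rho, -1.0, 1.0)),
    )


@dataclass
class JointTest:
    statistic: float
    df: int
    pvalue: float


def joint_null_test(cum: CumulativeEffects) -> JointTest:
    """Wald chi-square test that all cumulative effects are simultaneously
    zero, using the cluster-robust joint covariance."""
    x = cum.auc.to_numpy()
    V = cum.vcov_auc
    rank = int(np.linalg.matrix_rank(V))
    if rank < V.shape[0]:
        logger.warning("joint covariance rank-deficient (rank %d of %d); "
                       "using pseudo-inverse", rank, V.shape[0])
    stat = float(x @ np.linalg.pinv(V) @ x)
    return JointTest(statistic=stat, df=rank, pvalue=float(chi2.sf(stat, rank)))


# ---------------------------------------------------------------------------
# Missing-data scenarios
# ---------------------------------------------------------------------------


def apply_attrition_scenario(om: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Attrition sensitivity transforms of the outcome matrix.

    ``worst`` imputes missing health-care use and drug costs with the pooled
    95th percentile and missing HRQoL with the 5th; ``best`` reverses the
    percentiles; ``complete_case`` keeps participants who responded at every
    wave.  Percentiles are computed per outcome from observed values pooled
    across arms and waves.  Fully observed data pass through unchanged.
    """
    if scenario == "complete_case":
        full = om.groupby("participant_id")["responded"].agg(
            lambda s: bool(s.all()) and len(s) == len(WAVES)
        )
        keep = full[full].index
        return om[om["participant_id"].isin(keep)].reset_index(drop=True)
    if scenario not in ("best", "worst"):
        raise EstimationError(f"unknown attrition scenario {scenario!r}")
    out = om.copy()
    filled_any = np.zeros(len(out), dtype=bool)
    for outcome in OUTCOMES:
        vals = out[outcome].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            continue
        if outcome == "hrqol":
            q = 5 if scenario == "worst" else 95
        else:
            q = 95 if scenario == "worst" else 5
        fill = float(np.percentile(obs, q))
        missing = np.isnan(vals)
        vals[missing] = fill
        out[outcome] = vals
        filled_any |= missing
    out.loc[filled_any, "responded"] = True
    return out


def impute_pmm(
    om: pd.DataFrame,
    m: int = 20,
    k: int = 5,
    seed: int = 0,
    chain_mode: str = "main",
) -> tuple[list[pd.DataFrame], EffectEstimates]:
    """Multiple imputation by predictive mean matching, pooled by Rubin's
    rules.

    Per outcome, missing post-baseline values are predicted linearly from
    arm, wave and the participant's baseline value; each missing cell draws
    uniformly from the ``k`` observed donors nearest in predicted value.
    Missing baselines are imputed first (predictor: arm).  The pooled
    chained-effect covariance is within-imputation average plus
    (1 + 1/m) times the between-imputation covariance.
    """
    if m < 2:
        raise EstimationError("need at least 2 imputations")
    root = np.random.SeedSequence(seed)
    completed: list[pd.DataFrame] = []
    deltas, vcovs = [], []
    est_template = None
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        filled = _pmm_once(om, k, rng)
        completed.append(filled)
        est = chain_waitlist_effects(fit_joint_cell_means(filled), mode=chain_mode)
        est_template = est
        deltas.append(est.delta_vector())
        vcovs.append(est.vcov_delta)
    D = np.array(deltas)
    pooled = D.mean(axis=0)
    within = np.mean(vcovs, axis=0)
    centered = D - pooled
    between = centered.T @ centered / (m - 1)
    vcov = within + (1.0 + 1.0 / m) * between
    est = replace(
        est_template,
        estimator="multiple_imputation",
        delta=pd.DataFrame(
            pooled.reshape(len(OUTCOMES), 3), index=list(OUTCOMES),
            columns=list(HORIZONS),
        ),
        vcov_delta=vcov,
    )
    return completed, est


def _pmm_once(om: pd.DataFrame, k: int, rng: np.random.Generator) -> pd.DataFrame:
    out = om.copy()
    arm_ind = (out["arm"] == "intervention").to_numpy(dtype=float)
    wave = out["wave"].to_numpy()
    is_base = wave == 0
    for outcome in OUTCOMES:
        y = out[outcome].to_numpy(dtype=float)
        # baseline first (predictor: arm)
        y = _pmm_fill(y, np.column_stack([np.ones(len(y)), arm_ind]),
                      is_base, k, rng)
        # per-participant baseline as predictor for later waves
        base_by_pid = pd.Series(
            y[is_base], index=out.loc[is_base, "participant_id"]
        )
        y0 = base_by_pid.reindex(out["participant_id"]).to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(y)), arm_ind, (wave == 6).astype(float),
             (wave == 9).astype(float), np.nan_to_num(y0)]
        )
        y = _pmm_fill(y, X, ~is_base, k, rng)
        out[outcome] = y
    out["responded"] = True
    return out


def _pmm_fill(
    y: np.ndarray, X: np.ndarray, mask: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fill NaNs of y (within mask) by predictive mean matching on X."""
    y = y.copy()
    obs = mask & ~np.isnan(y)
    mis = mask & np.isnan(y)
    if not mis.any():
        return y
    if obs.sum() < 2:
        raise EstimationError("too few observed values for predictive mean matching")
    kk = min(k, int(obs.sum()))
    if kk < k:
        logger.warning("donor pool reduced to %d", kk)
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    pred_obs = X[obs] @ beta
    pred_mis = X[mis] @ beta
    donors = y[obs]
    mis_idx = np.flatnonzero(mis)
    for j, p in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - p), kind="stable")[:kk]
        y[mis_idx[j]] = donors[nearest[rng.integers(kk)]]
    return y
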