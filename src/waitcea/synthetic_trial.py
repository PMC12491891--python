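"""Synthetic waitlist-RCT generator.

Emulates a two-arm trial (immediate versus 3-month-delayed access to an
app-guided self-management intervention) with the statistical structure the
downstream analysis assumes:

* an HRQoL index in [0, 1] with a participant-level random effect (repeated
  measures are correlated within participants),
* zero-heavy, right-skewed health-care-use counts from a hurdle model
  (Bernoulli any-use x shifted negative-binomial positive part) with
  participant-level heterogeneity in the any-use propensity,
* drug consumption per related/unrelated class with lognormal positive costs,
* treatment effects that switch on at exposure: immediately for the
  intervention arm, from month 6 for the waitlist arm (exposed at month 3),
* wave non-response hitting configured per-wave counts exactly, including a
  configurable number of all-wave responders (the real trial's response
  pattern was not monotone: fewer complete cases than month-9 responders),
* independent item-level missingness at a small configured rate.

Effects on counts are multiplicative and applied by binomial thinning
(factor < 1) or Poisson superposition (factor > 1), so the expected count
scales exactly by the factor while counts stay non-negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import SpecError, ValidationError
from .trial_data import (
    ARMS,
    ITEMS,
    WAVES,
    AnalysisConfig,
    CostingTables,
    TrialRecord,
    frames_to_records,
)

HORIZONS = (3, 6, 9)  # months after exposure at which effects are defined


@dataclass(frozen=True)
class CountModel:
    """Hurdle model for one TiC-P item: P(any use), mean count given any use
    (>= 1) and a negative-binomial size parameter for the positive part
    (smaller = heavier tail)."""

    p_any: float
    mean_given_any: float
    dispersion: float = 0.8

    @property
    def marginal_mean(self) -> float:
        return self.p_any * self.mean_given_any


@dataclass(frozen=True)
class DrugModel:
    """Per-class drug use: P(any use in a 3-month window) and lognormal
    parameters of the positive 3-month cost (SEK)."""

    p_use: float
    meanlog: float
    sdlog: float


# Any-use probabilities pooled from the trial's baseline table; the positive
# part means and dispersions are calibration choices (the baseline table
# prints only any-use proportions and heavy-tailed cost summaries).
_DEFAULT_COUNT_MODELS: dict[int, CountModel] = {
    1: CountModel(0.335, 2.5),   # general practitioner (1mo)
    2: CountModel(0.022, 4.0),   # home care (1mo)
    3: CountModel(0.045, 2.5),   # private mental health care (1mo)
    4: CountModel(0.073, 3.0),   # public mental health care (1mo)
    5: CountModel(0.011, 1.5),   # occupational-health physician (1mo)
    6: CountModel(0.106, 1.8),   # specialist physician (3mo)
    7: CountModel(0.229, 3.0),   # paramedical professional (3mo)
    8: CountModel(0.128, 2.5),   # social worker / counselor (3mo)
    9: CountModel(0.011, 2.0),   # alcohol/drug clinic (3mo)
    10: CountModel(0.061, 2.5),  # alternative medicine (3mo)
    11: CountModel(0.045, 3.0),  # self-help group (3mo)
    12: CountModel(0.006, 5.0),  # psychiatric day care (3mo)
    13: CountModel(0.067, 5.0),  # inpatient care days (3mo)
}

_DEFAULT_DRUG_MODELS: dict[str, DrugModel] = {
    # marginal means ~ 0.355*exp(5.52+1.3^2/2) ~ 205 and 0.38*exp(6.06+1.5^2/2) ~ 500 SEK
    "related": DrugModel(0.355, 5.52, 1.3),
    "unrelated": DrugModel(0.38, 6.06, 1.5),
}

_DRUG_CODES = {"related": "REL01", "unrelated": "UNREL01"}


@dataclass
class SimulationSpec:
    """Study conditions for one simulated trial."""

    n_intervention: int = 89
    n_waitlist: int = 90
    hrqol_baseline_mean: float = 0.564
    hrqol_between_sd: float = 0.070
    hrqol_within_sd: float = 0.053
    #: additive HRQoL effect at 3/6/9 months after exposure
    treatment_effect_hrqol: dict[int, float] = field(
        default_factory=lambda: {h: 0.0 for h in HORIZONS}
    )
    count_models: dict[int, CountModel] = field(
        default_factory=lambda: dict(_DEFAULT_COUNT_MODELS)
    )
    #: multiplicative post-exposure effect on each item's expected count
    treatment_effect_counts: dict[int, float] = field(
        default_factory=lambda: {i: 1.0 for i in ITEMS}
    )
    drug_models: dict[str, DrugModel] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_MODELS)
    )
    #: multiplicative post-exposure effect on each class's drug cost
    treatment_effect_drugs: dict[str, float] = field(
        default_factory=lambda: {"related": 1.0, "unrelated": 1.0}
    )
    any_use_heterogeneity: float = 0.7  # probit random-effect SD for any-use
    waitlist_delay_months: int = 3
    waitlist_exposed: bool = True  # False: unexposed control at all waves
    retention: tuple[int, int, int, int] = (179, 149, 134, 118)
    complete_case_target: int | None = 104  # None => monotone dropout
    item_missing_rate: float = 0.0055
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_intervention + self.n_waitlist
        if self.n_intervention <= 0 or self.n_waitlist <= 0:
            raise SpecError("both arms must be non-empty")
        if self.retention[0] != n:
            raise SpecError(
                f"wave-0 retention {self.retention[0]} must equal sample size {n}"
            )
        if any(r > n for r in self.retention):
            raise SpecError("retention target exceeds sample size")
        if any(b > a for a, b in zip(self.retention, self.retention[1:])):
            raise SpecError("retention targets must be non-increasing")
        if self.complete_case_target is not None and (
            self.complete_case_target > min(self.retention)
        ):
            raise SpecError("complete-case target exceeds a retention target")
        if not 0.0 <= self.item_missing_rate < 1.0:
            raise SpecError("item_missing_rate must be in [0, 1)")
        for cm in self.count_models.values():
            if not 0.0 <= cm.p_any <= 1.0 or cm.mean_given_any < 1.0:
                raise SpecError("count model needs p_any in [0,1], mean_given_any >= 1")
        for f in self.treatment_effect_counts.values():
            if f < 0:
                raise SpecError("count effect factors must be >= 0")


def _response_patterns(spec: SimulationSpec) -> list[tuple[int, tuple[bool, ...]]]:
    """Deterministic allocation of follow-up response patterns.

    Returns (count, responded-at-waves-3/6/9) pairs hitting the per-wave
    retention targets exactly and, when requested, the all-wave responder
    count.  The allocation greedily keeps dropout as monotone as possible and
    introduces intermittent patterns only as needed.
    """
    n = spec.retention[0]
    n3, n6, n9 = spec.retention[1:]
    if spec.complete_case_target is None:
        return [
            (n9, (True, True, True)),
            (n6 - n9, (True, True, False)),
            (n3 - n6, (True, False, False)),
            (n - n3, (False, False, False)),
        ]
    nall = spec.complete_case_target
    m3, m6, m9 = n3 - nall, n6 - nall, n9 - nall
    if min(m3, m6, m9) < 0:
        raise SpecError("complete-case target exceeds a retention target")
    a = min(m3, m6)          # (1,1,0)
    r3, r6 = m3 - a, m6 - a
    d = min(r6, m9)          # (0,1,1)
    r9 = m9 - d
    b = min(r3, r9)          # (1,0,1)
    c, e, f = r3 - b, r6 - d, r9 - b
    g = n - nall - (a + b + c + d + e + f)  # (0,0,0)
    if g < 0:
        raise SpecError("retention targets incompatible with complete-case target")
    return [
        (nall, (True, True, True)),
        (a, (True, True, False)),
        (b, (True, False, True)),
        (c, (True, False, False)),
        (d, (False, True, True)),
        (e, (False, True, False)),
        (f, (False, False, True)),
        (g, (False, False, False)),
    ]


def _months_after_exposure(arm_is_intervention: np.ndarray, wave: int,
                           spec: SimulationSpec) -> np.ndarray:
    mae = np.where(arm_is_intervention, wave, wave - spec.waitlist_delay_months)
    if not spec.waitlist_exposed:
        mae = np.where(arm_is_intervention, mae, -1)
    return mae


def _positive_part(rng: np.random.Generator, model: CountModel, size: int) -> np.ndarray:
    """Draw the >=1 part of the hurdle: 1 + negative binomial."""
    mu = model.mean_given_any - 1.0
    if mu <= 0:
        return np.ones(size, dtype=np.int64)
    k = model.dispersion
    return 1 + rng.negative_binomial(k, k / (k + mu), size=size)


def simulate_frames(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one trial, returning the flat (trial, drugs) frames."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_intervention + spec.n_waitlist
    pad = max(4, len(str(n)))
    ids = np.array([f"P{j + 1:0{pad}d}" for j in range(n)])
    arm_idx = rng.permutation(
        np.array([0] * spec.n_intervention + [1] * spec.n_waitlist)
    )
    arms = np.where(arm_idx == 0, ARMS[0], ARMS[1])
    is_int = arm_idx == 0

    # response patterns for waves 3/6/9 (wave 0 always responded)
    patterns = _response_patterns(spec)
    pattern_of = np.concatenate(
        [np.full(count, p, dtype=int) for p, (count, _) in enumerate(patterns)]
    )
    rng.shuffle(pattern_of)
    responded = np.ones((n, 4), dtype=bool)
    for w, _wave in enumerate(WAVES[1:], start=1):
        responded[:, w] = [patterns[p][1][w - 1] for p in pattern_of]

    # participant-level latents
    hrqol_re = rng.normal(0.0, spec.hrqol_between_sd, n)
    any_use_re = rng.normal(0.0, 1.0, n)

    tau = spec.any_use_heterogeneity
    trial_rows: dict[str, list] = {c: [] for c in ("participant_id", "arm", "wave",
                                                   "responded", "hrqol")}
    item_cols: dict[int, list] = {i: [] for i in ITEMS}
    drug_rows: list[dict] = []

    for w, wave in enumerate(WAVES):
        mae = _months_after_exposure(is_int, wave, spec)
        exposed = mae > 0

        # HRQoL
        eff = np.array([spec.treatment_effect_hrqol.get(int(m), 0.0) if m > 0 else 0.0
                        for m in mae])
        hrqol = np.clip(
            spec.hrqol_baseline_mean + hrqol_re + eff
            + rng.normal(0.0, spec.hrqol_within_sd, n),
            0.0, 1.0,
        )

        # counts
        counts = {}
        for i in ITEMS:
            cm = spec.count_models[i]
            # probit any-use with participant random effect; marginal P = p_any
            cut = -norm.ppf(cm.p_any) * np.sqrt(1.0 + tau**2)
            any_use = tau * any_use_re + rng.normal(0.0, 1.0, n) > cut
            c = np.where(any_use, _positive_part(rng, cm, n), 0).astype(np.int64)
            f = spec.treatment_effect_counts.get(i, 1.0)
            if f != 1.0:
                c_exp = c[exposed]
                if f < 1.0:
                    c_exp = rng.binomial(c_exp, f)
                else:
                    c_exp = c_exp + rng.poisson((f - 1.0) * cm.marginal_mean,
                                                c_exp.size)
                c = c.copy()
                c[exposed] = c_exp
            counts[i] = c.astype(float)

        # item-level missingness within responded waves
        if spec.item_missing_rate > 0:
            miss = rng.random((n, len(ITEMS))) < spec.item_missing_rate
            for j, i in enumerate(ITEMS):
                counts[i][miss[:, j]] = np.nan

        # drugs
        drug_units = {}
        for cls, dm in spec.drug_models.items():
            use = rng.random(n) < dm.p_use
            units = np.where(use, rng.lognormal(dm.meanlog, dm.sdlog, n), 0.0)
            f = spec.treatment_effect_drugs.get(cls, 1.0)
            if f != 1.0:
                units[exposed] *= f
            drug_units[cls] = units

        resp = responded[:, w]
        trial_rows["participant_id"].extend(ids)
        trial_rows["arm"].extend(arms)
        trial_rows["wave"].extend([wave] * n)
        trial_rows["responded"].extend(resp)
        trial_rows["hrqol"].extend(np.where(resp, hrqol, np.nan))
        for i in ITEMS:
            item_cols[i].extend(np.where(resp, counts[i], np.nan))
        for cls, units in drug_units.items():
            for j in np.flatnonzero(resp & (units > 0)):
                drug_rows.append(
                    {
                        "participant_id": ids[j],
                        "wave": wave,
                        "drug_code": _DRUG_CODES[cls],
                        "units": float(units[j]),
                    }
                )

    trial = pd.DataFrame(trial_rows)
    for i in ITEMS:
        trial[f"item_{i}"] = item_cols[i]
    drugs = pd.DataFrame(drug_rows,
                         columns=["participant_id", "wave", "drug_code", "units"])
    trial = trial.sort_values(["participant_id", "wave"], kind="stable",
                              ignore_index=True)
    drugs = drugs.sort_values(["participant_id", "wave", "drug_code"], kind="stable",
                              ignore_index=True)
    return trial, drugs


def simulate_trial(spec: SimulationSpec) -> list[TrialRecord]:
    """Simulate one trial as a validated record collection."""
    trial, drugs = simulate_frames(spec)
    return frames_to_records(trial, drugs)


# ---------------------------------------------------------------------------
# Baseline summary (calibration view)
# ---------------------------------------------------------------------------


def baseline_summary(
    records: Sequence[TrialRecord], tables: CostingTables | None = None
) -> pd.DataFrame:
    """Per-arm baseline (wave 0) summaries: HRQoL mean/SD, any-use
    proportions per item and mean costs under both funding scopes."""
    from .costing import cost_drugs, cost_use  # local import avoids a cycle

    tables = tables or CostingTables.default()
    base = [r for r in records if r.wave == 0 and r.responded]
    rows = {}
    for arm in ARMS:
        sub = [r for r in base if r.arm == arm]
        if not sub:
            raise ValidationError(f"no baseline records in arm {arm!r}")
        hrqol = np.array([r.hrqol for r in sub if r.hrqol is not None], dtype=float)
        row: dict[str, float] = {
            "n": len(sub),
            "hrqol_mean": float(hrqol.mean()) if hrqol.size else np.nan,
            "hrqol_sd": float(hrqol.std(ddof=1)) if hrqol.size > 1 else np.nan,
        }
        for i in ITEMS:
            vals = [r.use_counts.get(i) for r in sub]
            obs = [v for v in vals if v is not None]
            row[f"any_item_{i}"] = (
                float(np.mean([v > 0 for v in obs])) if obs else np.nan
            )
        for scope in ("public", "all"):
            c1 = c3 = 0.0
            for r in sub:
                a, b = cost_use(r.use_counts, tables, scope)
                c1 += a
                c3 += b
            row[f"cost_{scope}_1mo_mean"] = c1 / len(sub)
            row[f"cost_{scope}_3mo_mean"] = c3 / len(sub)
        rel = unrel = 0.0
        for r in sub:
            a, b = cost_drugs(r.drug_entries, tables.drug_prices)
            rel += a
            unrel += b
        row["drug_related_mean"] = rel / len(sub)
        row["drug_unrelated_mean"] = unrel / len(sub)
        rows[arm] = row
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Effect injection helpers (parameter-recovery experiments)
# ---------------------------------------------------------------------------


def spec_with_injected_effects(
    spec: SimulationSpec,
    config: AnalysisConfig,
    tables: CostingTables,
    target_qaly: float,
    target_cost: float,
    cost_item: int = 1,
) -> tuple[SimulationSpec, dict[str, float]]:
    """Return a spec whose constant per-wave effects produce the requested
    cumulative incremental effectiveness (QALYs) and health-care cost (SEK,
    excluding the app cost), plus the implied truth for the full pipeline.

    The HRQoL effect is a constant additive shift after exposure; the cost
    effect is a multiplicative shift of one item's expected count sized so
    that unit cost x discounted count AUC hits the target.
    """
    r = config.discount_rate
    disc = {m: (1.0 + r) ** (-m / 12.0) for m in HORIZONS}
    if config.hrqol_auc == "trapezoid":
        qaly_per_delta = (
            0.125 * (disc[3] + disc[6]) + 0.125 * (disc[6] + disc[9]) + 0.125 * disc[9]
        )
    else:
        qaly_per_delta = 0.25 * sum(disc.values())
    d_hrqol = target_qaly / qaly_per_delta

    cm = spec.count_models[cost_item]
    uc = tables.unit_costs[cost_item]
    per_wave_scale = 3.0 if uc.recall == "1mo" else 1.0
    auc_per_delta = per_wave_scale * sum(disc.values())
    delta_count = target_cost / (uc.sek_per_unit * auc_per_delta)
    factor = 1.0 + delta_count / cm.marginal_mean
    if factor < 0:
        raise SpecError(
            f"cost target {target_cost} not reachable through item {cost_item}"
        )
    new = replace(
        spec,
        treatment_effect_hrqol={h: d_hrqol for h in HORIZONS},
        treatment_effect_counts={**spec.treatment_effect_counts, cost_item: factor},
    )
    truth = {
        "delta_e": target_qaly,
        "delta_c": target_cost + config.app_cost_per_user,
    }
    return new, truth
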