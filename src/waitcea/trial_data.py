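"""Domain types, validation and CSV I/O for waitlist-trial records.

The unit of observation is one participant at one survey wave (months 0, 3,
6, 9 after randomization).  Each responded wave carries a health-related
quality-of-life (HRQoL) index in [0, 1], counts for the 13 health-care-use
items of the TiC-P consumption section (items 1-5 ask about the previous
month, items 6-13 about the previous 3 months; item 13 counts inpatient care
days), and a list of drug-consumption entries (TiC-P item 14).

Costing tables map TiC-P items to unit costs (with a public/private funding
flag and a recall window) and drug codes to prices (with a related/unrelated
classification).  The analysis configuration collects the decision-analytic
parameters: threshold grid, discount rate, population model and app cost.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, ValidationError

WAVES = (0, 3, 6, 9)
ARMS = ("intervention", "waitlist")
ITEMS = tuple(range(1, 14))
ITEM_COLUMNS = tuple(f"item_{i}" for i in ITEMS)

#: TiC-P items reimbursed by the public health-care sector (main-analysis scope).
PUBLIC_ITEMS = frozenset({1, 2, 4, 6, 7, 8, 9, 12, 13})
#: Items paid out of pocket (private mental health care, occupational physician,
#: alternative medicine, self-help groups); costed only in the private-care scenario.
PRIVATE_ITEMS = frozenset({3, 5, 10, 11})
#: Items with a 1-month recall window.
RECALL_1MO_ITEMS = frozenset({1, 2, 3, 4, 5})
#: Items with a 3-month recall window (item 13 = inpatient days).
RECALL_3MO_ITEMS = frozenset({6, 7, 8, 9, 10, 11, 12, 13})

TRIAL_COLUMNS = ("participant_id", "arm", "wave", "responded", "hrqol") + ITEM_COLUMNS
DRUG_COLUMNS = ("participant_id", "wave", "drug_code", "units")


@dataclass
class TrialRecord:
    """One participant-wave observation."""

    participant_id: str
    arm: str
    wave: int
    responded: bool
    hrqol: float | None = None
    use_counts: dict[int, float | None] = field(default_factory=dict)
    drug_entries: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"participant {self.participant_id}: unknown arm {self.arm!r}"
            )
        if self.wave not in WAVES:
            raise ValidationError(
                f"participant {self.participant_id}: wave {self.wave} not in {WAVES}"
            )
        if self.hrqol is not None and not 0.0 <= self.hrqol <= 1.0:
            raise ValidationError(
                f"participant {self.participant_id} wave {self.wave}: "
                f"hrqol {self.hrqol} outside [0, 1]"
            )
        for item, count in self.use_counts.items():
            if item not in ITEMS:
                raise ValidationError(
                    f"participant {self.participant_id}: unknown TiC-P item {item}"
                )
            if count is not None and count < 0:
                raise ValidationError(
                    f"participant {self.participant_id} wave {self.wave}: "
                    f"item {item} count {count} negative"
                )
        for code, units in self.drug_entries:
            if units < 0:
                raise ValidationError(
                    f"participant {self.participant_id} wave {self.wave}: "
                    f"drug {code} units {units} negative"
                )
        if not self.responded:
            outcome_present = (
                self.hrqol is not None
                or any(v is not None for v in self.use_counts.values())
                or bool(self.drug_entries)
            )
            if outcome_present:
                raise ValidationError(
                    f"participant {self.participant_id} wave {self.wave}: "
                    "outcomes present in a non-responded wave"
                )


@dataclass(frozen=True)
class UnitCost:
    sek_per_unit: float
    funding: str  # {public, private}
    recall: str  # {1mo, 3mo}


@dataclass(frozen=True)
class DrugPrice:
    sek_per_unit: float
    drug_class: str  # {related, unrelated}


@dataclass
class CostingTables:
    """Unit costs per TiC-P item and prices per drug code."""

    unit_costs: dict[int, UnitCost]
    drug_prices: dict[str, DrugPrice]

    def public_items(self) -> frozenset[int]:
        return frozenset(
            i for i, uc in self.unit_costs.items() if uc.funding == "public"
        )

    def scope_items(self, scope: str) -> frozenset[int]:
        if scope == "public":
            return self.public_items()
        if scope == "all":
            return frozenset(self.unit_costs)
        raise ConfigurationError(f"unknown costing scope {scope!r}")

    @classmethod
    def default(cls) -> "CostingTables":
        return default_costing_tables()


# Synthetic default unit costs (SEK, 2023 price level).  The published
# cost-per-patient figures are not reproduced here; these are calibration
# choices with the right funding scope, recall windows and rough magnitudes
# (a GP visit in the low thousands, an inpatient day near ten thousand).
_DEFAULT_UNIT_COSTS: dict[int, UnitCost] = {
    1: UnitCost(2500.0, "public", "1mo"),  # general practitioner
    2: UnitCost(1500.0, "public", "1mo"),  # home-care professional
    3: UnitCost(1100.0, "private", "1mo"),  # private mental health care
    4: UnitCost(2600.0, "public", "1mo"),  # public mental health care
    5: UnitCost(1900.0, "private", "1mo"),  # occupational-health physician
    6: UnitCost(3600.0, "public", "3mo"),  # hospital outpatient specialist
    7: UnitCost(900.0, "public", "3mo"),  # paramedical professional
    8: UnitCost(1300.0, "public", "3mo"),  # social worker / counselor
    9: UnitCost(1800.0, "public", "3mo"),  # alcohol/drug clinic
    10: UnitCost(700.0, "private", "3mo"),  # alternative medicine
    11: UnitCost(300.0, "private", "3mo"),  # self-help group
    12: UnitCost(3500.0, "public", "3mo"),  # psychiatric day-care program
    13: UnitCost(9000.0, "public", "3mo"),  # inpatient care day
}

# Drug prices of 1 SEK/unit make simulated "units" directly interpretable as
# SEK, so the drug-cost pathway is exercised without a real price list.
_DEFAULT_DRUG_PRICES: dict[str, DrugPrice] = {
    "REL01": DrugPrice(1.0, "related"),
    "UNREL01": DrugPrice(1.0, "unrelated"),
}


def default_costing_tables() -> CostingTables:
    return CostingTables(dict(_DEFAULT_UNIT_COSTS), dict(_DEFAULT_DRUG_PRICES))


def validate_costing(tables: CostingTables) -> CostingTables:
    """Check funding-scope and recall-window invariants of a costing table.

    Every item 1-13 must be priced; the public/private split and the
    1-month/3-month recall windows must match the questionnaire layout.
    """
    missing = sorted(set(ITEMS) - set(tables.unit_costs))
    if missing:
        raise ConfigurationError(f"unit cost missing for items {missing}")
    for item, uc in tables.unit_costs.items():
        if uc.sek_per_unit < 0:
            raise ValidationError(f"item {item}: negative unit cost")
        expected_funding = "public" if item in PUBLIC_ITEMS else "private"
        if uc.funding != expected_funding:
            raise ValidationError(
                f"item {item}: funding {uc.funding!r}, expected {expected_funding!r}"
            )
        expected_recall = "1mo" if item in RECALL_1MO_ITEMS else "3mo"
        if uc.recall != expected_recall:
            raise ValidationError(
                f"item {item}: recall {uc.recall!r}, expected {expected_recall!r}"
            )
    for code, price in tables.drug_prices.items():
        if price.sek_per_unit < 0:
            raise ValidationError(f"drug {code}: negative price")
        if price.drug_class not in ("related", "unrelated"):
            raise ValidationError(f"drug {code}: unknown class {price.drug_class!r}")
    return tables


@dataclass
class AnalysisConfig:
    """Decision-analytic parameters.

    lambda_base       base-case cost-effectiveness threshold, SEK per QALY
    lambda_max        upper end of the threshold range (curve plots)
    discount_rate     annual discount rate applied to effects, costs and users
    users_per_year    expected app users per year (population scaling)
    horizon_years     population time horizon in years
    app_cost_per_user intervention cost per user, SEK
    usd_per_sek       exchange rate, used for report decoration only
    hrqol_auc         'trapezoid' (effect ramps from 0 at randomization) or
                      'constant' (each quarter held at its endpoint effect)
    user_timing       'end' counts users at the end of years 1..H, 'start'
                      at the start (years 0..H-1)
    """

    lambda_base: float = 500_000.0
    lambda_max: float = 1_000_000.0
    discount_rate: float = 0.03
    users_per_year: float = 988.0
    horizon_years: int = 5
    app_cost_per_user: float = 12.0
    usd_per_sek: float = 0.094
    hrqol_auc: str = "trapezoid"
    user_timing: str = "end"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.lambda_base <= 0 or self.lambda_max <= 0:
            raise ConfigurationError("thresholds must be > 0")
        if self.users_per_year <= 0 or self.horizon_years <= 0:
            raise ConfigurationError("population model must be positive")
        if self.hrqol_auc not in ("trapezoid", "constant"):
            raise ConfigurationError(f"unknown hrqol_auc {self.hrqol_auc!r}")
        if self.user_timing not in ("end", "start"):
            raise ConfigurationError(f"unknown user_timing {self.user_timing!r}")

    def lambda_grid(self, n: int = 200) -> np.ndarray:
        """Log-spaced threshold grid from SEK 1 to lambda_max."""
        return np.geomspace(1.0, self.lambda_max, n)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _to_float(value, where: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"malformed numeric field at {where}: {value!r}") from None


def frames_to_records(
    trial: pd.DataFrame, drugs: pd.DataFrame | None = None
) -> list[TrialRecord]:
    """Build validated records from the flat trial/drugs frames."""
    for col in TRIAL_COLUMNS:
        if col not in trial.columns:
            raise ParseError(f"trial data missing column {col!r}")
    drug_map: dict[tuple[str, int], list[tuple[str, float]]] = {}
    if drugs is not None and len(drugs):
        for col in DRUG_COLUMNS:
            if col not in drugs.columns:
                raise ParseError(f"drug data missing column {col!r}")
        for row in drugs.itertuples(index=True):
            units = _to_float(row.units, f"drugs row {row.Index}")
            if units is None:
                raise ParseError(f"drugs row {row.Index}: missing units")
            key = (str(row.participant_id), int(row.wave))
            drug_map.setdefault(key, []).append((str(row.drug_code), units))

    records: list[TrialRecord] = []
    seen: set[tuple[str, int]] = set()
    for row in trial.itertuples(index=True):
        where = f"trial row {row.Index}"
        pid = str(row.participant_id)
        try:
            wave = int(row.wave)
        except (TypeError, ValueError):
            raise ParseError(f"malformed wave at {where}: {row.wave!r}") from None
        key = (pid, wave)
        if key in seen:
            raise ValidationError(f"duplicate record for participant {pid} wave {wave}")
        seen.add(key)
        responded = _parse_bool(row.responded, where)
        rec = TrialRecord(
            participant_id=pid,
            arm=str(row.arm),
            wave=wave,
            responded=responded,
            hrqol=_to_float(row.hrqol, where),
            use_counts={
                i: _to_float(getattr(row, f"item_{i}"), where) for i in ITEMS
            },
            drug_entries=drug_map.get(key, []),
        )
        rec.validate()
        records.append(rec)
    return records


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ParseError(f"malformed boolean at {where}: {value!r}")


def records_to_frames(
    records: Iterable[TrialRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    trial_rows = []
    drug_rows = []
    for rec in records:
        row: dict = {
            "participant_id": rec.participant_id,
            "arm": rec.arm,
            "wave": rec.wave,
            "responded": rec.responded,
            "hrqol": np.nan if rec.hrqol is None else rec.hrqol,
        }
        for i in ITEMS:
            v = rec.use_counts.get(i)
            row[f"item_{i}"] = np.nan if v is None else v
        trial_rows.append(row)
        for code, units in rec.drug_entries:
            drug_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "wave": rec.wave,
                    "drug_code": code,
                    "units": units,
                }
            )
    trial = pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS))
    drugs = pd.DataFrame(drug_rows, columns=list(DRUG_COLUMNS))
    return trial, drugs


def read_trial(
    trial_path: str | Path, drugs_path: str | Path | None = None
) -> list[TrialRecord]:
    """Read and validate the long-format trial CSV (plus optional drugs CSV)."""
    try:
        trial = pd.read_csv(trial_path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse {trial_path}: {exc}") from exc
    drugs = None
    if drugs_path is not None and Path(drugs_path).exists():
        drugs = pd.read_csv(drugs_path, float_precision="round_trip")
    return frames_to_records(trial, drugs)


def write_trial(
    records: Sequence[TrialRecord],
    trial_path: str | Path,
    drugs_path: str | Path | None = None,
) -> None:
    trial, drugs = records_to_frames(records)
    # %.17g guarantees binary round-trip of doubles through the text format
    trial.to_csv(trial_path, index=False, float_format="%.17g")
    if drugs_path is not None:
        drugs.to_csv(drugs_path, index=False, float_format="%.17g")


def read_unit_costs(path: str | Path) -> dict[int, UnitCost]:
    df = pd.read_csv(path)
    for col in ("item", "sek_per_unit", "funding", "recall"):
        if col not in df.columns:
            raise ParseError(f"unit cost table missing column {col!r}")
    return {
        int(r.item): UnitCost(float(r.sek_per_unit), str(r.funding), str(r.recall))
        for r in df.itertuples()
    }


def read_drug_prices(path: str | Path) -> dict[str, DrugPrice]:
    df = pd.read_csv(path)
    for col in ("drug_code", "sek_per_unit", "drug_class"):
        if col not in df.columns:
            raise ParseError(f"drug price table missing column {col!r}")
    return {
        str(r.drug_code): DrugPrice(float(r.sek_per_unit), str(r.drug_class))
        for r in df.itertuples()
    }


def read_costing_tables(
    unit_costs_path: str | Path | None = None,
    drug_prices_path: str | Path | None = None,
) -> CostingTables:
    tables = default_costing_tables()
    if unit_costs_path is not None:
        tables.unit_costs = read_unit_costs(unit_costs_path)
    if drug_prices_path is not None:
        tables.drug_prices = read_drug_prices(drug_prices_path)
    return validate_costing(tables)
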