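"""Resource-use costing and item-level missingness handling.

Converts reported health-care use and drug consumption into per-wave SEK
costs under a configurable funding scope.  1-month-recall and 3-month-recall
sums are kept separate throughout: they cover different spans of calendar
time and are aggregated with different weights downstream.

Item-level missingness (a participant responded to a wave but skipped an
item) is handled by last observation carried forward; a missing baseline
takes the next later value instead (carried backward).  The carry chains
across consecutive missing waves by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trial_data import (
    ITEM_COLUMNS,
    ITEMS,
    CostingTables,
    DrugPrice,
    TrialRecord,
    frames_to_records,
    records_to_frames,
)

logger = logging.getLogger(__name__)


def app_cost_per_user(total_cost_sek: float, downloads: int) -> float:
    """Intervention cost per user: total maintenance (and, for the upper
    bound, development) cost divided by the number of downloads."""
    if downloads <= 0:
        raise ConfigurationError("downloads must be positive")
    return total_cost_sek / downloads


# ---------------------------------------------------------------------------
# Item-level imputation (LOCF / NOCB)
# ---------------------------------------------------------------------------


def impute_items_frame(trial: pd.DataFrame, chain: bool = True) -> pd.DataFrame:
    """LOCF/NOCB imputation of item columns on the flat trial frame.

    Only responded waves are touched; non-responded waves stay absent.  With
    ``chain=False`` a value is carried at most one wave forward/backward.
    """
    out = trial.sort_values(["participant_id", "wave"], kind="stable").copy()
    resp = out["responded"].astype(bool).to_numpy()
    cols = list(ITEM_COLUMNS)
    limit = None if chain else 1
    sub = out.loc[resp, ["participant_id"] + cols]
    grouped = sub.groupby("participant_id", sort=False)[cols]
    filled = grouped.ffill(limit=limit)
    filled = filled.groupby(sub["participant_id"], sort=False).bfill(limit=limit)
    still_missing = filled.isna().any(axis=0)
    for col in filled.columns[still_missing]:
        pids = sub.loc[filled[col].isna(), "participant_id"].unique()
        logger.warning(
            "item %s missing at every responded wave for participants %s",
            col, list(pids),
        )
    out.loc[resp, cols] = filled.to_numpy()
    return out


def impute_items(records: Sequence[TrialRecord], chain: bool = True) -> list[TrialRecord]:
    """Record-level wrapper around :func:`impute_items_frame`."""
    trial, drugs = records_to_frames(records)
    return frames_to_records(impute_items_frame(trial, chain=chain), drugs)


# ---------------------------------------------------------------------------
# Costing
# ---------------------------------------------------------------------------


def cost_drugs(
    drug_entries: Iterable[tuple[str, float]],
    drug_prices: Mapping[str, DrugPrice],
) -> tuple[float, float]:
    """Sum drug costs per class: (related, unrelated) SEK."""
    related = unrelated = 0.0
    unknown = sorted({code for code, _ in drug_entries if code not in drug_prices})
    if unknown:
        raise ConfigurationError(f"no price for drug codes {unknown}")
    for code, units in drug_entries:
        price = drug_prices[code]
        if price.drug_class == "related":
            related += units * price.sek_per_unit
        else:
            unrelated += units * price.sek_per_unit
    return related, unrelated


def cost_use(
    use_counts: Mapping[int, float | None],
    tables: CostingTables,
    scope: str = "public",
) -> tuple[float, float]:
    """Cost the 13 use counts under a funding scope.

    Returns (1-month-recall SEK, 3-month-recall SEK); the two cover
    different time spans and are never added directly.  A count left absent
    (missing at every wave) contributes zero.
    """
    items = tables.scope_items(scope)
    c1 = c3 = 0.0
    for item in ITEMS:
        if item not in items:
            continue
        count = use_counts.get(item)
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        uc = tables.unit_costs[item]
        if uc.recall == "1mo":
            c1 += count * uc.sek_per_unit
        else:
            c3 += count * uc.sek_per_unit
    return c1, c3


def cost_waves(
    records: Sequence[TrialRecord], tables: CostingTables
) -> pd.DataFrame:
    """Per responded participant-wave cost summary (one row each)."""
    rows = []
    for rec in records:
        if not rec.responded:
            continue
        pub1, pub3 = cost_use(rec.use_counts, tables, "public")
        all1, all3 = cost_use(rec.use_counts, tables, "all")
        rel, unrel = cost_drugs(rec.drug_entries, tables.drug_prices)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "wave": rec.wave,
                "public_cost_1mo": pub1,
                "public_cost_3mo": pub3,
                "all_cost_1mo": all1,
                "all_cost_3mo": all3,
                "drug_cost_related": rel,
                "drug_cost_unrelated": unrel,
            }
        )
    return pd.DataFrame(rows)
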