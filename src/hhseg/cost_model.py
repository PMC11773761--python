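"""Cost-weighted utilisation: contacts -> person, household, per-capita cost.

Each contact row contributes ``n_contacts`` times its unit cost, where a
row-level override supersedes the configured sector tariff.  Household
costs are member sums; per-capita divides by all members, children and
adults alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hhseg.io_config import SECTORS, ConfigError, RunConfig


class CostModelError(ValueError):
    """Raised when a cost computation is undefined (e.g. zero total spend)."""


def cost_contacts(contacts: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-person annual cost by sector.

    Returns a frame indexed by ``person_id`` with one column per sector
    plus ``total``.  Persons appear only if they have contacts; callers
    treat absent persons as all-zero.
    """
    missing = set(SECTORS) - set(cfg.tariffs)
    if missing:
        raise ConfigError(f"no tariff configured for sector(s): {sorted(missing)}")

    df = contacts.copy()
    unit = df["sector"].map(cfg.tariffs).astype(float)
    override = pd.to_numeric(df["unit_cost_override"], errors="coerce")
    unit = override.where(override.notna(), unit)
    df["cost"] = df["n_contacts"].astype(float) * unit

    by_sector = (
        df.pivot_table(
            index="person_id", columns="sector", values="cost", aggfunc="sum"
        )
        .reindex(columns=list(SECTORS))
        .fillna(0.0)
    )
    by_sector.columns.name = None
    by_sector["total"] = by_sector[list(SECTORS)].sum(axis=1)
    return by_sector


def household_costs(
    households: pd.DataFrame, members: pd.DataFrame, person_costs: pd.DataFrame
) -> pd.DataFrame:
    """Household sector costs, totals and per-capita spend.

    ``households`` and ``members`` come from the household builder;
    ``person_costs`` from :func:`cost_contacts`.  Members without any
    contact cost zero.
    """
    cols = list(SECTORS) + ["total"]
    member_costs = (
        members[["person_id", "household_id"]]
        .merge(
            person_costs.reset_index(), on="person_id", how="left"
        )
        .fillna({c: 0.0 for c in cols})
    )
    hh = member_costs.groupby("household_id")[cols].sum()
    out = households.merge(hh, on="household_id", how="left").fillna(
        {c: 0.0 for c in cols}
    )
    out["per_capita"] = out["total"] / out["n_members"]
    return out


def nearest_rank_cutoff(values: np.ndarray | pd.Series, upper_fraction: float) -> float:
    """Threshold such that the top ``upper_fraction`` of values (nearest
    rank, ties inclusive) are >= the returned cutoff.

    With n values the cutoff is the ``ceil(upper_fraction * n)``-th
    largest value, so exactly that many values exceed or equal it, plus
    any ties at the threshold.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise CostModelError("cutoff undefined on empty input")
    k = int(np.ceil(upper_fraction * n))
    k = min(max(k, 1), n)
    return float(arr[n - k])


def cost_share_by_sector(
    segment_household_ids: pd.Series | list,
    household_cost_table: pd.DataFrame,
) -> pd.DataFrame:
    """Distribution of segment spend across sectors.

    Returns a frame with columns ``sector``, ``amount``, ``share`` where
    shares sum to 1 over the segment households' total spend.
    """
    seg = household_cost_table.loc[
        household_cost_table["household_id"].isin(set(segment_household_ids))
    ]
    amounts = seg[list(SECTORS)].sum()
    total = float(amounts.sum())
    if total <= 0:
        raise CostModelError("cost shares undefined: segment total spend is zero")
    return pd.DataFrame(
        {
            "sector": list(SECTORS),
            "amount": amounts.to_numpy(dtype=float),
            "share": amounts.to_numpy(dtype=float) / total,
        }
    )
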