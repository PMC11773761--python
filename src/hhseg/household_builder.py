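"""Derive analysis households from pseudonymised address identifiers.

People sharing an address identifier form one household.  Address groups
larger than the configured maximum are dropped wholesale (they likely
represent institutions or multi-occupancy buildings), and people with no
address link are dropped and counted — both exclusions are returned in a
run log rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from hhseg.io_config import RunConfig

logger = logging.getLogger(__name__)

HOUSEHOLD_COLUMNS = (
    "household_id",
    "n_members",
    "n_children",
    "n_adults",
    "imd_score",
)


@dataclass(frozen=True)
class BuildLog:
    """Exclusion accounting for one household-derivation run."""

    n_persons_in: int
    n_missing_household_id: int
    n_in_oversize_households: int
    n_oversize_households: int
    n_imd_discrepant_households: int
    n_households_out: int


def build_households(
    persons: pd.DataFrame, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, BuildLog]:
    """Group persons into households and apply the size exclusion.

    Returns ``(households, members, log)`` where ``households`` has one
    row per retained household (id, member counts, deprivation score)
    and ``members`` is the retained person table augmented with an
    ``is_child`` column.  Household deprivation is the mean of members'
    area scores; since all members share an address these should agree,
    and households where they do not are counted in the log.
    """
    child_max = cfg.thresholds.child_age_max
    missing = persons["household_id"].isna()
    linked = persons.loc[~missing].copy()

    sizes = linked.groupby("household_id")["person_id"].size()
    oversize_ids = sizes.index[sizes > cfg.thresholds.max_household_size]
    retained = linked.loc[~linked["household_id"].isin(oversize_ids)].copy()
    retained["is_child"] = retained["age"] <= child_max

    grouped = retained.groupby("household_id", sort=True)
    households = pd.DataFrame(
        {
            "n_members": grouped["person_id"].size(),
            "n_children": grouped["is_child"].sum().astype(int),
            "imd_score": grouped["imd_score"].mean(),
        }
    )
    households["n_adults"] = households["n_members"] - households["n_children"]
    n_discrepant = int((grouped["imd_score"].nunique(dropna=True) > 1).sum())
    households = households.reset_index()[list(HOUSEHOLD_COLUMNS)]

    log = BuildLog(
        n_persons_in=len(persons),
        n_missing_household_id=int(missing.sum()),
        n_in_oversize_households=int(sizes.loc[oversize_ids].sum()),
        n_oversize_households=len(oversize_ids),
        n_imd_discrepant_households=n_discrepant,
        n_households_out=len(households),
    )
    if log.n_missing_household_id or log.n_oversize_households:
        logger.info(
            "household build: dropped %d persons with no address link, "
            "%d households (> %d members, %d persons)",
            log.n_missing_household_id,
            log.n_oversize_households,
            cfg.thresholds.max_household_size,
            log.n_in_oversize_households,
        )
    if n_discrepant:
        logger.warning(
            "household build: %d households with discrepant member IMD scores",
            n_discrepant,
        )
    return households, retained.reset_index(drop=True), log


def households_with_children(
    households: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Restrict to households with at least one child (age 0..child_age_max)."""
    return households.loc[households["n_children"] >= 1].reset_index(drop=True)
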