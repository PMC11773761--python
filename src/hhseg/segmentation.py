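"""The four-criterion complex-household rule set.

A household with children enters the segment when, simultaneously:

1. at least one adult carries a physical long-term condition AND at
   least one adult (possibly a different one) carries a mental health
   condition;
2. at least one child carries a health/social problem code or an
   in-care marker;
3. at least one social-vulnerability indicator holds (homelessness,
   frequent A&E use, substance abuse, lone parenthood, a child in care,
   area deprivation, or use of three or more distinct care sectors);
4. per-capita cost-weighted utilisation lies in the top spend quantile
   of households with children.

Criteria are evaluated vectorised over households; a deliberately naive
per-household re-reading of the same definition lives in
``tests`` as the oracle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hhseg.cost_model import cost_contacts, household_costs, nearest_rank_cutoff
from hhseg.household_builder import build_households, households_with_children
from hhseg.io_config import RunConfig

logger = logging.getLogger(__name__)

SUBFLAG_COLUMNS = (
    "homelessness",
    "high_ae",
    "substance_abuse",
    "lone_parent",
    "child_in_care",
    "deprived",
    "multi_service",
)

SEGMENT_COLUMNS = (
    ("household_id",)
    + ("c1_adult_phys_and_mental", "c2_child_problem")
    + SUBFLAG_COLUMNS
    + ("c3_vulnerability", "c4_top_spend", "per_capita_cost", "in_segment")
)


def _households_with_any(
    members: pd.DataFrame,
    person_ids_with_attr: set[str],
    member_mask: pd.Series | None = None,
) -> set[str]:
    """Household ids containing >=1 (optionally masked) member with the attribute."""
    mask = members["person_id"].isin(person_ids_with_attr)
    if member_mask is not None:
        mask &= member_mask
    return set(members.loc[mask, "household_id"])


def _persons_with_codes(conditions: pd.DataFrame, codes: frozenset[str]) -> set[str]:
    return set(conditions.loc[conditions["condition_code"].isin(codes), "person_id"])


def eval_condition1(
    members: pd.DataFrame, conditions: pd.DataFrame, cfg: RunConfig
) -> pd.Series:
    """Adults with physical and mental conditions (possibly different adults).

    Returns a boolean Series indexed by household_id.
    """
    adults = ~members["is_child"]
    phys = _persons_with_codes(conditions, frozenset(cfg.physical_conditions))
    ment = _persons_with_codes(conditions, frozenset(cfg.mental_conditions))
    hh_phys = _households_with_any(members, phys, adults)
    hh_ment = _households_with_any(members, ment, adults)
    idx = pd.Index(members["household_id"].unique(), name="household_id").sort_values()
    return pd.Series(
        [h in hh_phys and h in hh_ment for h in idx], index=idx, dtype=bool
    )


def eval_condition2(
    members: pd.DataFrame, conditions: pd.DataFrame, cfg: RunConfig
) -> pd.Series:
    """A child with any health/social problem or an in-care marker."""
    children = members["is_child"]
    problem = _persons_with_codes(
        conditions, frozenset(cfg.child_problem_conditions or ())
    )
    in_care = _persons_with_codes(
        conditions, frozenset(cfg.vulnerability_codes["child_in_care"])
    )
    hit = _households_with_any(members, problem | in_care, children)
    idx = pd.Index(members["household_id"].unique(), name="household_id").sort_values()
    return pd.Series([h in hit for h in idx], index=idx, dtype=bool)


def eval_condition3(
    households: pd.DataFrame,
    members: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    cfg: RunConfig,
    region_deprivation_cutoff: float | None,
) -> pd.DataFrame:
    """Social-vulnerability sub-flags; the condition is their disjunction.

    ``region_deprivation_cutoff`` is the precomputed score at/above which
    an address falls in the most-deprived quantile; ``None`` disables the
    deprivation sub-flag (all False, logged).
    """
    hh = households.set_index("household_id")
    idx = hh.index

    homeless_p = _persons_with_codes(
        conditions, frozenset(cfg.vulnerability_codes["homelessness"])
    )
    substance_p = _persons_with_codes(
        conditions, frozenset(cfg.vulnerability_codes["substance_abuse"])
    )
    in_care_p = _persons_with_codes(
        conditions, frozenset(cfg.vulnerability_codes["child_in_care"])
    )

    ae = contacts.loc[contacts["sector"] == "ae"]
    ae_counts = ae.groupby("person_id")["n_contacts"].sum()
    high_ae_p = set(ae_counts.index[ae_counts > cfg.thresholds.ae_visits_per_year])

    out = pd.DataFrame(index=idx)
    out["homelessness"] = idx.isin(_households_with_any(members, homeless_p))
    out["high_ae"] = idx.isin(_households_with_any(members, high_ae_p))
    out["substance_abuse"] = idx.isin(_households_with_any(members, substance_p))
    out["lone_parent"] = (hh["n_adults"] == 1) & (hh["n_children"] >= 1)
    out["child_in_care"] = idx.isin(
        _households_with_any(members, in_care_p, members["is_child"])
    )

    if region_deprivation_cutoff is None:
        n_missing = int(hh["imd_score"].isna().sum())
        if n_missing:
            logger.info("deprivation flag disabled; %d households unscored", n_missing)
        out["deprived"] = False
    else:
        imd = hh["imd_score"]
        if imd.isna().any():
            logger.info(
                "deprived sub-flag false for %d households with missing imd_score",
                int(imd.isna().sum()),
            )
        out["deprived"] = (imd >= region_deprivation_cutoff).fillna(False).astype(bool)

    sectors_used = (
        contacts.merge(members[["person_id", "household_id"]], on="person_id")
        .groupby("household_id")["sector"]
        .nunique()
    )
    out["multi_service"] = (
        sectors_used.reindex(idx).fillna(0).astype(int)
        >= cfg.thresholds.distinct_services_min
    )
    out["c3_vulnerability"] = out[list(SUBFLAG_COLUMNS)].any(axis=1)
    return out


def eval_condition4(
    per_capita: pd.Series, cfg: RunConfig
) -> tuple[pd.Series, float]:
    """Top spend-quantile flag over the supplied per-capita costs.

    The cutoff is the nearest-rank threshold such that the top
    ``1 - spend_quantile`` fraction of households (ties included) are
    flagged.  Requires at least 4 households.
    """
    if len(per_capita) < 4:
        raise ValueError(
            f"spend quantile undefined on {len(per_capita)} households (< 4)"
        )
    cutoff = nearest_rank_cutoff(per_capita, 1.0 - cfg.thresholds.spend_quantile)
    return (per_capita >= cutoff).astype(bool), cutoff


def deprivation_cutoff(
    households: pd.DataFrame, cfg: RunConfig
) -> float | None:
    """Score cutoff for the most-deprived quantile of the supplied households.

    Computed empirically over the household deprivation scores (higher =
    more deprived); returns None when no household carries a score.
    """
    scores = households["imd_score"].dropna()
    if scores.empty:
        return None
    return nearest_rank_cutoff(scores, cfg.thresholds.deprivation_quantile)


def segment_households(
    households: pd.DataFrame,
    members: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    household_cost_table: pd.DataFrame,
    cfg: RunConfig,
    region_deprivation_cutoff: float | None = None,
    enabled_criteria: tuple[bool, bool, bool, bool] = (True, True, True, True),
) -> pd.DataFrame:
    """Evaluate all four criteria on households with children.

    ``households``/``members`` are the child-containing cohort from the
    household builder; ``household_cost_table`` comes from
    :func:`hhseg.cost_model.household_costs` over the same cohort (it is
    the spend-quantile population).  ``enabled_criteria`` allows
    switching individual criteria off (treated as satisfied) for
    monotonicity audits.

    Returns one row per household: criterion flags, Condition-3
    sub-flags, per-capita cost and the final ``in_segment`` indicator.
    """
    if region_deprivation_cutoff is None:
        region_deprivation_cutoff = deprivation_cutoff(households, cfg)

    idx = pd.Index(households["household_id"], name="household_id").sort_values()
    members = members.loc[members["household_id"].isin(idx)]
    c1 = eval_condition1(members, conditions, cfg).reindex(idx, fill_value=False)
    c2 = eval_condition2(members, conditions, cfg).reindex(idx, fill_value=False)
    c3_frame = (
        eval_condition3(
            households, members, conditions, contacts, cfg, region_deprivation_cutoff
        )
        .reindex(idx)
        .fillna(False)
    )
    per_capita = (
        household_cost_table.set_index("household_id")["per_capita"]
        .reindex(idx)
        .fillna(0.0)
    )
    c4, spend_cutoff = eval_condition4(per_capita, cfg)

    out = pd.DataFrame(index=idx)
    out["c1_adult_phys_and_mental"] = c1
    out["c2_child_problem"] = c2
    for col in SUBFLAG_COLUMNS:
        out[col] = c3_frame[col].astype(bool)
    out["c3_vulnerability"] = c3_frame["c3_vulnerability"].astype(bool)
    out["c4_top_spend"] = c4
    out["per_capita_cost"] = per_capita

    e1, e2, e3, e4 = enabled_criteria
    out["in_segment"] = (
        (c1 | (not e1))
        & (c2 | (not e2))
        & (out["c3_vulnerability"] | (not e3))
        & (c4 | (not e4))
    )
    out = out.reset_index()
    out.attrs["spend_cutoff"] = spend_cutoff
    out.attrs["deprivation_cutoff"] = region_deprivation_cutoff
    logger.info(
        "segmentation: %d/%d households with children in segment",
        int(out["in_segment"].sum()),
        len(out),
    )
    return out


def run_segmentation(
    persons: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """End-to-end convenience wrapper: persons -> segment table.

    Returns a dict with the built households, child-cohort, member
    table, person/household cost tables, segment table and the build
    log — the working set every report consumes.
    """
    households, members, build_log = build_households(persons, cfg)
    cohort = households_with_children(households, cfg)
    cohort_members = members.loc[
        members["household_id"].isin(set(cohort["household_id"]))
    ].reset_index(drop=True)
    person_costs = cost_contacts(contacts, cfg)
    hh_costs = household_costs(cohort, cohort_members, person_costs)
    segments = segment_households(
        cohort, cohort_members, conditions, contacts, hh_costs, cfg
    )
    return {
        "households": households,
        "cohort": cohort,
        "members": members,
        "cohort_members": cohort_members,
        "person_costs": person_costs,
        "household_costs": hh_costs,
        "segments": segments,
        "build_log": build_log,
    }
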