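"""Descriptive profiling of the segment versus other households with children.

Produces the criteria table (counts and percentages of households
satisfying each criterion and sub-flag, split total/other/complex), the
condition-prevalence and demographics comparison, household-size and
age/sex summaries, service co-use intersections, and the mental-health
service-use breakdowns.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from hhseg.io_config import MH_REASON_CLASSES, SECTORS, RunConfig
from hhseg.segmentation import SUBFLAG_COLUMNS

#: Default age banding for age-stratified outputs.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (0, 4),
    (5, 11),
    (12, 16),
    (17, 24),
    (25, 44),
    (45, 64),
    (65, 200),
)

CRITERIA_ROWS: tuple[tuple[str, str], ...] = (
    ("c1_adult_phys_and_mental", "criterion_1_adult_physical_and_mental"),
    ("c2_child_problem", "criterion_2_child_problem"),
    ("c3_vulnerability", "criterion_3_any_vulnerability"),
    ("homelessness", "c3_homelessness"),
    ("high_ae", "c3_high_ae"),
    ("substance_abuse", "c3_substance_abuse"),
    ("lone_parent", "c3_lone_parent"),
    ("child_in_care", "c3_child_in_care"),
    ("deprived", "c3_deprived"),
    ("multi_service", "c3_multi_service"),
    ("c4_top_spend", "criterion_4_top_spend"),
)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with .5 always going up (not banker's)."""
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def table_percent(count: int, denom: int) -> float:
    """Percentage styled like the criteria table: whole numbers, with
    small cells keeping one decimal below 2% and two below 0.05%."""
    if denom == 0:
        return 0.0
    pct = 100.0 * count / denom
    if pct < 0.05:
        return round_half_up(pct, 2)
    if pct < 2.0:
        return round_half_up(pct, 1)
    return round_half_up(pct, 0)


def _band_label(lo: int, hi: int) -> str:
    return f"{lo}+" if hi >= 200 else f"{lo}-{hi}"


def age_band(ages: pd.Series) -> pd.Series:
    """Map ages onto the configured band labels."""
    bins = [b[0] for b in AGE_BANDS] + [np.inf]
    labels = [_band_label(*b) for b in AGE_BANDS]
    return pd.cut(ages, bins=bins, labels=labels, right=False, include_lowest=True)


def criteria_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of households satisfying each criterion,
    for all households with children, the non-segment remainder, and the
    segment."""
    in_seg = segments["in_segment"]
    n_total, n_complex = len(segments), int(in_seg.sum())
    n_other = n_total - n_complex
    rows = []
    for col, label in CRITERIA_ROWS:
        flag = segments[col].astype(bool)
        t = int(flag.sum())
        c = int((flag & in_seg).sum())
        o = t - c
        rows.append(
            {
                "criterion": label,
                "total_count": t,
                "total_pct": table_percent(t, n_total),
                "other_count": o,
                "other_pct": table_percent(o, n_other),
                "complex_count": c,
                "complex_pct": table_percent(c, n_complex),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_total"] = n_total
    out.attrs["n_other"] = n_other
    out.attrs["n_complex"] = n_complex
    return out


def _person_groups(
    members: pd.DataFrame, segments: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Cohort member table with ``group`` (complex/other) and ``is_child``."""
    complex_ids = set(segments.loc[segments["in_segment"], "household_id"])
    cohort_ids = set(segments["household_id"])
    out = members.loc[members["household_id"].isin(cohort_ids)].copy()
    out["group"] = np.where(
        out["household_id"].isin(complex_ids), "complex", "other"
    )
    out["is_child"] = out["age"] <= cfg.thresholds.child_age_max
    return out


def prevalence_table(
    members: pd.DataFrame,
    conditions: pd.DataFrame,
    segments: pd.DataFrame,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Per-condition prevalence (%) for children and adults in complex vs
    other households, with group demographic summaries appended."""
    people = _person_groups(members, segments, cfg)
    flags = conditions.loc[conditions["person_id"].isin(set(people["person_id"]))]
    carriers = flags.groupby("condition_code")["person_id"].apply(set)

    rows = []
    groups = {
        (cls, grp): set(
            people.loc[
                (people["is_child"] == (cls == "children"))
                & (people["group"] == grp),
                "person_id",
            ]
        )
        for cls in ("children", "adults")
        for grp in ("complex", "other")
    }
    all_codes = sorted(set(cfg.physical_conditions) | set(cfg.mental_conditions))
    for code in all_codes:
        holders = carriers.get(code, set())
        row = {"condition": code}
        for (cls, grp), ids in groups.items():
            denom = len(ids)
            row[f"{cls}_{grp}_pct"] = (
                100.0 * len(holders & ids) / denom if denom else 0.0
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    demo_rows = []
    for cls in ("children", "adults"):
        for grp in ("complex", "other"):
            sub = people.loc[
                (people["is_child"] == (cls == "children")) & (people["group"] == grp)
            ]
            demo_rows.append(
                {
                    "class": cls,
                    "group": grp,
                    "n": len(sub),
                    "age_mean": sub["age"].mean(),
                    "age_sd": sub["age"].std(),
                    "pct_male": 100.0 * (sub["sex"] == "M").mean() if len(sub) else 0.0,
                    "imd_mean": sub["imd_score"].mean(),
                }
            )
    table.attrs["demographics"] = pd.DataFrame(demo_rows)
    return table


def size_summary(segments: pd.DataFrame, households: pd.DataFrame) -> pd.DataFrame:
    """Mean household size for the complex and other groups."""
    merged = households.merge(
        segments[["household_id", "in_segment"]], on="household_id"
    )
    merged["group"] = np.where(merged["in_segment"], "complex", "other")
    return (
        merged.groupby("group")["n_members"]
        .agg(n="size", mean_size="mean")
        .reset_index()
    )


def age_sex_density(
    members: pd.DataFrame, segments: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Person counts by age band x sex x group."""
    people = _person_groups(members, segments, cfg)
    people["band"] = age_band(people["age"])
    out = (
        people.groupby(["group", "band", "sex"], observed=False)["person_id"]
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def service_intersections(
    members: pd.DataFrame, contacts: pd.DataFrame, segments: pd.DataFrame
) -> pd.DataFrame:
    """Complex-household counts per exact used-sector subset, plus
    per-sector marginals (UpSet-style input)."""
    complex_ids = set(segments.loc[segments["in_segment"], "household_id"])
    seg_members = members.loc[members["household_id"].isin(complex_ids)]
    used = (
        contacts.merge(seg_members[["person_id", "household_id"]], on="person_id")
        .groupby("household_id")["sector"]
        .agg(lambda s: "|".join(sorted(set(s))))
    )
    no_use = complex_ids - set(used.index)
    subsets = used.value_counts().rename_axis("sectors").rename("n_households")
    if no_use:
        subsets.loc[""] = len(no_use)
    out = subsets.reset_index().sort_values(
        ["n_households", "sectors"], ascending=[False, True]
    )
    marginals = {
        s: int(sum(1 for subset in used for _ in [None] if s in subset.split("|")))
        for s in SECTORS
    }
    out.attrs["sector_marginals"] = marginals
    out.attrs["n_complex_households"] = len(complex_ids)
    return out.reset_index(drop=True)


def mh_breakdowns(
    members: pd.DataFrame,
    contacts: pd.DataFrame,
    segments: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mental-health service use by reason class (complex vs other), and
    emergency mental-health attendance counts by age band and sex within
    complex households."""
    people = _person_groups(members, segments, cfg)
    joined = contacts.merge(
        people[["person_id", "group", "age", "sex"]], on="person_id"
    )

    mh = joined.loc[
        (joined["sector"] == "mental_health")
        | joined["reason_class"].isin(MH_REASON_CLASSES)
    ]
    reason = (
        mh.groupby(["group", "reason_class"])["n_contacts"]
        .sum()
        .rename("contact_count")
        .reset_index()
    )

    ae_mh = joined.loc[
        joined["emergency"]
        & joined["reason_class"].isin(MH_REASON_CLASSES)
        & (joined["group"] == "complex")
    ].copy()
    ae_mh["band"] = age_band(ae_mh["age"])
    by_age_sex = (
        ae_mh.groupby(["band", "sex"], observed=False)["n_contacts"]
        .sum()
        .rename("attendances")
        .reset_index()
    )
    return reason, by_age_sex
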