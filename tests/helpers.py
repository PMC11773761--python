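"""Test helpers: table builders and a deliberately naive oracle.

The oracle re-reads the four-criterion household definition literally,
one household at a time, with plain Python loops and dicts — no shared
code with the vectorised implementation beyond the config object.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from hhseg.io_config import RunConfig

PERSON_DEFAULTS = {
    "household_id": None,
    "age": 30,
    "sex": "F",
    "ethnicity": "white",
    "imd_score": 0.3,
    "registered": True,
}
CONTACT_DEFAULTS = {
    "sector": "primary_care",
    "reason_class": "other",
    "emergency": False,
    "n_contacts": 1,
    "unit_cost_override": np.nan,
}


def persons_df(rows: list[dict]) -> pd.DataFrame:
    out = []
    for i, row in enumerate(rows):
        rec = dict(PERSON_DEFAULTS)
        rec.setdefault("person_id", f"p{i}")
        rec.update(row)
        rec.setdefault("person_id", f"p{i}")
        out.append(rec)
    df = pd.DataFrame(out)
    cols = ["person_id", "household_id", "age", "sex", "ethnicity",
            "imd_score", "registered"]
    return df[cols]


def conditions_df(rows: list[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["person_id", "condition_code"])


def contacts_df(rows: list[dict]) -> pd.DataFrame:
    out = []
    for row in rows:
        rec = dict(CONTACT_DEFAULTS)
        rec.update(row)
        out.append(rec)
    cols = ["person_id", "sector", "reason_class", "emergency",
            "n_contacts", "unit_cost_override"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out)[cols]


def _upper_cutoff(values: list[float], upper_fraction: float) -> float:
    vals = sorted(values)
    n = len(vals)
    k = int(math.ceil(upper_fraction * n))
    k = min(max(k, 1), n)
    return vals[n - k]


def oracle_segment(
    persons: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    cfg: RunConfig,
) -> dict[str, dict[str, bool]]:
    """Per-household literal evaluation of the definition.

    Returns {household_id: {c1, c2, c3, c4, in_segment, ...subflags}}
    over households with children only.
    """
    th = cfg.thresholds

    # 1. group people by address id, dropping unlinked people
    groups: dict[str, list[dict]] = {}
    for rec in persons.to_dict("records"):
        hid = rec["household_id"]
        if hid is None or (isinstance(hid, float) and math.isnan(hid)) or pd.isna(hid):
            continue
        groups.setdefault(str(hid), []).append(rec)

    # 2. wholesale drop of oversize address groups
    groups = {h: ms for h, ms in groups.items() if len(ms) <= th.max_household_size}

    # 3. restrict to households with at least one child
    def is_child(rec):
        return rec["age"] <= th.child_age_max

    cohort = {h: ms for h, ms in groups.items() if any(is_child(m) for m in ms)}

    # person -> set of codes
    codes: dict[str, set] = {}
    for rec in conditions.to_dict("records"):
        codes.setdefault(rec["person_id"], set()).add(rec["condition_code"])

    # person costs and sector use, naive double loop
    person_cost: dict[str, float] = {}
    person_sectors: dict[str, set] = {}
    person_ae: dict[str, int] = {}
    for rec in contacts.to_dict("records"):
        pid = rec["person_id"]
        unit = rec["unit_cost_override"]
        if unit is None or (isinstance(unit, float) and math.isnan(unit)):
            unit = cfg.tariffs[rec["sector"]]
        person_cost[pid] = person_cost.get(pid, 0.0) + rec["n_contacts"] * unit
        person_sectors.setdefault(pid, set()).add(rec["sector"])
        if rec["sector"] == "ae":
            person_ae[pid] = person_ae.get(pid, 0) + rec["n_contacts"]

    per_capita = {
        h: sum(person_cost.get(m["person_id"], 0.0) for m in ms) / len(ms)
        for h, ms in cohort.items()
    }

    imd_of = {}
    for h, ms in cohort.items():
        scores = [m["imd_score"] for m in ms
                  if m["imd_score"] is not None and not pd.isna(m["imd_score"])]
        imd_of[h] = sum(scores) / len(scores) if scores else None
    scored = [v for v in imd_of.values() if v is not None]
    depr_cut = _upper_cutoff(scored, th.deprivation_quantile) if scored else None
    spend_cut = _upper_cutoff(list(per_capita.values()), 1.0 - th.spend_quantile)

    phys = set(cfg.physical_conditions)
    ment = set(cfg.mental_conditions)
    child_prob = set(cfg.child_problem_conditions or ())
    homeless = set(cfg.vulnerability_codes["homelessness"])
    substance = set(cfg.vulnerability_codes["substance_abuse"])
    in_care = set(cfg.vulnerability_codes["child_in_care"])

    out = {}
    for h, ms in cohort.items():
        adults = [m for m in ms if not is_child(m)]
        children = [m for m in ms if is_child(m)]
        pcodes = lambda m: codes.get(m["person_id"], set())

        c1 = any(pcodes(a) & phys for a in adults) and any(
            pcodes(a) & ment for a in adults
        )
        c2 = any(pcodes(c) & (child_prob | in_care) for c in children)
        sub = {
            "homelessness": any(pcodes(m) & homeless for m in ms),
            "high_ae": any(
                person_ae.get(m["person_id"], 0) > th.ae_visits_per_year for m in ms
            ),
            "substance_abuse": any(pcodes(m) & substance for m in ms),
            "lone_parent": len(adults) == 1 and len(children) >= 1,
            "child_in_care": any(pcodes(c) & in_care for c in children),
            "deprived": (
                depr_cut is not None
                and imd_of[h] is not None
                and imd_of[h] >= depr_cut
            ),
            "multi_service": len(
                set().union(*(person_sectors.get(m["person_id"], set()) for m in ms))
            ) >= th.distinct_services_min,
        }
        c3 = any(sub.values())
        c4 = per_capita[h] >= spend_cut
        out[h] = {
            "c1": c1, "c2": c2, "c3": c3, "c4": c4,
            "in_segment": c1 and c2 and c3 and c4,
            **sub,
        }
    return out


def random_small_population(rng: np.random.Generator, n_households: int):
    """A randomized tiny population exercising every rule branch."""
    persons, conditions, contacts = [], [], []
    pid = 0
    all_codes = ["asthma", "depression", "anxiety", "diabetes",
                 "homelessness", "substance_abuse", "child_in_care",
                 "learning_disability", "epilepsy"]
    sectors = ["primary_care", "ae", "inpatient", "outpatient",
               "mental_health", "community", "adult_social_care",
               "children_social_care"]
    for h in range(n_households):
        size = int(rng.integers(1, 13))  # sometimes oversize (dropped)
        imd = round(float(rng.random()), 3) if rng.random() > 0.1 else np.nan
        for _ in range(size):
            age = int(rng.integers(0, 90))
            persons.append({
                "person_id": f"p{pid}",
                "household_id": f"h{h}" if rng.random() > 0.05 else None,
                "age": age,
                "sex": rng.choice(["M", "F"]),
                "ethnicity": "white",
                "imd_score": imd,
                "registered": True,
            })
            for code in all_codes:
                if rng.random() < 0.12:
                    conditions.append((f"p{pid}", code))
            for sector in sectors:
                if rng.random() < 0.25:
                    contacts.append({
                        "person_id": f"p{pid}",
                        "sector": sector,
                        "reason_class": "other",
                        "emergency": bool(sector == "ae"),
                        "n_contacts": int(rng.integers(1, 9)),
                        "unit_cost_override": (
                            float(rng.integers(10, 500))
                            if rng.random() < 0.2 else np.nan
                        ),
                    })
            pid += 1
    return (
        persons_df(persons),
        conditions_df(conditions) if conditions
        else pd.DataFrame(columns=["person_id", "condition_code"]),
        contacts_df(contacts),
    )
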