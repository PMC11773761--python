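"""Unmet-need contrast: emergency mental-health attendance odds, complex
versus other households, stratified by prior mental-health engagement.

High odds of emergency attendance among people with *no* prior contact
point to needs not being met upstream.  The 2x2 odds ratio is computed
in closed form with a Wald interval and cross-checked against a
saturated log-linear (Poisson) fit; both routes must agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from hhseg.io_config import MH_REASON_CLASSES, RunConfig

STRATA = ("no_prior_contact", "known_to_services")


class DegenerateTableError(ValueError):
    """A 2x2 cell (or margin) is zero, so the odds ratio is undefined."""


@dataclass(frozen=True)
class StratumTable:
    """One stratum's 2x2 table and odds-ratio estimate.

    Cells: a = complex with event, b = complex without, c = other with
    event, d = other without.
    """

    stratum: str
    a: int
    b: int
    c: int
    d: int
    or_estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def classify_persons(
    members: pd.DataFrame,
    contacts: pd.DataFrame,
    conditions: pd.DataFrame,
    segments: pd.DataFrame,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Per-person stratum, exposure and outcome for the contrast.

    Known to services = any non-emergency mental-health sector contact
    or any mental-condition diagnosis flag.  Outcome = any emergency
    contact (A&E or admission) with a mental-health reason class in the
    year.  Exposure = living in a segment household.
    """
    cohort_ids = set(segments["household_id"])
    complex_ids = set(segments.loc[segments["in_segment"], "household_id"])
    people = members.loc[members["household_id"].isin(cohort_ids)].copy()

    prior = set(
        contacts.loc[
            (contacts["sector"] == "mental_health") & ~contacts["emergency"],
            "person_id",
        ]
    )
    diagnosed = set(
        conditions.loc[
            conditions["condition_code"].isin(cfg.mental_conditions), "person_id"
        ]
    )
    events = set(
        contacts.loc[
            contacts["emergency"]
            & contacts["reason_class"].isin(MH_REASON_CLASSES),
            "person_id",
        ]
    )
    people["stratum"] = np.where(
        people["person_id"].isin(prior | diagnosed),
        "known_to_services",
        "no_prior_contact",
    )
    people["in_complex_household"] = people["household_id"].isin(complex_ids)
    people["emergency_mh_event"] = people["person_id"].isin(events)
    return people[
        ["person_id", "stratum", "in_complex_household", "emergency_mh_event"]
    ]


def build_strata(
    members: pd.DataFrame,
    contacts: pd.DataFrame,
    conditions: pd.DataFrame,
    segments: pd.DataFrame,
    cfg: RunConfig,
    continuity_correction: bool = False,
) -> list[StratumTable]:
    """2x2 tables (with OR and 95% CI) for both prior-contact strata."""
    people = classify_persons(members, contacts, conditions, segments, cfg)
    return strata_from_classification(people, continuity_correction)


def strata_from_classification(
    people: pd.DataFrame, continuity_correction: bool = False
) -> list[StratumTable]:
    """Build the stratum tables from a per-person classification frame
    (columns ``stratum``, ``in_complex_household``, ``emergency_mh_event``)."""
    out = []
    for stratum in STRATA:
        sub = people.loc[people["stratum"] == stratum]
        a = int((sub["in_complex_household"] & sub["emergency_mh_event"]).sum())
        b = int((sub["in_complex_household"] & ~sub["emergency_mh_event"]).sum())
        c = int((~sub["in_complex_household"] & sub["emergency_mh_event"]).sum())
        d = int((~sub["in_complex_household"] & ~sub["emergency_mh_event"]).sum())
        try:
            or_est, lo, hi = estimate_or(
                (a, b, c, d), continuity_correction=continuity_correction
            )
            degenerate = False
        except DegenerateTableError:
            or_est = lo = hi = float("nan")
            degenerate = True
        out.append(StratumTable(stratum, a, b, c, d, or_est, lo, hi, degenerate))
    return out


def estimate_or(
    cells: tuple[int, int, int, int], continuity_correction: bool = False
) -> tuple[float, float, float]:
    """Odds ratio and Wald 95% CI for a 2x2 table (a, b, c, d).

    With ``continuity_correction`` a Haldane–Anscombe 0.5 is added to
    every cell when any cell is zero; otherwise a zero cell raises
    :class:`DegenerateTableError`.
    """
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    if a + b + c + d <= 0:
        raise DegenerateTableError("empty table")
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            raise DegenerateTableError(
                f"zero cell in 2x2 table {cells}; "
                "enable continuity_correction to proceed"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_est)
    return (
        float(or_est),
        float(np.exp(log_or - 1.96 * se)),
        float(np.exp(log_or + 1.96 * se)),
    )


def estimate_or_loglinear(
    cells: tuple[int, int, int, int]
) -> tuple[float, float, float]:
    """Odds ratio via a saturated log-linear Poisson fit on the 2x2 counts.

    The interaction coefficient of the saturated model equals the log
    odds ratio; this provides the independent second route against the
    closed form.
    """
    a, b, c, d = cells
    if min(a, b, c, d) <= 0:
        raise DegenerateTableError(f"zero cell in 2x2 table {cells}")
    counts = np.array([a, b, c, d], dtype=float)
    exposed = np.array([1, 1, 0, 0], dtype=float)
    event = np.array([1, 0, 1, 0], dtype=float)
    X = np.column_stack([np.ones(4), exposed, event, exposed * event])
    with warnings.catch_warnings():
        # the saturated fit has zero residual df; statsmodels warns noisily
        warnings.simplefilter("ignore")
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit(
            tol=1e-12, maxiter=200
        )
    log_or = fit.params[3]
    se = fit.bse[3]
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - 1.96 * se)),
        float(np.exp(log_or + 1.96 * se)),
    )


def strata_report(tables: list[StratumTable]) -> pd.DataFrame:
    """Flatten stratum tables into the ``strata.csv`` layout."""
    return pd.DataFrame(
        [
            {
                "stratum": t.stratum,
                "complex_event": t.a,
                "complex_no_event": t.b,
                "other_event": t.c,
                "other_no_event": t.d,
                "odds_ratio": t.or_estimate,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "degenerate": t.degenerate,
            }
            for t in tables
        ]
    )
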