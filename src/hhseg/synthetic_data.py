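"""Synthetic linked person/condition/contact generator with planted truth.

Households are sampled size-first, then member ages, then per-person
condition flags (a bivariate Bernoulli couples mental and physical flags
within adults at a configured log-odds), then per-sector contact counts
from Poisson rates.  A configurable fraction of households is *planted*
as complex: they are forced to satisfy the first three segmentation
criteria deterministically and their contact rates are inflated so that
most land in the top spend quantile — but the quantile itself is always
computed, never planted, so recovering the planted labels genuinely
exercises the spend-quartile logic.

All randomness flows from a single seeded generator; identical config
and seed yield byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from hhseg.io_config import (
    DEFAULT_MENTAL_CONDITIONS,
    DEFAULT_PHYSICAL_CONDITIONS,
    CONDITION_COLUMNS,
    CONTACT_COLUMNS,
    PERSON_COLUMNS,
)

#: Mean annual contact-row rates per person and sector (before inflation).
BASE_SECTOR_RATES: dict[str, float] = {
    "primary_care": 2.0,
    "ae": 0.25,
    "inpatient": 0.06,
    "outpatient": 0.7,
    "mental_health": 0.25,
    "community": 0.6,
    "adult_social_care": 0.04,
    "children_social_care": 0.04,
}

DEFAULT_SIZE_DIST: dict[int, float] = {
    1: 0.18,
    2: 0.28,
    3: 0.22,
    4: 0.18,
    5: 0.08,
    6: 0.04,
    7: 0.01,
    8: 0.01,
}

_ETHNICITIES = ("white", "asian", "black", "mixed", "other")
_ETHNICITY_P = (0.85, 0.07, 0.04, 0.03, 0.01)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generator.

    Prevalence pairs are ``(planted_complex, other)``.  ``seed`` drives
    every random draw.
    """

    n_households: int = 1000
    planted_complex_fraction: float = 0.08
    household_size_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DIST)
    )
    child_fraction_target: float = 0.35
    adult_physical_prev: tuple[float, float] = (0.9, 0.15)
    adult_mental_prev: tuple[float, float] = (0.9, 0.10)
    child_problem_prev: tuple[float, float] = (0.9, 0.08)
    comorbidity_log_odds: float = 1.0
    sector_rate_multiplier_complex: float = 6.0
    planted_unmet_need_or: float = 6.8
    known_unmet_need_or: float = 2.0
    emergency_mh_base_prob: tuple[float, float] = (0.10, 0.02)
    teen_girl_mh_odds_mult: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        for name in ("adult_physical_prev", "adult_mental_prev", "child_problem_prev"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} entries must lie in [0, 1]")
        if not 0.0 <= self.planted_complex_fraction <= 1.0:
            raise ValueError("planted_complex_fraction must lie in [0, 1]")
        if self.sector_rate_multiplier_complex < 1.0:
            raise ValueError("sector_rate_multiplier_complex must be >= 1")
        if self.planted_unmet_need_or <= 0:
            raise ValueError("planted_unmet_need_or must be > 0")
        probs = np.array(list(self.household_size_dist.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("household_size_dist must be a probability distribution")


def bivariate_bernoulli_p11(p1: float, p2: float, log_odds: float) -> float:
    """Joint success probability of two Bernoullis with given marginals
    and log odds ratio (the standard Plackett-style coupling)."""
    psi = float(np.exp(log_odds))
    if np.isclose(psi, 1.0):
        return p1 * p2
    s = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = s * s - 4.0 * psi * (psi - 1.0) * p1 * p2
    p11 = (s - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    return float(np.clip(p11, max(0.0, p1 + p2 - 1.0), min(p1, p2)))


def _sample_joint_flags(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray, log_odds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vector draw of coupled (physical, mental) flags per person."""
    n = p1.size
    p11 = np.array(
        [bivariate_bernoulli_p11(a, b, log_odds) for a, b in zip(p1, p2)]
    )
    p10 = p1 - p11
    p01 = p2 - p11
    u = rng.random(n)
    first = u < p11 + p10
    second = (u < p11) | (u >= p11 + p10) & (u < p11 + p10 + p01)
    return first, second


def generate_population(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(persons, conditions, contacts, truth)``.

    ``truth`` has one row per household: ``household_id``, ``planted``
    (complex ground truth) and ``has_child``.
    """
    if cfg.planted_complex_fraction > 0.5:
        warnings.warn(
            "planted_complex_fraction exceeds the top-quartile capacity; "
            "full planted-label recovery is impossible by construction",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    n_hh = cfg.n_households
    n_planted = int(round(cfg.planted_complex_fraction * n_hh))
    planted_hh = np.zeros(n_hh, dtype=bool)
    planted_hh[:n_planted] = True

    sizes_support = np.array(sorted(cfg.household_size_dist), dtype=int)
    probs = np.array(
        [cfg.household_size_dist[s] for s in sizes_support], dtype=float
    )
    sizes = rng.choice(sizes_support, size=n_hh, p=probs)
    sizes[planted_hh] = np.maximum(sizes[planted_hh], 2)

    n_child = rng.binomial(sizes, cfg.child_fraction_target)
    # planted households need >=1 child (cohort entry) and >=1 adult (c1)
    n_child[planted_hh] = np.clip(n_child[planted_hh], 1, sizes[planted_hh] - 1)
    n_child = np.minimum(n_child, sizes)

    hh_ids = np.array([f"hh{i:06d}" for i in range(n_hh)])
    hh_index = np.repeat(np.arange(n_hh), sizes)
    n_persons = int(sizes.sum())
    within = np.concatenate([np.arange(s) for s in sizes])
    is_child = within < n_child[hh_index]

    ages = np.where(
        is_child,
        rng.integers(0, 17, size=n_persons),
        rng.integers(17, 91, size=n_persons),
    )
    sex = rng.choice(np.array(["M", "F"]), size=n_persons)
    ethnicity = rng.choice(
        np.array(_ETHNICITIES), size=n_persons, p=np.array(_ETHNICITY_P)
    )
    imd_hh = np.where(
        planted_hh, rng.beta(4.0, 3.0, size=n_hh), rng.beta(2.0, 4.0, size=n_hh)
    ).round(4)

    persons = pd.DataFrame(
        {
            "person_id": [f"p{i:07d}" for i in range(n_persons)],
            "household_id": hh_ids[hh_index],
            "age": ages.astype(int),
            "sex": sex,
            "ethnicity": ethnicity,
            "imd_score": imd_hh[hh_index],
            "registered": True,
        }
    )[list(PERSON_COLUMNS)]

    planted_person = planted_hh[hh_index]
    conditions = _sample_conditions(rng, persons, is_child, planted_person, cfg)
    contacts = _sample_contacts(
        rng, persons, is_child, planted_person, hh_index, n_hh, cfg
    )

    truth = pd.DataFrame(
        {
            "household_id": hh_ids,
            "planted": planted_hh,
            "has_child": n_child >= 1,
        }
    )
    return persons, conditions, contacts, truth


def _pick_codes(
    rng: np.random.Generator, codes: tuple[str, ...], n: int
) -> np.ndarray:
    return np.array(codes)[rng.integers(0, len(codes), size=n)]


def _sample_conditions(
    rng: np.random.Generator,
    persons: pd.DataFrame,
    is_child: np.ndarray,
    planted_person: np.ndarray,
    cfg: SyntheticConfig,
) -> pd.DataFrame:
    phys_codes = tuple(sorted(DEFAULT_PHYSICAL_CONDITIONS))
    ment_codes = tuple(sorted(DEFAULT_MENTAL_CONDITIONS))
    problem_codes = phys_codes + ment_codes
    pid = persons["person_id"].to_numpy()

    adult = ~is_child
    p_phys = np.where(planted_person, *cfg.adult_physical_prev) * adult
    p_ment = np.where(planted_person, *cfg.adult_mental_prev) * adult
    has_phys, has_ment = _sample_joint_flags(
        rng, p_phys, p_ment, cfg.comorbidity_log_odds
    )
    p_child = np.where(planted_person, *cfg.child_problem_prev) * is_child
    has_problem = rng.random(p_child.size) < p_child

    rows: list[pd.DataFrame] = [
        pd.DataFrame(
            {
                "person_id": pid[has_phys],
                "condition_code": _pick_codes(rng, phys_codes, int(has_phys.sum())),
            }
        ),
        pd.DataFrame(
            {
                "person_id": pid[has_ment],
                "condition_code": _pick_codes(rng, ment_codes, int(has_ment.sum())),
            }
        ),
        pd.DataFrame(
            {
                "person_id": pid[has_problem],
                "condition_code": _pick_codes(
                    rng, problem_codes, int(has_problem.sum())
                ),
            }
        ),
    ]

    # deterministic forcing: every planted household must satisfy c1 and c2
    hh = persons["household_id"].to_numpy()
    force_rows: list[tuple[str, str]] = []
    planted_ids = pd.unique(hh[planted_person])
    adult_phys_hh = set(hh[adult & has_phys])
    adult_ment_hh = set(hh[adult & has_ment])
    child_prob_hh = set(hh[is_child & has_problem])
    first_adult = pd.Series(pid[adult], index=hh[adult]).groupby(level=0).first()
    first_child = pd.Series(pid[is_child], index=hh[is_child]).groupby(level=0).first()
    for h in planted_ids:
        if h not in adult_phys_hh:
            force_rows.append((first_adult[h], "asthma"))
        if h not in adult_ment_hh:
            force_rows.append((first_adult[h], "depression"))
        if h not in child_prob_hh:
            force_rows.append((first_child[h], "asthma"))
    if force_rows:
        rows.append(pd.DataFrame(force_rows, columns=["person_id", "condition_code"]))

    out = pd.concat(rows, ignore_index=True)
    out = out.drop_duplicates().sort_values(list(CONDITION_COLUMNS))
    return out.reset_index(drop=True)[list(CONDITION_COLUMNS)]


def _sample_contacts(
    rng: np.random.Generator,
    persons: pd.DataFrame,
    is_child: np.ndarray,
    planted_person: np.ndarray,
    hh_index: np.ndarray,
    n_hh: int,
    cfg: SyntheticConfig,
) -> pd.DataFrame:
    sectors = list(BASE_SECTOR_RATES)
    rates = np.array([BASE_SECTOR_RATES[s] for s in sectors])
    n_persons = len(persons)
    lam = np.tile(rates, (n_persons, 1))
    lam[planted_person] *= cfg.sector_rate_multiplier_complex
    i_asc = sectors.index("adult_social_care")
    i_csc = sectors.index("children_social_care")
    lam[is_child, i_asc] = 0.0
    lam[~is_child, i_csc] = 0.0
    counts = rng.poisson(lam)

    # force planted households to use >= 3 distinct sectors (c3 multi_service)
    used = np.zeros((n_hh, len(sectors)), dtype=bool)
    np.logical_or.at(used, hh_index, counts > 0)
    first_member = np.zeros(n_hh, dtype=int)
    seen: set[int] = set()
    for i, h in enumerate(hh_index):
        if h not in seen:
            first_member[h] = i
            seen.add(h)
    planted_hh_idx = np.flatnonzero(
        pd.Series(planted_person).groupby(hh_index).any().to_numpy()
    )
    for h in planted_hh_idx:
        deficit = 3 - int(used[h].sum())
        if deficit > 0:
            for j in (
                sectors.index("primary_care"),
                sectors.index("community"),
                sectors.index("mental_health"),
            ):
                if not used[h, j]:
                    counts[first_member[h], j] = max(counts[first_member[h], j], 1)
                    used[h, j] = True
                    deficit -= 1
                if deficit == 0:
                    break

    pid = persons["person_id"].to_numpy()
    person_rows, sector_rows = np.nonzero(counts)
    sector_arr = np.array(sectors)[sector_rows]
    contacts = pd.DataFrame(
        {
            "person_id": pid[person_rows],
            "sector": sector_arr,
            "reason_class": np.where(
                sector_arr == "mental_health", "mental_health", "other"
            ),
            "emergency": sector_arr == "ae",
            "n_contacts": counts[person_rows, sector_rows],
            "unit_cost_override": np.nan,
        }
    )
    return contacts.reset_index(drop=True)[list(CONTACT_COLUMNS)]


def generate_unmet_need_strata(
    persons: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SyntheticConfig,
    mental_codes: frozenset[str] = DEFAULT_MENTAL_CONDITIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant emergency mental-health attendance under a two-stratum model.

    A person is *known to services* when they carry a mental-condition
    flag or any non-emergency mental-health sector contact (both are
    derivable downstream, so the marker round-trips through the data).
    Within each stratum, attendance is Bernoulli with baseline
    probability ``emergency_mh_base_prob`` (known, unknown) for members
    of non-planted households; for planted households the odds are
    multiplied by ``known_unmet_need_or`` / ``planted_unmet_need_or``
    respectively.

    Returns ``(contacts_augmented, person_strata)`` where
    ``person_strata`` carries the ground-truth stratum and event flag
    per person.  Draw order is seeded from ``cfg.seed + 1`` so the call
    composes deterministically with :func:`generate_population`.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    complex_hh = set(truth.loc[truth["planted"], "household_id"])
    in_complex = persons["household_id"].isin(complex_hh).to_numpy()

    flagged = set(
        conditions.loc[
            conditions["condition_code"].isin(mental_codes), "person_id"
        ]
    )
    prior_contact = set(
        contacts.loc[
            (contacts["sector"] == "mental_health") & ~contacts["emergency"],
            "person_id",
        ]
    )
    known = (
        persons["person_id"].isin(flagged | prior_contact).to_numpy()
    )

    p_known_base, p_unknown_base = cfg.emergency_mh_base_prob
    base = np.where(known, p_known_base, p_unknown_base)
    or_mult = np.where(known, cfg.known_unmet_need_or, cfg.planted_unmet_need_or)
    # optional within-stratum rate concentration on girls aged 12-16; applied
    # to exposed and unexposed alike so the planted stratum OR is unchanged
    teen_girl = (persons["sex"].to_numpy() == "F") & persons["age"].between(
        12, 16
    ).to_numpy()
    odds = (
        base
        / (1.0 - base)
        * np.where(in_complex, or_mult, 1.0)
        * np.where(teen_girl, cfg.teen_girl_mh_odds_mult, 1.0)
    )
    p_event = odds / (1.0 + odds)
    event = rng.random(len(persons)) < p_event

    event_rows = pd.DataFrame(
        {
            "person_id": persons.loc[event, "person_id"].to_numpy(),
            "sector": "ae",
            "reason_class": "mental_health",
            "emergency": True,
            "n_contacts": 1,
            "unit_cost_override": np.nan,
        }
    )
    augmented = pd.concat(
        [contacts, event_rows[list(CONTACT_COLUMNS)]], ignore_index=True
    )
    person_strata = pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "stratum": np.where(known, "known_to_services", "no_prior_contact"),
            "in_complex_household": in_complex,
            "emergency_mh_event": event,
        }
    )
    return augmented, person_strata
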