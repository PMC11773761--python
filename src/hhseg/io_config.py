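"""Tabular input/output and run configuration.

All downstream stages consume the validated :class:`pandas.DataFrame`
tables produced here; nothing else re-parses raw text.  The run
configuration carries the condition taxonomy (which codes count as
physical, mental, or child problems), the vulnerability code lists, the
sector tariff table, and the rule thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: The eight care sectors recognised throughout the pipeline.
SECTORS: tuple[str, ...] = (
    "primary_care",
    "ae",
    "inpatient",
    "outpatient",
    "mental_health",
    "community",
    "adult_social_care",
    "children_social_care",
)

#: Sectors in which a contact may carry the emergency flag.
EMERGENCY_SECTORS: frozenset[str] = frozenset({"ae", "inpatient"})

#: Reason classes counted as mental-health related.
MH_REASON_CLASSES: frozenset[str] = frozenset(
    {
        "mental_health",
        "crisis",
        "self_harm",
        "anxiety",
        "eating_disorder",
        "neurodevelopmental",
    }
)

SEX_VALUES: frozenset[str] = frozenset({"M", "F", "unknown"})

DEFAULT_PHYSICAL_CONDITIONS: frozenset[str] = frozenset(
    {
        "asthma",
        "cancer",
        "cardiovascular_disease",
        "chronic_kidney_disease",
        "chronic_liver_disease",
        "copd",
        "dementia",
        "diabetes",
        "epilepsy",
        "gastroenterological",
        "neurological",
        "rheumatological",
        "physical_disability",
    }
)

DEFAULT_MENTAL_CONDITIONS: frozenset[str] = frozenset(
    {
        "anxiety",
        "depression",
        "severe_mental_illness",
        "neurodevelopmental",
        "learning_disability",
    }
)

DEFAULT_VULNERABILITY_CODES: dict[str, frozenset[str]] = {
    "homelessness": frozenset({"homelessness"}),
    "substance_abuse": frozenset({"substance_abuse"}),
    "child_in_care": frozenset({"child_in_care"}),
}

DEFAULT_TARIFFS: dict[str, float] = {
    "primary_care": 40.0,
    "ae": 180.0,
    "inpatient": 1500.0,
    "outpatient": 150.0,
    "mental_health": 250.0,
    "community": 80.0,
    "adult_social_care": 400.0,
    "children_social_care": 900.0,
}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """Rows violate a table invariant; message carries row diagnostics."""


class ConfigError(ValueError):
    """The run configuration is internally inconsistent."""


@dataclass(frozen=True)
class Thresholds:
    """Numeric thresholds of the segmentation rules.

    ``ae_visits_per_year`` is exclusive: a member is flagged with more
    than this many A&E attendances in the year.  ``child_age_max`` is
    inclusive: a child is aged 0 to ``child_age_max``.
    """

    ae_visits_per_year: int = 5
    distinct_services_min: int = 3
    spend_quantile: float = 0.75
    deprivation_quantile: float = 0.20
    child_age_max: int = 16
    max_household_size: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.spend_quantile < 1.0:
            raise ConfigError("spend_quantile must lie in (0, 1)")
        if not 0.0 < self.deprivation_quantile < 1.0:
            raise ConfigError("deprivation_quantile must lie in (0, 1)")
        if self.max_household_size < 1:
            raise ConfigError("max_household_size must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration.

    ``child_problem_conditions`` defaults to every physical and mental
    code (children inherit the full adult condition list) plus nothing
    else; the in-care marker is handled through ``vulnerability_codes``.
    """

    physical_conditions: frozenset[str] = DEFAULT_PHYSICAL_CONDITIONS
    mental_conditions: frozenset[str] = DEFAULT_MENTAL_CONDITIONS
    child_problem_conditions: frozenset[str] | None = None
    vulnerability_codes: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_VULNERABILITY_CODES)
    )
    tariffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TARIFFS))
    thresholds: Thresholds = field(default_factory=Thresholds)
    random_seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.physical_conditions) & set(self.mental_conditions)
        if overlap:
            raise ConfigError(
                "physical and mental condition sets overlap: "
                + ", ".join(sorted(overlap))
            )
        for key in ("homelessness", "substance_abuse", "child_in_care"):
            if key not in self.vulnerability_codes:
                raise ConfigError(f"vulnerability_codes missing key {key!r}")
        if self.child_problem_conditions is None:
            object.__setattr__(
                self,
                "child_problem_conditions",
                frozenset(self.physical_conditions) | frozenset(self.mental_conditions),
            )

    @property
    def known_codes(self) -> frozenset[str]:
        """Every condition code the taxonomy can resolve."""
        codes: set[str] = set(self.physical_conditions) | set(self.mental_conditions)
        codes |= set(self.child_problem_conditions or ())
        for vals in self.vulnerability_codes.values():
            codes |= set(vals)
        return frozenset(codes)


def default_config(**overrides) -> RunConfig:
    """A :class:`RunConfig` with shipped defaults, optionally overridden."""
    return dataclasses.replace(RunConfig(), **overrides) if overrides else RunConfig()


# ---------------------------------------------------------------------------
# configuration file handling


def _config_to_dict(cfg: RunConfig) -> dict:
    return {
        "physical_conditions": sorted(cfg.physical_conditions),
        "mental_conditions": sorted(cfg.mental_conditions),
        "child_problem_conditions": sorted(cfg.child_problem_conditions or ()),
        "vulnerability_codes": {
            k: sorted(v) for k, v in cfg.vulnerability_codes.items()
        },
        "tariffs": dict(cfg.tariffs),
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "random_seed": cfg.random_seed,
    }


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON when the suffix is ``.json``)."""
    path = Path(path)
    payload = _config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config file, applying defaults for absent keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    kwargs: dict = {}
    for key in ("physical_conditions", "mental_conditions"):
        if key in raw:
            kwargs[key] = frozenset(raw[key])
    if raw.get("child_problem_conditions"):
        kwargs["child_problem_conditions"] = frozenset(raw["child_problem_conditions"])
    if "vulnerability_codes" in raw:
        vc = dict(DEFAULT_VULNERABILITY_CODES)
        vc.update({k: frozenset(v) for k, v in raw["vulnerability_codes"].items()})
        kwargs["vulnerability_codes"] = vc
    if "tariffs" in raw:
        tariffs = dict(DEFAULT_TARIFFS)
        tariffs.update({k: float(v) for k, v in raw["tariffs"].items()})
        unknown = set(tariffs) - set(SECTORS)
        if unknown:
            raise ConfigError(f"tariff for unknown sector(s): {sorted(unknown)}")
        kwargs["tariffs"] = tariffs
    if "thresholds" in raw and raw["thresholds"]:
        kwargs["thresholds"] = Thresholds(**raw["thresholds"])
    if "random_seed" in raw:
        kwargs["random_seed"] = int(raw["random_seed"])
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# table schemas

PERSON_COLUMNS = (
    "person_id",
    "household_id",
    "age",
    "sex",
    "ethnicity",
    "imd_score",
    "registered",
)
CONDITION_COLUMNS = ("person_id", "condition_code")
CONTACT_COLUMNS = (
    "person_id",
    "sector",
    "reason_class",
    "emergency",
    "n_contacts",
    "unit_cost_override",
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _bad_rows(mask: pd.Series, reason: str, errors: list[str]) -> None:
    if mask.any():
        rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:20]]
        errors.append(f"{reason} (rows {rows}{', ...' if mask.sum() > 20 else ''})")


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "": False,
    }
    return (
        s.fillna(False)
        .astype(str)
        .str.strip()
        .str.lower()
        .map(mapping)
        .fillna(False)
        .astype(bool)
    )


def validate_persons(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a person table; raises on invariant violations."""
    _require_columns(df, PERSON_COLUMNS, "persons")
    out = df.loc[:, list(PERSON_COLUMNS)].copy()
    out["person_id"] = out["person_id"].astype(str)
    hid = out["household_id"]
    out["household_id"] = hid.where(hid.notna() & (hid.astype(str) != ""), pd.NA)
    out.loc[out["household_id"].notna(), "household_id"] = out.loc[
        out["household_id"].notna(), "household_id"
    ].astype(str)
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    out["imd_score"] = pd.to_numeric(out["imd_score"], errors="coerce")
    out["sex"] = out["sex"].fillna("unknown").astype(str)
    out["ethnicity"] = out["ethnicity"].fillna("unknown").astype(str)
    out["registered"] = _coerce_bool(out["registered"])

    errors: list[str] = []
    _bad_rows(out["person_id"].duplicated(), "duplicate person_id", errors)
    _bad_rows(out["age"].isna() | (out["age"] < 0), "age missing or negative", errors)
    _bad_rows(~out["sex"].isin(SEX_VALUES), "sex not in {M, F, unknown}", errors)
    imd = out["imd_score"]
    _bad_rows(imd.notna() & ~imd.between(0.0, 1.0), "imd_score outside [0, 1]", errors)
    if errors:
        raise ValidationError("persons table invalid: " + "; ".join(errors))
    out["age"] = out["age"].astype(int)
    return out.reset_index(drop=True)


def validate_conditions(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Validate a condition-flag table against the loaded taxonomy."""
    _require_columns(df, CONDITION_COLUMNS, "conditions")
    out = df.loc[:, list(CONDITION_COLUMNS)].copy()
    out["person_id"] = out["person_id"].astype(str)
    out["condition_code"] = out["condition_code"].astype(str)
    errors: list[str] = []
    _bad_rows(
        ~out["condition_code"].isin(cfg.known_codes),
        "condition_code not in taxonomy",
        errors,
    )
    if errors:
        raise ValidationError("conditions table invalid: " + "; ".join(errors))
    return out.reset_index(drop=True)


def validate_contacts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a care-contact table."""
    _require_columns(df, CONTACT_COLUMNS, "contacts")
    out = df.loc[:, list(CONTACT_COLUMNS)].copy()
    out["person_id"] = out["person_id"].astype(str)
    out["sector"] = out["sector"].astype(str)
    out["reason_class"] = out["reason_class"].fillna("other").astype(str)
    out["emergency"] = _coerce_bool(out["emergency"])
    out["n_contacts"] = pd.to_numeric(out["n_contacts"], errors="coerce")
    out["unit_cost_override"] = pd.to_numeric(
        out["unit_cost_override"], errors="coerce"
    )
    errors: list[str] = []
    _bad_rows(~out["sector"].isin(SECTORS), "unknown sector label", errors)
    _bad_rows(
        out["n_contacts"].isna() | (out["n_contacts"] < 1),
        "n_contacts missing or < 1",
        errors,
    )
    _bad_rows(
        out["emergency"] & ~out["sector"].isin(EMERGENCY_SECTORS),
        "emergency flag outside ae/inpatient",
        errors,
    )
    uco = out["unit_cost_override"]
    _bad_rows(uco.notna() & (uco < 0), "negative unit_cost_override", errors)
    if errors:
        raise ValidationError("contacts table invalid: " + "; ".join(errors))
    out["n_contacts"] = out["n_contacts"].astype(int)
    return out.reset_index(drop=True)


def load_tables(
    persons_path: str | Path,
    conditions_path: str | Path,
    contacts_path: str | Path,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three input tables (CSV, UTF-8, header row)."""
    frames = []
    for path, validator in (
        (persons_path, validate_persons),
        (conditions_path, lambda df: validate_conditions(df, cfg)),
        (contacts_path, validate_contacts),
    ):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        frames.append(validator(pd.read_csv(path, dtype={"person_id": str})))
    persons, conditions, contacts = frames
    return persons, conditions, contacts


def write_tables(
    persons: pd.DataFrame,
    conditions: pd.DataFrame,
    contacts: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three tables as CSV into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out_dir / "persons.csv",
        "conditions": out_dir / "conditions.csv",
        "contacts": out_dir / "contacts.csv",
    }
    persons.to_csv(paths["persons"], index=False)
    conditions.to_csv(paths["conditions"], index=False)
    contacts.to_csv(paths["contacts"], index=False)
    return paths
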