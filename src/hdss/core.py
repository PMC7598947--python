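"""Census data schema, validation, I/O and age-sex tabulation.

The individual-level census record is the shared currency of the toolkit:
one row per enumerated person with household key, completed age in years,
sex, and the socio-demographic covariates used by the fertility analysis.
Validation is flag-and-report — records with unparseable or missing ages
are kept and flagged, never silently dropped, because silent omission is
itself a source of rate bias in surveillance data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical census columns, in on-disk order.
CENSUS_COLUMNS = [
    "person_id",
    "household_id",
    "age",
    "sex",
    "residence",
    "education",
    "religion",
    "ethnicity",
    "marital_status",
    "gave_birth_last_year",
]

#: Columns that must be present (possibly under a mapped name) in any census CSV.
MANDATORY_COLUMNS = ["person_id", "household_id", "age", "sex"]

BIRTH_COLUMNS = ["mother_person_id", "plurality", "outcome", "place", "infant_sex"]

DEATH_COLUMNS = [
    "deceased_name_key",
    "household_id",
    "sex",
    "age_at_death",
    "date_of_death",
    "place",
    "cause",
    "source",
]

SEXES = ("male", "female")
EDUCATION_LEVELS = ("illiterate_read_write", "basic", "primary", "secondary", "higher")


class SchemaError(ValueError):
    """A mandatory column is absent from an input file."""


@dataclass
class ValidationReport:
    """Counts of records flagged (not dropped) during validation."""

    n_records: int = 0
    n_missing_age: int = 0
    n_invalid_birth_flag: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return self.n_missing_age + self.n_invalid_birth_flag

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_missing_age": self.n_missing_age,
            "n_invalid_birth_flag": self.n_invalid_birth_flag,
            "messages": list(self.messages),
        }


@dataclass
class CensusDataset:
    """Validated individual-level census records.

    ``persons`` carries one row per enumerated individual with the canonical
    columns; ``age`` is a nullable integer (completed years). ``report``
    summarises validation flags.
    """

    persons: pd.DataFrame
    report: ValidationReport

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_households(self) -> int:
        return self.persons["household_id"].nunique()

    def known_age(self) -> pd.DataFrame:
        """Rows with a non-missing age (the basis of all age-dependent indices)."""
        return self.persons[self.persons["age"].notna()]

    def women_reproductive(self, lo: int = 15, hi: int = 49) -> pd.DataFrame:
        p = self.known_age()
        return p[(p["sex"] == "female") & (p["age"] >= lo) & (p["age"] <= hi)]


def _validate_persons(df: pd.DataFrame) -> CensusDataset:
    report = ValidationReport(n_records=len(df))
    df = df.copy()

    # Coerce age: unparseable or negative values become missing + a flag.
    age = pd.to_numeric(df.get("age"), errors="coerce")
    age = age.where(age >= 0)
    frac = age.notna() & (age % 1 != 0)
    age = age.where(~frac)  # non-integer ages are unusable as completed years
    report.n_missing_age = int(age.isna().sum())
    if report.n_missing_age:
        report.messages.append(
            f"{report.n_missing_age} record(s) with missing/unparseable age flagged"
        )
    df["age"] = age.astype("Int64")

    if "gave_birth_last_year" not in df.columns:
        df["gave_birth_last_year"] = False
    gb = df["gave_birth_last_year"]
    if gb.dtype != bool:
        gb = gb.astype(str).str.strip().str.lower().isin(("true", "1", "yes", "y"))
    # The flag is meaningful only for women aged 15-49: enforce elsewhere.
    eligible = (df["sex"] == "female") & df["age"].notna() & df["age"].between(15, 49)
    invalid = gb & ~eligible
    report.n_invalid_birth_flag = int(invalid.sum())
    if report.n_invalid_birth_flag:
        report.messages.append(
            f"{report.n_invalid_birth_flag} birth flag(s) outside women 15-49 cleared"
        )
    df["gave_birth_last_year"] = (gb & eligible).astype(bool)

    for col in CENSUS_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return CensusDataset(df[CENSUS_COLUMNS].reset_index(drop=True), report)


def from_dataframe(df: pd.DataFrame) -> CensusDataset:
    """Validate an in-memory persons table (same contract as :func:`read_census`)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"census table lacks mandatory column(s): {', '.join(missing)}")
    return _validate_persons(df)


def read_census(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> CensusDataset:
    """Read and validate a census CSV.

    Parameters
    ----------
    path
        UTF-8, comma-separated file with a header row.
    schema_config
        Optional mapping from source column names to canonical names, to
        absorb schema drift (e.g. ``{"hh_id": "household_id"}``).
    """
    df = pd.read_csv(path, encoding="utf-8")
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    return from_dataframe(df)


def write_census(dataset: CensusDataset, path: str | Path) -> None:
    df = dataset.persons.copy()
    df.to_csv(path, index=False, lineterminator="\n")


def read_births(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("mother_person_id", "plurality", "outcome") if c not in df.columns]
    if missing:
        raise SchemaError(f"birth table lacks mandatory column(s): {', '.join(missing)}")
    for col in BIRTH_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[BIRTH_COLUMNS]


def read_deaths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("deceased_name_key", "sex", "source") if c not in df.columns]
    if missing:
        raise SchemaError(f"death table lacks mandatory column(s): {', '.join(missing)}")
    bad = set(df["source"].dropna().unique()) - {"census", "iddir"}
    if bad:
        raise SchemaError(f"unknown death source label(s): {sorted(bad)}")
    for col in DEATH_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["date_of_death"] = pd.to_datetime(df["date_of_death"], errors="coerce")
    return df[DEATH_COLUMNS]


# ---------------------------------------------------------------------------
# Age-sex tabulation


@dataclass
class AgeSexTabulation:
    """Population counts by age band and sex, plus single-year counts.

    ``band_edges`` are the lower bounds of closed-open bands [x, x+n); the
    final band is open-ended. Single-year counts run 0..max_age and aggregate
    exactly to the band counts.
    """

    band_edges: np.ndarray
    counts_male: np.ndarray
    counts_female: np.ndarray
    single_year_male: np.ndarray
    single_year_female: np.ndarray

    @property
    def counts_total(self) -> np.ndarray:
        return self.counts_male + self.counts_female

    @property
    def single_year_total(self) -> np.ndarray:
        return self.single_year_male + self.single_year_female

    @property
    def n_known_age(self) -> int:
        return int(self.counts_total.sum())

    def band_labels(self) -> list[str]:
        labels = []
        edges = self.band_edges
        for i, lo in enumerate(edges):
            if i == len(edges) - 1:
                labels.append(f"{lo}+")
            else:
                labels.append(f"{lo}-{edges[i + 1] - 1}")
        return labels

    def to_frame(self) -> pd.DataFrame:
        """Band counts as a tidy table (the population-pyramid tabulation)."""
        return pd.DataFrame(
            {
                "band": self.band_labels(),
                "lower": self.band_edges,
                "male": self.counts_male,
                "female": self.counts_female,
                "total": self.counts_total,
            }
        )


def tabulate(
    dataset: CensusDataset, band_width: int = 5, open_age: int = 85
) -> AgeSexTabulation:
    """Tabulate persons with known age into [x, x+n) bands with an open tail.

    ``band_width`` must be 1 or 5. Counts conserve the number of persons with
    known age by construction.
    """
    if band_width not in (1, 5):
        raise ValueError("band_width must be 1 or 5")
    known = dataset.known_age()
    ages = known["age"].to_numpy(dtype=int)
    sexes = known["sex"].to_numpy()

    max_age = int(ages.max()) if len(ages) else 0
    nyears = max(max_age + 1, open_age + 1)
    sy_m = np.bincount(ages[sexes == "male"], minlength=nyears)
    sy_f = np.bincount(ages[sexes == "female"], minlength=nyears)

    edges = np.arange(0, open_age + band_width, band_width)
    edges = edges[edges <= open_age]

    def _band(sy: np.ndarray) -> np.ndarray:
        out = np.zeros(len(edges), dtype=int)
        for i, lo in enumerate(edges):
            hi = edges[i + 1] if i + 1 < len(edges) else nyears
            out[i] = sy[lo:hi].sum()
        return out

    return AgeSexTabulation(
        band_edges=edges,
        counts_male=_band(sy_m),
        counts_female=_band(sy_f),
        single_year_male=sy_m,
        single_year_female=sy_f,
    )


# ---------------------------------------------------------------------------
# External rate schedules


@dataclass
class RateSchedule:
    """An external rate schedule used for scenario substitution.

    Rates are on the conventional reporting scales: infant and child
    mortality per 1000 live births, crude birth rate per 1000 population,
    ASFR in births per woman-year by 5-year maternal age band.
    """

    label: str
    infant_mortality: float | None = None
    child_mortality_1_4: float | None = None
    crude_birth_rate: float | None = None
    asfr: Sequence[float] | None = None

    def __post_init__(self) -> None:
        vals = [self.infant_mortality, self.child_mortality_1_4, self.crude_birth_rate]
        if all(v is None for v in vals) and self.asfr is None:
            raise ValueError(f"rate schedule {self.label!r} has no populated field")
        for v in vals:
            if v is not None and v < 0:
                raise ValueError("rates must be non-negative")
        if self.asfr is not None and any(a < 0 for a in self.asfr):
            raise ValueError("ASFR values must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateSchedule":
        return cls(
            label=d["label"],
            infant_mortality=d.get("infant_mortality"),
            child_mortality_1_4=d.get("child_mortality_1_4"),
            crude_birth_rate=d.get("crude_birth_rate"),
            asfr=d.get("asfr"),
        )


def read_rate_schedules(path: str | Path) -> list[RateSchedule]:
    """Load rate schedules from a YAML or JSON file (list of mappings)."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if isinstance(raw, Mapping) and "schedules" in raw:
        raw = raw["schedules"]
    return [RateSchedule.from_dict(d) for d in raw]
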