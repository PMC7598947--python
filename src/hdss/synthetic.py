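"""Synthetic census generator with known demographic truth.

Generates a de-facto census of households and individuals over a single
retrospective year, together with birth events and death events routed to
two reporting sources (the census interview and the burial-association
register), under two configurable reporting-error mechanisms observed in
field surveillance:

* **age heaping** — adult ages are rounded to the nearest multiple of five
  with some probability, emulating terminal-digit preference;
* **age-differential death omission** — each true death reaches the census
  source only with probability ``1 - omission(age)``, typically highest for
  infants, and reaches the burial register with an independent coverage
  probability.

Every draw is governed by a single :class:`numpy.random.Generator` seed, so
a config + seed pair pins the full bundle (byte-identical fixtures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BIRTH_COLUMNS,
    CENSUS_COLUMNS,
    DEATH_COLUMNS,
    CensusDataset,
    from_dataframe,
)

#: Default ASFR (births per woman-year) by 5-year band 15-19 .. 45-49,
#: the observed schedule of a rural southern-Ethiopian surveillance
#: population (sums x5 to a TFR of ~2.9 children per woman).
DEFAULT_ASFR = (0.02504, 0.12709, 0.14310, 0.12916, 0.09626, 0.04511, 0.00820)

#: Default mortality schedule: deaths per person-year by age-band lower bound.
#: Magnitudes follow a high-infant-mortality, low-adult-mortality profile
#: consistent with a CDR near 5 per 1000.
DEFAULT_MORTALITY = {
    0: 0.0109,
    1: 0.0019,
    5: 0.0006,
    15: 0.0006,
    25: 0.0020,
    35: 0.0052,
    45: 0.0089,
    55: 0.0133,
    65: 0.0270,
    75: 0.0670,
    85: 0.2300,
}

#: Default probability that a death is omitted from the census source, by
#: age-class lower bound. Illustrative values anchored to field reports of
#: severe infant-death under-reporting.
DEFAULT_DEATH_OMISSION = {0: 0.8, 1: 0.6, 5: 0.3}


def _step_lookup(table: dict[int, float], ages: np.ndarray) -> np.ndarray:
    """Evaluate an age-banded step function at integer ages."""
    bounds = np.array(sorted(table))
    vals = np.array([table[b] for b in bounds], dtype=float)
    idx = np.searchsorted(bounds, ages, side="right") - 1
    idx = np.clip(idx, 0, len(bounds) - 1)
    return vals[idx]


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults emulate the surveyed districts."""

    n_households: int = 5179
    household_size_mean: float = 4.9
    sex_ratio_at_birth: float = 105.0  # males per 100 females
    asfr_true: tuple = DEFAULT_ASFR
    mortality_true: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY))
    heaping_prob: float = 0.5
    heaping_min_age: int = 23
    death_omission_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_DEATH_OMISSION)
    )
    iddir_coverage: float = 0.95
    covariate_model: dict = field(default_factory=dict)
    growth_rate: float = 0.025  # stable-population growth used for the age pyramid
    urban_fraction: float = 0.17
    max_age: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ValueError("n_households must be positive")
        for p in (self.heaping_prob, self.iddir_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for p in self.death_omission_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("death_omission_prob values must lie in [0, 1]")
        if any(a < 0 for a in self.asfr_true):
            raise ValueError("ASFR values must be non-negative")
        if any(m < 0 for m in self.mortality_true.values()):
            raise ValueError("mortality rates must be non-negative")

    def age_distribution(self) -> np.ndarray:
        """Stable-population single-year age proportions implied by the
        mortality schedule and growth rate: p(a) ∝ l(a)·exp(-r·a)."""
        ages = np.arange(self.max_age + 1)
        mu = _step_lookup(self.mortality_true, ages)
        lx = np.concatenate([[1.0], np.exp(-np.cumsum(mu[:-1]))])
        w = lx * np.exp(-self.growth_rate * ages)
        return w / w.sum()

    def true_tfr(self) -> float:
        return 5.0 * float(np.sum(self.asfr_true))


@dataclass
class SyntheticBundle:
    census: CensusDataset
    births: pd.DataFrame
    deaths_census: pd.DataFrame
    deaths_iddir: pd.DataFrame
    truth: dict


def _heap_ages(ages: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Round masked integer ages to the nearest multiple of 5 (remainder 3,4 up)."""
    heaped = ages.copy()
    r = ages % 5
    down = ages - r
    up = down + 5
    heaped[mask] = np.where(r[mask] <= 2, down[mask], up[mask])
    return heaped


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Generate one census bundle: persons, births, two death sources, truth.

    Each woman aged 15-49 bears a birth in the last year with her band ASFR,
    shifted on the log-odds scale by any configured covariate coefficients;
    each person experiences a retrospective death event with the age-banded
    mortality rate. Deaths are routed to the census and burial-register
    sources by independent Bernoulli draws.
    """
    rng = np.random.default_rng(config.seed)

    sizes = 1 + rng.poisson(max(config.household_size_mean - 1.0, 0.0), config.n_households)
    n = int(sizes.sum())
    if n == 0:
        raise ValueError("degenerate config: zero population generated")
    household_id = np.repeat(np.arange(config.n_households), sizes)
    person_id = np.arange(n)

    age_true = rng.choice(config.max_age + 1, size=n, p=config.age_distribution())
    p_male = config.sex_ratio_at_birth / (100.0 + config.sex_ratio_at_birth)
    sex = np.where(rng.random(n) < p_male, "male", "female")

    hh_urban = rng.random(config.n_households) < config.urban_fraction
    residence = np.where(hh_urban[household_id], "urban", "rural")
    education = rng.choice(
        ["illiterate_read_write", "basic", "primary", "secondary", "higher"],
        size=n,
        p=[0.21, 0.24, 0.35, 0.18, 0.02],
    )
    religion = rng.choice(
        ["protestant", "orthodox", "muslim", "other"], size=n, p=[0.89, 0.04, 0.03, 0.04]
    )
    ethnicity = rng.choice(["sidama", "non_sidama"], size=n, p=[0.965, 0.035])
    marital = rng.choice(["never_married", "married", "widowed", "divorced"],
                         size=n, p=[0.50, 0.44, 0.04, 0.02])

    # --- births: band ASFR through a logistic link with covariate shifts
    women = (sex == "female") & (age_true >= 15) & (age_true <= 49)
    band = (age_true - 15) // 5
    p_birth = np.zeros(n)
    asfr = np.asarray(config.asfr_true, dtype=float)
    p_birth[women] = asfr[band[women]]
    if config.covariate_model:
        eta = np.log(np.clip(p_birth, 1e-12, 1 - 1e-12) /
                     np.clip(1 - p_birth, 1e-12, None))
        for (col, level), beta in _iter_coefs(config.covariate_model):
            vals = {"residence": residence, "education": education,
                    "religion": religion, "ethnicity": ethnicity}[col]
            eta = eta + beta * (vals == level)
        p = 1.0 / (1.0 + np.exp(-eta))
        p_birth = np.where(women, p, 0.0)
    gave_birth = rng.random(n) < p_birth

    mothers = person_id[gave_birth]
    n_births = len(mothers)
    births = pd.DataFrame(
        {
            "mother_person_id": mothers,
            "plurality": rng.choice(["singleton", "multiple"], n_births, p=[0.983, 0.017]),
            "outcome": rng.choice(["live", "stillbirth"], n_births, p=[0.998, 0.002]),
            "place": rng.choice(
                ["health_institution", "home", "other"], n_births, p=[0.567, 0.403, 0.03]
            ),
            "infant_sex": np.where(rng.random(n_births) < p_male, "male", "female"),
        },
        columns=BIRTH_COLUMNS,
    )

    # --- deaths and two-source reporting
    p_death = _step_lookup(config.mortality_true, age_true)
    died = rng.random(n) < p_death
    dead_idx = person_id[died]
    n_dead = len(dead_idx)
    death_day = rng.integers(0, 365, n_dead)
    dates = pd.Timestamp("2017-07-01") + pd.to_timedelta(death_day, unit="D")
    omission = _step_lookup(config.death_omission_prob, age_true[dead_idx])
    in_census = rng.random(n_dead) >= omission
    in_iddir = rng.random(n_dead) < config.iddir_coverage

    deaths_all = pd.DataFrame(
        {
            "deceased_name_key": [f"p{i:06d}" for i in dead_idx],
            "household_id": household_id[dead_idx],
            "sex": sex[dead_idx],
            "age_at_death": age_true[dead_idx],
            "date_of_death": dates,
            "place": rng.choice(
                ["health_institution", "home", "road", "other"],
                n_dead,
                p=[0.333, 0.614, 0.030, 0.023],
            ),
            "cause": rng.choice(["reported", "unknown"], n_dead, p=[0.773, 0.227]),
        }
    )
    deaths_census = deaths_all[in_census].copy()
    deaths_census["source"] = "census"
    deaths_iddir = deaths_all[in_iddir].copy()
    deaths_iddir["source"] = "iddir"
    deaths_census = deaths_census[DEATH_COLUMNS].reset_index(drop=True)
    deaths_iddir = deaths_iddir[DEATH_COLUMNS].reset_index(drop=True)

    # --- reported (possibly heaped) ages
    heap_mask = (age_true >= config.heaping_min_age) & (
        rng.random(n) < config.heaping_prob
    )
    age_reported = _heap_ages(age_true.astype(int), heap_mask)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "household_id": household_id,
            "age": age_reported,
            "sex": sex,
            "residence": residence,
            "education": education,
            "religion": religion,
            "ethnicity": ethnicity,
            "marital_status": marital,
            "gave_birth_last_year": gave_birth,
        },
        columns=CENSUS_COLUMNS,
    )
    census = from_dataframe(persons)

    omission_by_class = {
        str(k): float(v) for k, v in sorted(config.death_omission_prob.items())
    }
    truth = {
        "seed": config.seed,
        "n_households": config.n_households,
        "n_persons": n,
        "n_births": n_births,
        "n_deaths_true": n_dead,
        "n_deaths_census": int(in_census.sum()),
        "n_deaths_iddir": int(in_iddir.sum()),
        "true_tfr": config.true_tfr(),
        "true_cdr_per_1000": 1000.0 * n_dead / n,
        "asfr_true": list(map(float, config.asfr_true)),
        "mortality_true": {str(k): float(v) for k, v in sorted(config.mortality_true.items())},
        "death_omission_prob": omission_by_class,
        "iddir_coverage": config.iddir_coverage,
        "heaping_prob": config.heaping_prob,
        "age_true": age_true.astype(int).tolist(),
    }
    return SyntheticBundle(census, births, deaths_census, deaths_iddir, truth)


def _iter_coefs(model: dict):
    """Yield ((column, level), beta) from {'residence': {'urban': 0.36}, ...}."""
    for col, levels in model.items():
        for level, beta in levels.items():
            yield (col, level), float(beta)


def write_fixture(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write census.csv, births.csv, deaths_census.csv, deaths_iddir.csv,
    truth.json. Output is byte-stable for a fixed config + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "census": out / "census.csv",
        "births": out / "births.csv",
        "deaths_census": out / "deaths_census.csv",
        "deaths_iddir": out / "deaths_iddir.csv",
        "truth": out / "truth.json",
    }
    bundle.census.persons.to_csv(paths["census"], index=False, lineterminator="\n")
    bundle.births.to_csv(paths["births"], index=False, lineterminator="\n")
    for key in ("deaths_census", "deaths_iddir"):
        df = getattr(bundle, key).copy()
        df["date_of_death"] = pd.to_datetime(df["date_of_death"]).dt.strftime("%Y-%m-%d")
        df.to_csv(paths[key], index=False, lineterminator="\n")
    truth = {k: v for k, v in bundle.truth.items() if k != "age_true"}
    paths["truth"].write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
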