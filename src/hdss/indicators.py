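"""Standard demographic indicators from census, birth and death records.

All component rates follow the conventional surveillance definitions:
crude rates per 1000 mid-year population, fertility rates per woman (ASFR)
or per 1000 women 15-49 (GFR), child-mortality proxies per 1000 live
births, dependency ratios per 100 working-age population. Full precision
is retained internally; :meth:`IndicatorReport.rounded` applies the print
conventions (rates to 1 decimal, ratios to integers).

One deliberate idiosyncrasy: the 1-4 child mortality proxy is expressed
per 1000 live births — the same denominator as the IMR — rather than per
child-year of exposure. That is the convention of the source surveillance
report; a per-child-population alternative is available via
``child_mortality_conventional``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CensusDataset, tabulate

ASFR_BAND_LOWER = np.arange(15, 50, 5)  # 15-19 .. 45-49


def crude_birth_rate(births: int, midyear_pop: int) -> float:
    """Births per 1000 mid-year population."""
    if midyear_pop <= 0:
        raise ValueError("mid-year population must be positive")
    return 1000.0 * births / midyear_pop


def crude_death_rate(deaths: int, midyear_pop: int) -> float:
    """Deaths per 1000 mid-year population."""
    if midyear_pop <= 0:
        raise ValueError("mid-year population must be positive")
    return 1000.0 * deaths / midyear_pop


def general_fertility_rate(births: int, women_15_49: int) -> float:
    """Births per 1000 women of reproductive age (15-49)."""
    if women_15_49 <= 0:
        raise ValueError("women 15-49 count must be positive")
    return 1000.0 * births / women_15_49


def asfr_and_tfr(
    women_by_band: Sequence[int], births_by_band: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Age-specific fertility rates (births per woman) for the seven 5-year
    bands 15-19 .. 45-49, and the TFR = 5 x sum(ASFR)."""
    women = np.asarray(women_by_band, dtype=float)
    births = np.asarray(births_by_band, dtype=float)
    if women.shape != (7,) or births.shape != (7,):
        raise ValueError("expected seven 5-year maternal age bands (15-49)")
    empty = (women == 0) & (births > 0)
    if empty.any():
        raise ValueError("births attributed to an age band with no women")
    asfr = np.divide(births, women, out=np.zeros(7), where=women > 0)
    return asfr, 5.0 * float(asfr.sum())


def mean_age_of_fertility(asfr: Sequence[float]) -> float:
    """ASFR-weighted mean of the maternal age-band midpoints."""
    asfr = np.asarray(asfr, dtype=float)
    if asfr.sum() == 0:
        raise ValueError("all-zero fertility schedule has no mean age")
    mids = ASFR_BAND_LOWER + 2.5
    return float((mids * asfr).sum() / asfr.sum())


def grr_nrr(asfr_female: Sequence[float], survivorship: float) -> tuple[float, float]:
    """Gross reproduction rate (daughters per woman) and the net rate after
    discounting by survivorship to the mean age of the fertility schedule."""
    if not 0.0 <= survivorship <= 1.0:
        raise ValueError("survivorship must lie in [0, 1]")
    grr = 5.0 * float(np.sum(asfr_female))
    return grr, grr * survivorship


def dependency_ratios(
    pop_0_14: int, pop_15_64: int, pop_65plus: int
) -> tuple[float, float, float]:
    """(total, young, old) dependents per 100 working-age population."""
    if pop_15_64 <= 0:
        raise ValueError("working-age population must be positive")
    young = 100.0 * pop_0_14 / pop_15_64
    old = 100.0 * pop_65plus / pop_15_64
    return young + old, young, old


def child_mortality_proxies(
    infant_deaths: int, child_deaths_1_4: int, u5_deaths: int, live_births: int
) -> tuple[float, float, float]:
    """(IMR, 1-4 proxy, U5 proxy), each deaths per 1000 live births."""
    if live_births <= 0:
        raise ValueError("live births must be positive")
    f = 1000.0 / live_births
    return infant_deaths * f, child_deaths_1_4 * f, u5_deaths * f


def child_mortality_conventional(child_deaths_1_4: int, pop_1_4: int) -> float:
    """1-4 death rate per 1000 children aged 1-4 (exposure-based alternative)."""
    if pop_1_4 <= 0:
        raise ValueError("child population must be positive")
    return 1000.0 * child_deaths_1_4 / pop_1_4


@dataclass
class IndicatorReport:
    """Full indicator panel; see module docstring for unit conventions."""

    cbr: float
    cdr: float
    gfr: float
    asfr: list
    tfr: float
    grr: float
    nrr: float
    mean_age_of_fertility: float
    survivorship_to_mean_age: float
    imr: float
    cmr_1_4: float
    u5mr: float
    natural_increase: float
    dependency_total: float
    dependency_young: float
    dependency_old: float
    child_woman_ratio: float
    sex_ratio_birth: float
    sex_ratio_total: float
    median_age: float
    persons_per_household: float
    live_birth_fraction: float
    singleton_fraction: float
    out_of_facility_birth_fraction: float
    n_persons: int
    n_households: int
    n_births: int
    n_deaths: int

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Display-precision view: rates to 1 decimal, reproduction rates to
        2 decimals, sex ratios to integers."""
        d = self.to_dict()
        for k in ("cbr", "cdr", "gfr", "tfr", "imr", "cmr_1_4", "u5mr",
                  "natural_increase", "dependency_total", "dependency_young",
                  "dependency_old", "persons_per_household"):
            d[k] = round(d[k], 1)
        for k in ("grr", "nrr"):
            d[k] = round(d[k], 2)
        for k in ("sex_ratio_birth", "sex_ratio_total"):
            d[k] = round(d[k])
        return d


def summary_report(
    dataset: CensusDataset,
    births: pd.DataFrame,
    deaths: pd.DataFrame,
    survivorship: float | None = None,
) -> IndicatorReport:
    """Compute the full indicator panel.

    ``deaths`` should be the reconciled (deduplicated union) death list;
    ``survivorship`` is the probability of surviving to the mean age of the
    fertility schedule, used for the NRR. When not supplied it is taken
    from an abridged life table built from the inputs themselves.
    """
    persons = dataset.persons
    n = dataset.n_persons
    n_hh = dataset.n_households
    if n == 0:
        raise ValueError("empty census")

    n_births = len(births)
    n_deaths = len(deaths)
    cbr = crude_birth_rate(n_births, n)
    cdr = crude_death_rate(n_deaths, n)

    known = dataset.known_age()
    ages = known["age"].to_numpy(dtype=int)
    women = dataset.women_reproductive()
    n_women = len(women)
    gfr = general_fertility_rate(n_births, n_women) if n_women else float("nan")

    # ASFR from mothers' (reported) ages
    merged = births.merge(
        persons[["person_id", "age"]],
        left_on="mother_person_id",
        right_on="person_id",
        how="left",
    )
    mother_ages = merged["age"].dropna().astype(int)
    mother_ages = mother_ages[(mother_ages >= 15) & (mother_ages <= 49)]
    births_by_band = np.array(
        [((mother_ages >= lo) & (mother_ages <= lo + 4)).sum() for lo in ASFR_BAND_LOWER]
    )
    w_ages = women["age"].astype(int)
    women_by_band = np.array(
        [((w_ages >= lo) & (w_ages <= lo + 4)).sum() for lo in ASFR_BAND_LOWER]
    )
    asfr, tfr = asfr_and_tfr(women_by_band, births_by_band)

    # female-birth split applied proportionally across bands
    infant_sex = births["infant_sex"].dropna()
    n_girls = int((infant_sex == "female").sum())
    n_boys = int((infant_sex == "male").sum())
    female_frac = n_girls / n_births if n_births else 0.0
    maf = mean_age_of_fertility(asfr) if asfr.sum() > 0 else float("nan")

    if survivorship is None:
        survivorship = _survivorship_from_data(dataset, deaths, maf)
    grr, nrr = grr_nrr(asfr * female_frac, survivorship)

    # mortality proxies
    dage = pd.to_numeric(deaths["age_at_death"], errors="coerce")
    infant_d = int((dage == 0).sum())
    child_d = int(((dage >= 1) & (dage <= 4)).sum())
    u5_d = infant_d + child_d
    imr, cmr, u5 = (
        child_mortality_proxies(infant_d, child_d, u5_d, n_births)
        if n_births
        else (float("nan"),) * 3
    )

    dep_total, dep_young, dep_old = dependency_ratios(
        int((ages <= 14).sum()), int(((ages >= 15) & (ages <= 64)).sum()),
        int((ages >= 65).sum()),
    ) if ((ages >= 15) & (ages <= 64)).any() else (float("nan"),) * 3

    u5_pop = int((ages <= 4).sum())
    cwr = u5_pop / n_women if n_women else float("nan")

    n_m = int((persons["sex"] == "male").sum())
    n_f = int((persons["sex"] == "female").sum())
    srb = 100.0 * n_boys / n_girls if n_girls else float("nan")
    srt = 100.0 * n_m / n_f if n_f else float("nan")

    median_age = float(np.percentile(ages, 50, method="lower")) if len(ages) else float("nan")

    live = (births["outcome"] == "live") if n_births else pd.Series(dtype=bool)
    singleton = (births["plurality"] == "singleton") if n_births else pd.Series(dtype=bool)
    out_fac = (
        (births["place"] != "health_institution") if n_births else pd.Series(dtype=bool)
    )

    return IndicatorReport(
        cbr=cbr,
        cdr=cdr,
        gfr=gfr,
        asfr=asfr.tolist(),
        tfr=tfr,
        grr=grr,
        nrr=nrr,
        mean_age_of_fertility=maf,
        survivorship_to_mean_age=survivorship,
        imr=imr,
        cmr_1_4=cmr,
        u5mr=u5,
        natural_increase=(cbr - cdr) / 10.0,
        dependency_total=dep_total,
        dependency_young=dep_young,
        dependency_old=dep_old,
        child_woman_ratio=cwr,
        sex_ratio_birth=srb,
        sex_ratio_total=srt,
        median_age=median_age,
        persons_per_household=n / n_hh if n_hh else float("nan"),
        live_birth_fraction=float(live.mean()) if n_births else float("nan"),
        singleton_fraction=float(singleton.mean()) if n_births else float("nan"),
        out_of_facility_birth_fraction=float(out_fac.mean()) if n_births else float("nan"),
        n_persons=n,
        n_households=n_hh,
        n_births=n_births,
        n_deaths=n_deaths,
    )


def _survivorship_from_data(
    dataset: CensusDataset, deaths: pd.DataFrame, age: float
) -> float:
    """Survivorship to ``age`` from an abridged life table built on the
    dataset's own population and death counts. Falls back to 1.0 when the
    table cannot be built (e.g. no deaths)."""
    from .life_table import LifeTableInput, build, survivorship_to

    if not np.isfinite(age):
        return 1.0
    try:
        lt_input = LifeTableInput.from_records(dataset, deaths)
        result = build(lt_input)
        return survivorship_to(result, age)
    except (ValueError, ZeroDivisionError):
        return 1.0


def pyramid_tabulation(dataset: CensusDataset, band_width: int = 5) -> pd.DataFrame:
    """Age-sex band counts in tidy form, ready for pyramid plotting."""
    return tabulate(dataset, band_width=band_width).to_frame()
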