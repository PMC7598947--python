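"""Sensitivity scenarios: substitute external rates, count the implied gap.

Under-reporting of infant and child deaths is probed by substituting
external per-1000 rates (national / regional survey estimates, or another
surveillance site's crude birth rate) into the observed exposure, rounding
the expected event count half-up to an integer, and reporting the gap
expected − observed as the implied number of unreported events. Scenario
life tables re-build the abridged table with the substituted death counts
to show the life-expectancy consequence.

Exposure convention: infant and child substitution uses the band's
mid-period population (the life-table P(x)), not the live-birth count —
the convention that makes external per-1000 rates commensurate with the
band death counts they replace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import RateSchedule
from .life_table import LifeTableInput, LifeTableResult, build


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def expected_deaths(rate_per_1000: float, exposed_pop: float) -> int:
    """Expected deaths when ``rate_per_1000`` applies to ``exposed_pop``."""
    if rate_per_1000 < 0 or exposed_pop < 0:
        raise ValueError("rate and exposure must be non-negative")
    return round_half_up(rate_per_1000 * exposed_pop / 1000.0)


def expected_births(cbr_per_1000: float, midyear_pop: float) -> int:
    """Expected births when ``cbr_per_1000`` applies to the mid-year population."""
    if cbr_per_1000 < 0:
        raise ValueError("crude birth rate must be non-negative")
    return round_half_up(cbr_per_1000 * midyear_pop / 1000.0)


@dataclass
class ScenarioResult:
    """Expected counts, observed counts and gaps under one rate schedule."""

    label: str
    expected_deaths: dict = field(default_factory=dict)  # band label -> count
    observed_deaths: dict = field(default_factory=dict)
    expected_births: int | None = None
    observed_births: int | None = None
    e0_scenario: float | None = None
    flags: list = field(default_factory=list)

    @property
    def death_gaps(self) -> dict:
        return {
            k: self.expected_deaths[k] - self.observed_deaths.get(k, 0)
            for k in self.expected_deaths
        }

    @property
    def birth_gap(self) -> int | None:
        if self.expected_births is None or self.observed_births is None:
            return None
        return self.expected_births - self.observed_births

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "expected_deaths": dict(self.expected_deaths),
            "observed_deaths": dict(self.observed_deaths),
            "death_gaps": self.death_gaps,
            "expected_births": self.expected_births,
            "observed_births": self.observed_births,
            "birth_gap": self.birth_gap,
            "e0_scenario": self.e0_scenario,
            "flags": list(self.flags),
        }


def scenario_life_table(
    base: LifeTableInput, substitutions: dict[float, float]
) -> LifeTableResult:
    """Rebuild the life table with D(x) replaced in the named bands
    (keyed by band lower bound); all other bands untouched."""
    return build(base.with_substitutions(substitutions))


def run_scenario(
    schedule: RateSchedule,
    base: LifeTableInput,
    observed_births: int | None = None,
    midyear_pop: float | None = None,
) -> ScenarioResult:
    """Apply one external rate schedule to the observed exposures.

    Infant mortality substitutes into the age-0 band, child mortality into
    the 1-4 band, each against that band's population; the scenario life
    table is rebuilt with the substituted counts. A crude birth rate is
    applied to ``midyear_pop``. Internally inconsistent printed sources can
    be detected by comparing the returned computed counts with theirs.
    """
    res = ScenarioResult(label=schedule.label)
    subs: dict[float, float] = {}

    def band_index(lo: float) -> int:
        import numpy as np

        idx = np.nonzero(base.x == lo)[0]
        if len(idx) == 0:
            raise ValueError(f"life-table input has no band starting at {lo}")
        return int(idx[0])

    if schedule.infant_mortality is not None:
        i = band_index(0)
        exp = expected_deaths(schedule.infant_mortality, base.Px[i])
        res.expected_deaths["infant"] = exp
        res.observed_deaths["infant"] = int(base.Dx[i])
        subs[0.0] = exp
    if schedule.child_mortality_1_4 is not None:
        i = band_index(1)
        exp = expected_deaths(schedule.child_mortality_1_4, base.Px[i])
        res.expected_deaths["child_1_4"] = exp
        res.observed_deaths["child_1_4"] = int(base.Dx[i])
        subs[1.0] = exp
    if subs:
        res.e0_scenario = scenario_life_table(base, subs).e0
    if schedule.crude_birth_rate is not None and midyear_pop is not None:
        res.expected_births = expected_births(schedule.crude_birth_rate, midyear_pop)
        res.observed_births = observed_births
    return res
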