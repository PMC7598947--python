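"""Two-source death reconciliation: census interviews vs burial registers.

Burial associations keep informal registers (names, sex, date) that catch
deaths a retrospective census interview misses — in communities where
infant death is a taboo subject, most of them. This module matches the two
lists deterministically (normalised name key + sex + date window, greedy
one-to-one in ascending date distance), treats the deduplicated union as
the working death set, and quantifies what the census alone would have
missed, overall and by age class.

No capture-recapture correction is applied: deaths absent from both
sources remain invisible, and the reported "missed" fractions are
therefore lower bounds on true omission.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_AGE_CLASS_BREAKS = (0, 1, 5, 15, 65)  # <1, 1-4, 5-14, 15-64, 65+


def normalize_name_key(name: str) -> str:
    """Case-fold, strip diacritics and punctuation, collapse whitespace."""
    s = unicodedata.normalize("NFKD", str(name))
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.casefold()
    s = re.sub(r"[^\w\s]", "", s)
    return re.sub(r"\s+", " ", s).strip()


@dataclass
class MatchResult:
    pairs: list  # (census_index, iddir_index) positional pairs
    unmatched_census: list
    unmatched_iddir: list

    @property
    def n_both(self) -> int:
        return len(self.pairs)


def match_deaths(
    census: pd.DataFrame, iddir: pd.DataFrame, window_days: int = 30
) -> MatchResult:
    """Greedy one-to-one matching of two death lists.

    A census record and a burial-register record match iff their normalised
    name keys are equal, sexes are equal, and dates of death lie within
    ``window_days`` of each other (records with a missing date on either
    side match on key + sex alone, ranked after all dated candidates).
    Candidate pairs are taken in ascending date-difference order, ties
    broken by record order, so the outcome is deterministic.
    """
    ckeys = census["deceased_name_key"].map(normalize_name_key)
    ikeys = iddir["deceased_name_key"].map(normalize_name_key)
    cdates = pd.to_datetime(census["date_of_death"], errors="coerce")
    idates = pd.to_datetime(iddir["date_of_death"], errors="coerce")
    csex = census["sex"].to_numpy()
    isex = iddir["sex"].to_numpy()

    by_key: dict[tuple, list[int]] = {}
    for j, (k, s) in enumerate(zip(ikeys, isex)):
        by_key.setdefault((k, s), []).append(j)

    candidates = []  # (datediff_days, ci, ij)
    for ci, (k, s) in enumerate(zip(ckeys, csex)):
        for ij in by_key.get((k, s), ()):
            cd, idt = cdates.iloc[ci], idates.iloc[ij]
            if pd.isna(cd) or pd.isna(idt):
                diff = window_days  # undated: admissible, ranked last
            else:
                diff = abs((cd - idt).days)
                if diff > window_days:
                    continue
            candidates.append((diff, ci, ij))
    candidates.sort()

    used_c: set[int] = set()
    used_i: set[int] = set()
    pairs = []
    for _, ci, ij in candidates:
        if ci in used_c or ij in used_i:
            continue
        pairs.append((ci, ij))
        used_c.add(ci)
        used_i.add(ij)
    return MatchResult(
        pairs=pairs,
        unmatched_census=[i for i in range(len(census)) if i not in used_c],
        unmatched_iddir=[j for j in range(len(iddir)) if j not in used_i],
    )


@dataclass
class ReconciliationReport:
    n_census: int
    n_iddir: int
    n_both: int
    n_union: int
    missed_by_census_fraction: float
    missed_by_age_class: dict
    place_of_death_distribution: dict
    cause_unknown_fraction: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_census": self.n_census,
            "n_iddir": self.n_iddir,
            "n_both": self.n_both,
            "n_union": self.n_union,
            "missed_by_census_fraction": self.missed_by_census_fraction,
            "missed_by_age_class": dict(self.missed_by_age_class),
            "place_of_death_distribution": dict(self.place_of_death_distribution),
            "cause_unknown_fraction": self.cause_unknown_fraction,
            "warnings": list(self.warnings),
        }


def union_deaths(
    census: pd.DataFrame, iddir: pd.DataFrame, match: MatchResult
) -> pd.DataFrame:
    """Deduplicated union: all census records plus unmatched register records."""
    extra = iddir.iloc[match.unmatched_iddir]
    return pd.concat([census, extra], ignore_index=True)


def reconciliation_report(
    census: pd.DataFrame,
    iddir: pd.DataFrame,
    window_days: int = 30,
    age_class_breaks=DEFAULT_AGE_CLASS_BREAKS,
) -> ReconciliationReport:
    """Match the two sources and summarise census under-reporting.

    ``missed_by_census_fraction`` = (union − census)/union: the share of the
    reconciled death set absent from the census source. Per-age-class
    fractions use the union records with a known age; place-of-death and
    unknown-cause tabulations run on the full union.
    """
    match = match_deaths(census, iddir, window_days=window_days)
    union = union_deaths(census, iddir, match)
    n_union = len(union)
    warnings = []
    if n_union == 0:
        warnings.append("empty union: no death records in either source")
        return ReconciliationReport(0, 0, 0, 0, 0.0, {}, {}, 0.0, warnings)

    in_census = np.zeros(n_union, dtype=bool)
    in_census[: len(census)] = True

    missed = float((n_union - len(census)) / n_union)

    ages = pd.to_numeric(union["age_at_death"], errors="coerce")
    known = ages.notna()
    if (~known).any():
        warnings.append(
            f"{int((~known).sum())} union record(s) lack age; excluded from age classes"
        )
    breaks = list(age_class_breaks) + [np.inf]
    by_class = {}
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        label = f"{lo}+" if np.isinf(hi) else f"{lo}-{int(hi) - 1}"
        in_class = known & (ages >= lo) & (ages < hi)
        n_class = int(in_class.sum())
        if n_class:
            by_class[label] = float((in_class & ~in_census).sum() / n_class)

    place = union["place"].dropna()
    place_dist = (place.value_counts(normalize=True)).to_dict() if len(place) else {}
    cause = union["cause"].astype(str).str.strip().str.lower()
    unknown = float((cause == "unknown").mean())

    return ReconciliationReport(
        n_census=len(census),
        n_iddir=len(iddir),
        n_both=match.n_both,
        n_union=n_union,
        missed_by_census_fraction=missed,
        missed_by_age_class=by_class,
        place_of_death_distribution=place_dist,
        cause_unknown_fraction=unknown,
        warnings=warnings,
    )
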