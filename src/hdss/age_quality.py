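"""Age-reporting quality indices: Whipple, Myers, UN joint score.

These indices quantify terminal-digit preference ("age heaping") and
age-sex irregularity in single-year and banded age counts:

* **Whipple's index** over ages 23-62: 100 means no preference for the
  requested terminal digits; 500 (digits {0,5}) or 1000 (a single digit)
  means total concentration.
* **Myers' blended index** in [0, 90]: the minimum percentage of the
  population that would have to shift terminal digit to equalise all ten;
  0 for a rectangular distribution.
* **UN age-sex accuracy index (joint score)**: 3 x mean absolute successive
  difference of band sex ratios, plus the mean absolute deviation of male
  and female age ratios from 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AgeSexTabulation


def whipple(
    single_year_counts,
    digits: tuple[int, ...] = (0, 5),
    age_range: tuple[int, int] = (23, 62),
) -> float:
    """Whipple's index for the given terminal digits over an inclusive range.

    index = 100 x (counts at ages ending in the digits) / (|digits|/10 x total).
    """
    counts = np.asarray(single_year_counts, dtype=float)
    lo, hi = age_range
    if hi < lo:
        raise ValueError("empty evaluation range")
    if hi >= len(counts):
        counts = np.pad(counts, (0, hi + 1 - len(counts)))
    digits = tuple(sorted(set(digits)))
    if not digits or any(d not in range(10) for d in digits):
        raise ValueError("digits must be a non-empty subset of 0..9")
    ages = np.arange(len(counts))
    in_range = (ages >= lo) & (ages <= hi)
    total = counts[in_range].sum()
    if total == 0:
        raise ValueError("no population in the evaluation range")
    heaped = counts[in_range & np.isin(ages % 10, digits)].sum()
    return 100.0 * heaped / (len(digits) / 10.0 * total)


def myers(single_year_counts, age_range: tuple[int, int] = (10, 89)) -> float:
    """Myers' blended index over a range spanning whole decades.

    For each terminal digit d the counts are summed over the first D-1 and
    the last D-1 decades of the range (D decades in total) and blended with
    weights d+1 and 9-d; the index is half the sum of absolute deviations
    of the blended percentages from 10. Exactly 0 for a rectangular
    distribution; 90 when all ages share one terminal digit.
    """
    counts = np.asarray(single_year_counts, dtype=float)
    lo, hi = age_range
    span = hi - lo + 1
    if span < 20 or span % 10 != 0 or lo % 10 != 0:
        raise ValueError("range must start on a decade and span >= 2 whole decades")
    if hi >= len(counts):
        counts = np.pad(counts, (0, hi + 1 - len(counts)))
    ndec = span // 10
    blended = np.empty(10)
    for d in range(10):
        first = counts[[lo + 10 * k + d for k in range(ndec - 1)]].sum()
        last = counts[[lo + 10 * (k + 1) + d for k in range(ndec - 1)]].sum()
        blended[d] = (d + 1) * first + (9 - d) * last
    total = blended.sum()
    if total == 0:
        raise ValueError("no population in the evaluation range")
    pct = 100.0 * blended / total
    return float(np.abs(pct - 10.0).sum() / 2.0)


def un_joint_score(tabulation: AgeSexTabulation, max_age: int = 70) -> float:
    """UN age-sex accuracy index on 5-year bands below ``max_age``.

    Sex-ratio component: mean absolute successive difference of 100·M/F
    across all bands fully below max_age, weighted 3. Age-ratio component:
    for each sex, mean |100·P_i/(½(P_{i-1}+P_{i+1})) − 100| over interior
    bands (both neighbours also below max_age).
    """
    edges = tabulation.band_edges
    use = edges + 5 <= max_age
    if use.sum() < 3:
        raise ValueError("need at least three 5-year bands below max_age")
    m = tabulation.counts_male[use].astype(float)
    f = tabulation.counts_female[use].astype(float)
    if (f == 0).any():
        raise ValueError("zero female count in a band: sex ratio undefined")
    if (m == 0).any():
        raise ValueError("zero male count in a band: age ratio undefined")

    sr = 100.0 * m / f
    sr_component = float(np.abs(np.diff(sr)).mean())

    def age_ratio_dev(p: np.ndarray) -> float:
        ratios = 100.0 * p[1:-1] / (0.5 * (p[:-2] + p[2:]))
        return float(np.abs(ratios - 100.0).mean())

    return 3.0 * sr_component + age_ratio_dev(m) + age_ratio_dev(f)


@dataclass
class AgeQualityReport:
    whipple_combined: float
    whipple_digit: dict
    myers: float
    un_joint_score: float | None = None

    def to_dict(self) -> dict:
        d = {
            "whipple_combined": self.whipple_combined,
            "whipple_digit": dict(self.whipple_digit),
            "myers": self.myers,
            "un_joint_score": self.un_joint_score,
        }
        d["classifications"] = classify(self)
        return d


def classify(report: AgeQualityReport) -> dict:
    """UN accuracy categories for the Whipple index and the joint score."""
    out = {"whipple": _classify_whipple(report.whipple_combined)}
    out["whipple_digit"] = {
        d: _classify_whipple(v) for d, v in report.whipple_digit.items()
    }
    if report.un_joint_score is not None:
        s = report.un_joint_score
        out["un_joint_score"] = (
            "accurate" if s < 20 else "inaccurate" if s <= 40 else "highly inaccurate"
        )
    return out


def _classify_whipple(w: float) -> str:
    if w < 105:
        return "highly accurate"
    if w < 110:
        return "fairly accurate"
    if w < 125:
        return "approximate"
    if w < 175:
        return "rough"
    return "very rough"


def age_quality_report(tabulation: AgeSexTabulation, max_age: int = 70) -> AgeQualityReport:
    """All indices from one tabulation (single-year counts must be present)."""
    sy = tabulation.single_year_total
    return AgeQualityReport(
        whipple_combined=whipple(sy, digits=(0, 5)),
        whipple_digit={d: whipple(sy, digits=(d,)) for d in (0, 5)},
        myers=myers(sy),
        un_joint_score=un_joint_score(tabulation, max_age=max_age),
    )
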