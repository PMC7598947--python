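"""Crude odds ratios, asset-based wealth index, optional logistic fit.

The fertility-determinants analysis contrasts women 15-49 who gave birth
in the last year against those who did not, one factor at a time: each
non-reference factor level forms a 2x2 table against the reference level
and yields a crude odds ratio with a Woolf (log-odds) confidence interval,

    OR = ad/bc,   CI = exp( ln OR ± z · sqrt(1/a + 1/b + 1/c + 1/d) ).

The wealth index is the first principal component of a standardised
binary household-asset matrix, binned into equal-count quantiles. The
multivariable logistic fit (adjusted ORs) delegates to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CensusDataset


@dataclass
class TwoByTwo:
    """a: exposed w/ event, b: exposed w/o, c: reference w/ event, d: reference w/o."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    level_label: str = ""
    reference_label: str = ""
    corrected: bool = False  # Haldane-Anscombe +0.5 applied

    def to_dict(self) -> dict:
        return {
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level_label,
            "reference": self.reference_label,
            "corrected": self.corrected,
        }


def crude_or(
    t: TwoByTwo,
    alpha: float = 0.05,
    zero_correction: bool = True,
    level_label: str = "",
    reference_label: str = "",
) -> ORResult:
    """Cross-product odds ratio with a Woolf confidence interval.

    Zero cells trigger the Haldane-Anscombe +0.5 correction on all four
    cells (flagged in the result) unless ``zero_correction`` is disabled,
    in which case they raise.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = False
    if min(a, b, c, d) == 0:
        if not zero_correction:
            raise ValueError("zero cell: odds ratio undefined without correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_point = (a * d) / (b * c)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return ORResult(
        or_point=float(or_point),
        ci_low=float(np.exp(np.log(or_point) - z * se)),
        ci_high=float(np.exp(np.log(or_point) + z * se)),
        level_label=level_label,
        reference_label=reference_label,
        corrected=corrected,
    )


def _eligible_women(dataset: CensusDataset) -> pd.DataFrame:
    w = dataset.women_reproductive().copy()
    w["age_group"] = pd.cut(
        w["age"].astype(int),
        bins=list(range(15, 55, 5)),
        right=False,
        labels=[f"{lo}-{lo + 4}" for lo in range(15, 50, 5)],
    ).astype(str)
    return w


def or_table(
    dataset: CensusDataset,
    factor: str,
    reference: str,
    outcome: str = "gave_birth_last_year",
    alpha: float = 0.05,
) -> dict[str, ORResult]:
    """Crude OR per non-reference factor level, among women 15-49.

    ``factor`` may be any categorical census column or the derived
    ``age_group`` (5-year maternal bands, reference conventionally 15-19).
    """
    women = _eligible_women(dataset)
    if factor not in women.columns:
        raise ValueError(f"unknown factor column: {factor}")
    levels = [l for l in women[factor].dropna().unique()]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present in {factor!r}")
    y = women[outcome].astype(bool)
    ref_mask = women[factor] == reference
    c = int((y & ref_mask).sum())
    d = int((~y & ref_mask).sum())
    out: dict[str, ORResult] = {}
    for level in levels:
        if level == reference:
            continue
        mask = women[factor] == level
        t = TwoByTwo(int((y & mask).sum()), int((~y & mask).sum()), c, d)
        out[str(level)] = crude_or(
            t, alpha=alpha, level_label=str(level), reference_label=reference
        )
    return out


def wealth_index(
    asset_matrix: pd.DataFrame, n_quantiles: int = 3
) -> tuple[pd.Series, pd.Series]:
    """First-principal-component wealth score and quantile labels.

    ``asset_matrix``: one row per household, binary 0/1 asset indicators.
    Constant columns are dropped with a warning (they carry no signal).
    Returns (score, quantile label) indexed like the input; the score is
    oriented so that owning more assets scores higher. Quantile groups are
    equal-count (sizes differ by at most one).
    """
    from sklearn.decomposition import PCA
    import warnings as _warnings

    X = asset_matrix.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two asset indicators")
    if len(X) < n_quantiles:
        raise ValueError("need at least n_quantiles households")
    const = X.columns[X.nunique() <= 1]
    if len(const):
        _warnings.warn(f"dropping constant asset column(s): {list(const)}")
        X = X.drop(columns=const)
    Z = (X - X.mean()) / X.std(ddof=0)
    score = pd.Series(
        PCA(n_components=1).fit_transform(Z.to_numpy())[:, 0], index=X.index
    )
    if score.corr(X.sum(axis=1)) < 0:
        score = -score
    labels = (
        ["lower", "middle", "upper"]
        if n_quantiles == 3
        else [f"q{i + 1}" for i in range(n_quantiles)]
    )
    quantile = pd.qcut(score.rank(method="first"), n_quantiles, labels=labels)
    return score, quantile


@dataclass
class LogisticFitResult:
    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    params: pd.Series
    converged: bool
    separation_flag: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "or": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "coef": self.params,
            }
        )


def logistic_fit(
    dataset: CensusDataset,
    covariates: dict[str, str],
    outcome: str = "gave_birth_last_year",
    alpha: float = 0.05,
) -> LogisticFitResult:
    """Multivariable logistic regression (adjusted ORs) via statsmodels.

    ``covariates`` maps column name -> reference level; each factor is
    dummy-coded against its reference. Coefficients with |beta| > 15 are
    flagged as probable separation.
    """
    import statsmodels.api as sm

    women = _eligible_women(dataset)
    y = women[outcome].astype(int).to_numpy()
    X = pd.DataFrame(index=women.index)
    for col, ref in covariates.items():
        if col not in women.columns:
            raise ValueError(f"unknown covariate column: {col}")
        dummies = pd.get_dummies(women[col].astype(str), prefix=col, dtype=float)
        ref_col = f"{col}_{ref}"
        if ref_col not in dummies.columns:
            raise ValueError(f"reference level {ref!r} not present in {col!r}")
        X = pd.concat([X, dummies.drop(columns=ref_col)], axis=1)
    X = sm.add_constant(X)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(maxiter=100, tol=1e-10)
    params = fit.params.drop("const")
    conf = fit.conf_int(alpha=alpha).drop(index="const")
    return LogisticFitResult(
        odds_ratios=np.exp(params),
        ci_low=np.exp(conf[0]),
        ci_high=np.exp(conf[1]),
        params=params,
        converged=bool(getattr(fit, "converged", True)),
        separation_flag=bool((params.abs() > 15).any()),
    )
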