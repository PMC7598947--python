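"""Abridged period life tables from grouped population and death counts.

The table is built from central death rates m(x) = D(x)/P(x) converted to
probabilities of dying with the standard actuarial relation

    q(x) = n·m(x) / (1 + (n − a(x))·m(x))

where a(x) is the average number of years lived within [x, x+n) by those
dying there. Defaults: a(0) = 0.3, a(1-4) = 1.5, otherwise n/2 — the usual
high-mortality convention; all configurable. The open-ended final interval
has q = 1 and L = l/m. Radix 100,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RADIX = 100_000.0

#: Default abridged band lower bounds: 0, 1-4, then 5-year to the open 85+.
DEFAULT_BANDS = (0, 1, *range(5, 90, 5))


@dataclass
class LifeTableInput:
    """Contiguous age bands with mid-period population and death counts."""

    x: np.ndarray  # lower bound of each band
    n: np.ndarray  # width in years; final entry may be inf (open interval)
    Px: np.ndarray  # mid-period population per band
    Dx: np.ndarray  # deaths per band

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.Px = np.asarray(self.Px, dtype=float)
        self.Dx = np.asarray(self.Dx, dtype=float)
        if not (len(self.x) == len(self.n) == len(self.Px) == len(self.Dx)):
            raise ValueError("x, n, Px, Dx must have equal length")
        if self.x[0] != 0:
            raise ValueError("bands must start at age 0")
        closed = np.isfinite(self.n[:-1])
        if not closed.all():
            raise ValueError("only the final band may be open-ended")
        if not np.allclose(self.x[1:], self.x[:-1] + self.n[:-1]):
            raise ValueError("bands must be contiguous (x[i+1] = x[i] + n[i])")
        if (self.Px[:-1] <= 0).any():
            raise ValueError("closed bands require positive population")
        if (self.Dx < 0).any():
            raise ValueError("death counts must be non-negative")

    @classmethod
    def from_counts(cls, rows) -> "LifeTableInput":
        """Build from an iterable of (x, n, Px, Dx); n may be None/inf for
        the open band."""
        x, n, Px, Dx = zip(*rows)
        n = [np.inf if v is None else v for v in n]
        return cls(np.array(x), np.array(n), np.array(Px), np.array(Dx))

    @classmethod
    def from_records(cls, dataset, deaths: pd.DataFrame,
                     bands=DEFAULT_BANDS, sex: str | None = None) -> "LifeTableInput":
        """Group a census dataset and a death list into abridged bands.

        ``sex`` restricts both populations and deaths for sex-stratified
        tables.
        """
        persons = dataset.known_age()
        d = deaths.copy()
        if sex is not None:
            persons = persons[persons["sex"] == sex]
            d = d[d["sex"] == sex]
        ages = persons["age"].to_numpy(dtype=int)
        dage = pd.to_numeric(d["age_at_death"], errors="coerce").dropna().to_numpy()

        lowers = np.asarray(bands, dtype=float)
        uppers = np.append(lowers[1:], np.inf)
        Px = np.array([((ages >= lo) & (ages < hi)).sum() for lo, hi in zip(lowers, uppers)])
        Dx = np.array([((dage >= lo) & (dage < hi)).sum() for lo, hi in zip(lowers, uppers)])
        n = uppers - lowers
        return cls(lowers, n, Px, Dx)

    def with_substitutions(self, substitutions: dict[float, float]) -> "LifeTableInput":
        """Return a copy with Dx replaced in the named bands (keyed by x)."""
        Dx = self.Dx.copy()
        for lo, d in substitutions.items():
            idx = np.nonzero(self.x == lo)[0]
            if len(idx) == 0:
                raise ValueError(f"no band starts at age {lo}")
            Dx[idx[0]] = d
        return LifeTableInput(self.x.copy(), self.n.copy(), self.Px.copy(), Dx)


@dataclass
class LifeTableResult:
    """Columns of the abridged life table (radix 100,000)."""

    x: np.ndarray
    n: np.ndarray
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.ex[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: getattr(self, c) for c in
             ("x", "n", "mx", "ax", "qx", "lx", "dx", "Lx", "Tx", "ex")}
        )


def default_ax(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """a(0)=0.3, a(1-4)=1.5, else n/2 (open band gets 1/m later, unused)."""
    ax = n / 2.0
    ax[x == 0] = np.where(n[x == 0] == 1.0, 0.3, ax[x == 0])
    ax[(x == 1) & (n == 4)] = 1.5
    return ax


def build(inp: LifeTableInput, ax: np.ndarray | None = None) -> LifeTableResult:
    """Construct the life table.

    The open interval requires a positive death rate (D > 0) so that the
    remaining person-years l/m are finite.
    """
    k = len(inp.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = inp.Dx / inp.Px
    if inp.Px[-1] <= 0 or inp.Dx[-1] <= 0:
        raise ValueError("open band needs positive population and deaths "
                         "(or supply a fallback rate via Dx)")
    if ax is None:
        ax = default_ax(inp.x, inp.n)
    ax = np.asarray(ax, dtype=float)

    qx = np.empty(k)
    nc, mc, ac = inp.n[:-1], mx[:-1], ax[:-1]
    qx[:-1] = nc * mc / (1.0 + (nc - ac) * mc)
    qx[:-1] = np.clip(qx[:-1], 0.0, 1.0)
    qx[-1] = 1.0

    lx = np.empty(k)
    lx[0] = RADIX
    for i in range(k - 1):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = np.append(lx[:-1] - lx[1:], lx[-1])

    Lx = np.empty(k)
    Lx[:-1] = nc * lx[1:] + ac * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    return LifeTableResult(inp.x.copy(), inp.n.copy(), mx, ax, qx, lx, dx, Lx, Tx, ex)


def survivorship_to(result: LifeTableResult, age: float) -> float:
    """l(age)/l(0) with linear interpolation of l between exact ages."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age > result.x[-1]:
        raise ValueError("age lies beyond the start of the open interval")
    lx_at = np.interp(age, result.x, result.lx)
    return float(lx_at / result.lx[0])


def life_expectancy_at_birth(result: LifeTableResult) -> float:
    """e(0) = T(0)/l(0)."""
    return result.e0
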