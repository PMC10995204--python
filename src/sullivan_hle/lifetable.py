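"""Abridged period life tables from age-specific central death rates.

The central death rate :math:`{}_n m_x` (deaths per person-year lived in
the interval) is converted to the probability of dying

.. math::

    {}_n q_x = \\frac{n \\, m_x}{1 + (n - a_x) \\, m_x}

where :math:`n` is the interval length and :math:`a_x` the mean
person-years lived in the interval by those who die in it.  The cohort
column :math:`l_x` cascades from a radix (100,000 by default), deaths
:math:`d_x = l_x q_x`, person-years :math:`{}_n L_x = n\\,l_{x+n} + a_x
d_x` for closed intervals and :math:`L_x = l_x / m_x` for the open tail,
and expectancy :math:`e_x = T_x / l_x` with :math:`T_x` the person-years
remaining above age x.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .grids import OPEN, AgeGrid, GridError, Stratum

DEFAULT_RADIX = 100_000.0


class LifeTableError(ValueError):
    """Invalid input to life-table construction."""


class AxMode(str, enum.Enum):
    """How the separation factor is interpreted.

    FRACTION — a dimensionless fraction of the interval width, so an
    interval of width n contributes ``value * n`` person-years per death
    (the convention of standard abridged tables; 0.5 puts deaths at the
    interval midpoint).

    YEARS — a literal number of person-years per death, identical in
    every closed interval regardless of its width.
    """

    FRACTION = "fraction"
    YEARS = "years"


@dataclass(frozen=True)
class SeparationFactor:
    """Mean person-years lived in an interval by those dying in it (a_x)."""

    mode: AxMode = AxMode.FRACTION
    value: float = 0.5

    def __post_init__(self) -> None:
        if self.mode == AxMode.FRACTION and not 0.0 < self.value < 1.0:
            raise LifeTableError(f"FRACTION separation factor must lie in (0,1), got {self.value}")
        if self.mode == AxMode.YEARS and self.value <= 0.0:
            raise LifeTableError(f"YEARS separation factor must be positive, got {self.value}")

    def resolve(self, grid: AgeGrid) -> np.ndarray:
        """Person-years a_x for every closed interval of ``grid``."""
        widths = grid.closed_widths
        if self.mode == AxMode.FRACTION:
            ax = self.value * widths
        else:
            ax = np.full_like(widths, self.value)
        bad = np.nonzero(ax >= widths)[0]
        if bad.size:
            labels = [grid.labels()[i] for i in bad]
            raise LifeTableError(
                f"separation factor {self.value} person-years is not below the "
                f"interval width for intervals {labels}"
            )
        return ax


@dataclass(frozen=True)
class MortalitySchedule:
    """Central death rate per age interval for one population stratum."""

    grid: AgeGrid
    mx: np.ndarray
    stratum: Stratum = Stratum()

    def __post_init__(self) -> None:
        mx = np.asarray(self.mx, dtype=float)
        object.__setattr__(self, "mx", mx)
        if mx.shape != (len(self.grid),):
            raise LifeTableError(
                f"need one rate per interval: {len(self.grid)} intervals, {mx.shape} rates"
            )
        if not np.all(np.isfinite(mx)):
            raise LifeTableError("central death rates must be finite")
        if np.any(mx < 0):
            bad = [self.grid.labels()[i] for i in np.nonzero(mx < 0)[0]]
            raise LifeTableError(f"negative central death rate in intervals {bad}")

    def to_frame(self) -> pd.DataFrame:
        widths = ["open" if w == OPEN else w for w in self.grid.widths]
        return pd.DataFrame(
            {
                "age_start": self.grid.starts,
                "age_width": widths,
                **self.stratum.as_dict(),
                "mx": self.mx,
            }
        )


@dataclass(frozen=True)
class LifeTable:
    """A complete abridged period life table."""

    grid: AgeGrid
    mx: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float
    stratum: Stratum = Stratum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": self.grid.starts,
                "age_group": self.grid.labels(),
                "mx": self.mx,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )

    def expectancy_at(self, age_start: float) -> float:
        return float(self.ex[self.grid.index_of(age_start)])


def qx_from_mx(
    mx: float,
    n: float,
    a: SeparationFactor = SeparationFactor(),
    *,
    interval_label: str = "",
) -> float:
    """Probability of dying within an interval from its central death rate.

    ``n`` is the interval width in years; pass ``OPEN`` (``math.inf``)
    for the terminal interval, whose occupants all die there (q = 1).
    Values that the conversion formula pushes above 1 — representable
    only under extreme rates — are clamped to 1 with a warning.
    """
    where = f" in interval {interval_label}" if interval_label else ""
    if mx < 0:
        raise LifeTableError(f"negative central death rate{where}")
    if n == OPEN:
        return 1.0
    if n <= 0:
        raise LifeTableError(f"non-positive interval width{where}")
    if a.mode == AxMode.FRACTION:
        ax = a.value * n
    else:
        ax = a.value
    if ax >= n:
        raise LifeTableError(f"separation factor {ax} person-years >= interval width {n}{where}")
    q = n * mx / (1.0 + (n - ax) * mx)
    if q > 1.0:
        warnings.warn(
            f"probability of dying {q:.4f} > 1 clamped{where} (mx={mx})",
            RuntimeWarning,
            stacklevel=2,
        )
        q = 1.0
    return q


def build_life_table(
    schedule: MortalitySchedule,
    a: SeparationFactor = SeparationFactor(),
    radix: float = DEFAULT_RADIX,
) -> LifeTable:
    """Construct the full abridged life table from a mortality schedule.

    The terminal open interval is closed with ``Lx = lx / mx`` (constant
    force of mortality beyond the last exact age), which requires a
    strictly positive terminal rate.
    """
    if radix <= 0:
        raise LifeTableError("radix must be positive")
    grid, mx = schedule.grid, schedule.mx
    k = len(grid)
    if mx[-1] <= 0:
        raise LifeTableError(
            "terminal central death rate must be positive: person-years in the "
            "open interval are lx/mx"
        )
    ax = a.resolve(grid)
    widths = grid.closed_widths

    qx = np.empty(k)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        for i in range(k - 1):
            qx[i] = qx_from_mx(
                float(mx[i]), float(widths[i]), a, interval_label=grid.labels()[i]
            )
    qx[-1] = 1.0

    lx = np.empty(k)
    lx[0] = radix
    for i in range(k - 1):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = np.empty(k)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]

    Lx = np.empty(k)
    Lx[:-1] = widths * lx[1:] + ax * dx[:-1]
    Lx[-1] = lx[-1] / mx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    return LifeTable(
        grid=grid, mx=mx.copy(), qx=qx, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex,
        radix=radix, stratum=schedule.stratum,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def _parse_width(w) -> float:
    if isinstance(w, str) and w.strip().lower() == "open":
        return OPEN
    return float(w)


def _grid_from_frame(df: pd.DataFrame, context: str) -> AgeGrid:
    starts = tuple(float(s) for s in df["age_start"])
    widths = tuple(_parse_width(w) for w in df["age_width"])
    try:
        return AgeGrid(starts, widths)
    except GridError as err:
        raise GridError(f"{context}: {err}") from err


def read_mortality_csv(path: Union[str, Path]) -> list[MortalitySchedule]:
    """Read `age_start,age_width,sex,residence,division,mx` into schedules.

    One :class:`MortalitySchedule` is returned per (sex, residence,
    division) stratum present in the file; rows within a stratum are
    sorted by age.
    """
    df = pd.read_csv(path)
    required = {"age_start", "age_width", "sex", "residence", "division", "mx"}
    missing = required.difference(df.columns)
    if missing:
        raise LifeTableError(f"mortality CSV {path} missing columns {sorted(missing)}")
    out = []
    for (sex, res, div), sub in df.groupby(["sex", "residence", "division"], sort=True):
        sub = sub.sort_values("age_start")
        grid = _grid_from_frame(sub, f"mortality CSV stratum {sex}/{res}/{div}")
        out.append(
            MortalitySchedule(
                grid=grid,
                mx=sub["mx"].to_numpy(float),
                stratum=Stratum(sex=str(sex), residence=str(res), division=str(div)),
            )
        )
    return out


def write_life_table_csv(
    lt: LifeTable, path: Union[str, Path], *, display: bool = False
) -> None:
    """Write a life table as CSV.

    Full precision by default; ``display=True`` rounds expectancy-scale
    columns to 1 decimal (the convention of printed abridged tables)
    while keeping probabilities at 5 decimals.
    """
    df = lt.to_frame()
    if display:
        for col in ("ex",):
            df[col] = df[col].round(1)
        for col in ("mx", "qx"):
            df[col] = df[col].round(5)
        for col in ("lx", "dx", "Lx", "Tx"):
            df[col] = df[col].round(0).astype(int)
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.12g")
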