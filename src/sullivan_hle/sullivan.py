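"""Sullivan-method condition-free life expectancy.

The Sullivan method weights the life table's person-years by the
cross-sectional proportion of the population free of a condition:

.. math::

    \\mathrm{HLE}_x = \\frac{1}{l_x} \\sum_{i \\ge x} L_i (1 - \\pi_i)

where :math:`\\pi_i` is the condition prevalence in age interval i.
The sampling variance (mortality treated as fixed, prevalence as a
per-cell binomial proportion) is

.. math::

    \\mathrm{Var}(\\mathrm{HLE}_x) = \\frac{1}{l_x^2}
        \\sum_{i \\ge x} L_i^2 \\; \\frac{\\pi_i (1 - \\pi_i)}{N_i}

with :math:`N_i` the survey sample size behind the cell estimate.
Group contrasts use a normal (Z) test on the difference of two
independent estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .grids import OPEN, AgeGrid, GridError, Stratum
from .lifetable import LifeTable


class PrevalenceError(ValueError):
    """Invalid prevalence input."""


@dataclass(frozen=True)
class PrevalenceSchedule:
    """Condition prevalence per age interval for one stratum.

    ``pi`` is a proportion in [0, 1] per interval; ``n_sample`` the
    survey cell size behind each estimate (NaN where unknown);
    ``assumed`` flags intervals whose prevalence is an external
    assumption rather than a sample estimate — these get no sampling
    variance and suppress the confidence interval for starting ages
    that fall in them.
    """

    grid: AgeGrid
    condition: str
    pi: np.ndarray
    n_sample: Optional[np.ndarray] = None
    assumed: Optional[np.ndarray] = None
    stratum: Stratum = Stratum()

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (len(self.grid),):
            raise PrevalenceError(
                f"{self.condition}: need one prevalence per interval "
                f"({len(self.grid)} intervals, {pi.shape} values)"
            )
        if np.any((pi < 0) | (pi > 1) | ~np.isfinite(pi)):
            bad = [self.grid.labels()[i] for i in np.nonzero(~((pi >= 0) & (pi <= 1)))[0]]
            raise PrevalenceError(f"{self.condition}: prevalence outside [0,1] in {bad}")
        if self.n_sample is None:
            n = np.full(len(self.grid), np.nan)
        else:
            n = np.asarray(self.n_sample, dtype=float)
            if n.shape != (len(self.grid),):
                raise PrevalenceError(f"{self.condition}: one sample size per interval required")
            if np.any(n[np.isfinite(n)] < 1):
                raise PrevalenceError(f"{self.condition}: sample sizes must be >= 1")
        object.__setattr__(self, "n_sample", n)
        if self.assumed is None:
            a = np.zeros(len(self.grid), dtype=bool)
        else:
            a = np.asarray(self.assumed, dtype=bool)
            if a.shape != (len(self.grid),):
                raise PrevalenceError(f"{self.condition}: one 'assumed' flag per interval required")
        object.__setattr__(self, "assumed", a)

    def with_stratum(self, stratum: Stratum) -> "PrevalenceSchedule":
        return replace(self, stratum=stratum)


@dataclass(frozen=True)
class HealthExpectancyTable:
    """Condition-free expectancy with uncertainty, per starting age.

    ``var`` (and the CI bounds) are NaN where the sampling variance is
    not estimable — starting ages whose prevalence is assumed rather
    than surveyed, or with surveyed cells lacking a sample size.
    ``pct_with`` is the percentage of remaining life expected to be
    lived with the condition, ``100 (e_x - HLE_x) / e_x``.
    """

    grid: AgeGrid
    condition: str
    hle: np.ndarray
    var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pct_with: np.ndarray
    ex: np.ndarray
    level: float = 0.95
    stratum: Stratum = Stratum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": self.grid.starts,
                "age_group": self.grid.labels(),
                "condition": self.condition,
                **self.stratum.as_dict(),
                "ex": self.ex,
                "hle": self.hle,
                "var": self.var,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pct_with": self.pct_with,
            }
        )

    def at(self, age_start: float) -> dict[str, float]:
        i = self.grid.index_of(age_start)
        return {
            "ex": float(self.ex[i]),
            "hle": float(self.hle[i]),
            "var": float(self.var[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "pct_with": float(self.pct_with[i]),
        }


@dataclass(frozen=True)
class DifferenceTest:
    """Z-test for the difference of two health expectancies at one age."""

    age_start: float
    condition: str
    diff: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    stars: str
    degenerate: bool = False


def _check_aligned(lt: LifeTable, prev: PrevalenceSchedule) -> None:
    try:
        lt.grid.require_equal(prev.grid, context=f"life table vs {prev.condition} prevalence")
    except GridError:
        raise


def health_expectancy(
    lt: LifeTable, prev: PrevalenceSchedule, level: float = 0.95
) -> HealthExpectancyTable:
    """Sullivan condition-free life expectancy per starting age.

    Combines the life table's person-years with the condition-free
    proportion ``1 - pi`` of each interval; attaches the sampling
    variance, the Z confidence interval at ``level``, and the percent
    of remaining life lived with the condition.
    """
    _check_aligned(lt, prev)
    healthy_years = lt.Lx * (1.0 - prev.pi)
    total_above = np.cumsum(healthy_years[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        hle = np.where(lt.lx > 0, total_above / lt.lx, 0.0)
        var = hle_variance(lt, prev)
        ci_low, ci_high = ci(hle, var, level)
        pct = np.where(lt.ex > 0, 100.0 * (lt.ex - hle) / lt.ex, 0.0)
    return HealthExpectancyTable(
        grid=lt.grid, condition=prev.condition, hle=hle, var=var,
        ci_low=ci_low, ci_high=ci_high, pct_with=pct, ex=lt.ex.copy(),
        level=level, stratum=prev.stratum,
    )


def hle_variance(lt: LifeTable, prev: PrevalenceSchedule) -> np.ndarray:
    """Sampling variance of the Sullivan estimate per starting age.

    Prevalence cells are treated as independent binomial proportions;
    mortality sampling variation is ignored.  The variance at a
    starting age is NaN (not estimable) when that age's own prevalence
    is an assumption, or when any contributing surveyed cell with
    0 < pi < 1 lacks a sample size.
    """
    _check_aligned(lt, prev)
    k = len(lt.grid)
    needs_n = (prev.pi > 0) & (prev.pi < 1) & ~prev.assumed
    cell_ok = ~needs_n | np.isfinite(prev.n_sample)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_var = np.where(
            needs_n & np.isfinite(prev.n_sample),
            prev.pi * (1.0 - prev.pi) / prev.n_sample,
            0.0,
        )
    terms = lt.Lx**2 * cell_var
    tail = np.cumsum(terms[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(lt.lx > 0, tail / lt.lx**2, 0.0)
    # estimable only if every contributing cell is usable and the
    # starting interval itself is surveyed, not assumed
    tail_ok = np.minimum.accumulate(cell_ok[::-1])[::-1]
    var = np.where(tail_ok & ~prev.assumed, var, np.nan)
    return var


def ci(
    hle: np.ndarray, var: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-theory confidence bounds ``hle ± z * sqrt(var)``."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    var = np.asarray(var, dtype=float)
    if np.any(var[np.isfinite(var)] < 0):
        raise ValueError("negative variance")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return hle - half, hle + half


_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Significance marker for a two-sided p-value (0.05 / 0.01 / 0.001)."""
    if not math.isfinite(p):
        return ""
    for threshold, mark in _STAR_THRESHOLDS:
        if p <= threshold:
            return mark
    return ""


def difference_test(
    a: HealthExpectancyTable,
    b: HealthExpectancyTable,
    age_start: float,
    level: float = 0.95,
) -> DifferenceTest:
    """Z-test of ``hle_a - hle_b`` at one starting age.

    If either table lacks a variance at that age the difference is
    still reported but the standard error, CI and stars are suppressed
    (NaN / empty).  A zero standard error with a non-zero difference is
    flagged degenerate and the statistic reported as signed infinity.
    """
    if a.condition != b.condition:
        raise ValueError(f"conditions differ: {a.condition!r} vs {b.condition!r}")
    ia, ib = a.grid.index_of(age_start), b.grid.index_of(age_start)
    diff = float(a.hle[ia] - b.hle[ib])
    va, vb = float(a.var[ia]), float(b.var[ib])
    if not (math.isfinite(va) and math.isfinite(vb)):
        return DifferenceTest(
            age_start=age_start, condition=a.condition, diff=diff,
            se=math.nan, z=math.nan, p=math.nan,
            ci_low=math.nan, ci_high=math.nan, stars="",
        )
    se = math.sqrt(va + vb)
    degenerate = se == 0.0 and diff != 0.0
    if se == 0.0:
        z = math.copysign(math.inf, diff) if diff != 0.0 else 0.0
        p = 0.0 if diff != 0.0 else 1.0
    else:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return DifferenceTest(
        age_start=age_start, condition=a.condition, diff=diff, se=se, z=z, p=p,
        ci_low=diff - zcrit * se, ci_high=diff + zcrit * se,
        stars=stars_for_p(p),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

PREVALENCE_COLUMNS = [
    "age_start", "age_width", "sex", "residence", "division",
    "condition", "prevalence", "n_sample",
]


def read_prevalence_csv(path: Union[str, Path]) -> list[PrevalenceSchedule]:
    """Read the long prevalence CSV into one schedule per stratum × condition.

    Expected columns: ``age_start,age_width,sex,residence,division,
    condition,prevalence,n_sample`` with prevalence as a proportion in
    [0,1] and ``n_sample`` optionally blank.
    """
    df = pd.read_csv(path)
    missing = set(PREVALENCE_COLUMNS).difference(df.columns)
    if missing:
        raise PrevalenceError(f"prevalence CSV {path} missing columns {sorted(missing)}")
    from .lifetable import _grid_from_frame  # shared dialect

    out = []
    keys = ["sex", "residence", "division", "condition"]
    for (sex, res, div, cond), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("age_start")
        grid = _grid_from_frame(sub, f"prevalence CSV stratum {sex}/{res}/{div} {cond}")
        out.append(
            PrevalenceSchedule(
                grid=grid,
                condition=str(cond),
                pi=sub["prevalence"].to_numpy(float),
                n_sample=sub["n_sample"].to_numpy(float),
                stratum=Stratum(sex=str(sex), residence=str(res), division=str(div)),
            )
        )
    return out


def write_prevalence_csv(
    schedules: list[PrevalenceSchedule], path: Union[str, Path]
) -> None:
    rows = []
    for s in schedules:
        widths = ["open" if w == OPEN else w for w in s.grid.widths]
        rows.append(
            pd.DataFrame(
                {
                    "age_start": s.grid.starts,
                    "age_width": widths,
                    **s.stratum.as_dict(),
                    "condition": s.condition,
                    "prevalence": s.pi,
                    "n_sample": s.n_sample,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
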