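"""Abridged age grids.

An abridged period life table partitions age into contiguous intervals —
conventionally 0, 1–4, then five-year groups — closed by a single
unbounded ("open") terminal interval.  Everything downstream (mortality
schedules, prevalence schedules, life tables) is indexed by one of these
grids, so grid identity is checked eagerly and loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

#: Sentinel width of the terminal open interval.
OPEN = math.inf


class GridError(ValueError):
    """Raised for malformed or mismatched age grids."""


@dataclass(frozen=True)
class AgeGrid:
    """Ordered, contiguous abridged age intervals with one open tail.

    Parameters
    ----------
    starts : tuple of float
        Exact ages at which each interval begins, strictly increasing.
    widths : tuple of float
        Interval lengths in years; the last entry must be ``OPEN``
        (``math.inf``) and no other may be.
    """

    starts: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.widths):
            raise GridError("starts and widths differ in length")
        if len(self.starts) < 2:
            raise GridError("a grid needs at least one closed and one open interval")
        if not all(w == OPEN or w > 0 for w in self.widths):
            raise GridError("interval widths must be positive")
        if self.widths[-1] != OPEN:
            raise GridError("the last interval must be open (width OPEN)")
        if any(w == OPEN for w in self.widths[:-1]):
            raise GridError("only the last interval may be open")
        for i in range(len(self.starts) - 1):
            if not math.isclose(self.starts[i] + self.widths[i], self.starts[i + 1]):
                raise GridError(
                    f"grid not contiguous at interval {i}: "
                    f"{self.starts[i]}+{self.widths[i]} != {self.starts[i + 1]}"
                )

    @classmethod
    def default(cls) -> "AgeGrid":
        """The standard abridged grid 0, 1–4, 5–9, …, 75–79, 80+."""
        starts = [0.0, 1.0] + [float(a) for a in range(5, 85, 5)]
        widths = [1.0, 4.0] + [5.0] * 15 + [OPEN]
        return cls(tuple(starts), tuple(widths))

    @classmethod
    def from_age_starts(cls, starts: Sequence[float]) -> "AgeGrid":
        """Build a grid from interval start ages; the last start opens the tail."""
        starts = [float(s) for s in starts]
        widths = [b - a for a, b in zip(starts, starts[1:])] + [OPEN]
        return cls(tuple(starts), tuple(widths))

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.starts, self.widths))

    @property
    def closed_widths(self) -> np.ndarray:
        """Widths of the closed intervals as a float array."""
        return np.asarray(self.widths[:-1], dtype=float)

    def index_of(self, age_start: float) -> int:
        """Index of the interval beginning at ``age_start``."""
        for i, s in enumerate(self.starts):
            if math.isclose(s, age_start):
                return i
        raise GridError(f"no interval starts at age {age_start}")

    def labels(self) -> list[str]:
        """Human-readable labels: '0', '1-4', …, '80+'."""
        out = []
        for s, w in self:
            if w == OPEN:
                out.append(f"{_fmt(s)}+")
            elif w == 1:
                out.append(_fmt(s))
            else:
                out.append(f"{_fmt(s)}-{_fmt(s + w - 1)}")
        return out

    def require_equal(self, other: "AgeGrid", context: str = "") -> None:
        """Raise :class:`GridError` listing mismatched intervals."""
        if self == other:
            return
        mine, theirs = set(zip(self.starts, self.widths)), set(zip(other.starts, other.widths))
        diff = sorted(mine.symmetric_difference(theirs))
        where = f" in {context}" if context else ""
        raise GridError(f"age grids differ{where}; offending intervals: {diff}")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


@dataclass(frozen=True)
class Stratum:
    """Population stratum labels; 'total' means marginal over that axis."""

    sex: str = "total"
    residence: str = "total"
    division: str = "total"

    def __str__(self) -> str:
        return f"{self.sex}/{self.residence}/{self.division}"

    field_names = ("sex", "residence", "division")

    def as_dict(self) -> dict[str, str]:
        return {"sex": self.sex, "residence": self.residence, "division": self.division}
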