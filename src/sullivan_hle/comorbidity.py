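"""Coherence of linked condition-prevalence series.

Four series describe two diseases in one population: each disease
alone, "either" (at least one), and "both" (comorbidity).  At the
individual level these obey hard bounds

    both <= min(pH, pD)        max(pH, pD) <= either <= min(pH + pD, 1)

and the inclusion–exclusion identity ``either = pH + pD - both``.  When
the two diseases are measured on different survey subsamples the
identity holds only approximately; the validator therefore treats
bound violations as errors but identity drift within a tolerance as a
warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .grids import AgeGrid, Stratum
from .sullivan import PrevalenceSchedule

HYPERTENSION = "hypertension"
DIABETES = "diabetes"
EITHER = "either"
BOTH = "both"
CONDITIONS = (HYPERTENSION, DIABETES, EITHER, BOTH)

#: Default identity tolerance, in prevalence proportion (0.005 = 0.5
#: percentage points): accommodates series estimated on overlapping but
#: unequal survey subsamples.
DEFAULT_IDENTITY_TOL = 0.005


class ComorbidityError(ValueError):
    """Incoherent condition set."""


@dataclass(frozen=True)
class ConditionSet:
    """The four linked prevalence schedules on one grid and stratum."""

    hypertension: PrevalenceSchedule
    diabetes: PrevalenceSchedule
    either: PrevalenceSchedule
    both: PrevalenceSchedule
    derived_either: bool = False  # True when 'either' came from inclusion–exclusion

    def __post_init__(self) -> None:
        ref = self.hypertension
        for s in (self.diabetes, self.either, self.both):
            ref.grid.require_equal(s.grid, context=f"condition set ({s.condition})")
            if s.stratum != ref.stratum:
                raise ComorbidityError(
                    f"stratum mismatch in condition set: {s.stratum} vs {ref.stratum}"
                )

    def __iter__(self) -> Iterator[PrevalenceSchedule]:
        return iter((self.hypertension, self.diabetes, self.either, self.both))

    def __getitem__(self, condition: str) -> PrevalenceSchedule:
        try:
            return {s.condition: s for s in self}[condition]
        except KeyError:
            raise KeyError(f"no schedule for condition {condition!r}") from None

    @property
    def grid(self) -> AgeGrid:
        return self.hypertension.grid

    @property
    def stratum(self) -> Stratum:
        return self.hypertension.stratum


@dataclass
class ValidationIssue:
    interval_label: str
    message: str


@dataclass
class ValidationReport:
    """Hard-bound violations (errors) and identity drift (warnings)."""

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def clean(self) -> bool:
        return not self.errors and not self.warnings

    def summary(self) -> str:
        lines = [f"{len(self.errors)} errors, {len(self.warnings)} warnings"]
        for e in self.errors:
            lines.append(f"  ERROR   {e.interval_label}: {e.message}")
        for w in self.warnings:
            lines.append(f"  WARNING {w.interval_label}: {w.message}")
        return "\n".join(lines)


def validate_condition_set(
    cs: ConditionSet, tol: float = DEFAULT_IDENTITY_TOL
) -> ValidationReport:
    """Check hard bounds and the additive identity interval by interval.

    Bound breaches (e.g. both > hypertension) are errors; deviations of
    ``either`` from ``pH + pD - both`` beyond ``tol`` are warnings,
    since subsample differences legitimately produce small drift.  The
    either-series bounds are themselves consequences of the identity,
    so they get the same ``tol`` slack before escalating to an error —
    published tables estimated on unequal subsamples routinely graze
    them by a rounding digit.
    """
    report = ValidationReport()
    labels = cs.grid.labels()
    pH, pD = cs.hypertension.pi, cs.diabetes.pi
    pE, pB = cs.either.pi, cs.both.pi
    eps = 1e-12
    for i, lab in enumerate(labels):
        lo_e, hi_e = max(pH[i], pD[i]), min(pH[i] + pD[i], 1.0)
        if pB[i] > min(pH[i], pD[i]) + eps:
            report.errors.append(
                ValidationIssue(lab, f"both={pB[i]:.4f} exceeds min(pH,pD)={min(pH[i], pD[i]):.4f}")
            )
        if pE[i] < lo_e - tol - eps or pE[i] > hi_e + tol + eps:
            report.errors.append(
                ValidationIssue(
                    lab, f"either={pE[i]:.4f} outside [max(pH,pD), min(pH+pD,1)]=[{lo_e:.4f},{hi_e:.4f}]"
                )
            )
        drift = abs(pE[i] - (pH[i] + pD[i] - pB[i]))
        if drift > tol + eps:
            report.warnings.append(
                ValidationIssue(
                    lab,
                    f"inclusion-exclusion drift {drift:.4f} > tol {tol}: "
                    f"either={pE[i]:.4f} vs pH+pD-both={pH[i] + pD[i] - pB[i]:.4f}",
                )
            )
    return report


def derive_combined(
    pH: np.ndarray, pD: np.ndarray, pB: np.ndarray
) -> np.ndarray:
    """Either-condition prevalence by inclusion–exclusion, pE = pH + pD - pB.

    A fallback for when 'either' was not measured directly; inputs must
    already satisfy the hard bounds, and the result must land in [0,1].
    """
    pH, pD, pB = (np.asarray(a, dtype=float) for a in (pH, pD, pB))
    if np.any(pB > np.minimum(pH, pD) + 1e-12):
        raise ComorbidityError("both-prevalence exceeds a marginal prevalence")
    pE = pH + pD - pB
    if np.any((pE < -1e-12) | (pE > 1 + 1e-12)):
        raise ComorbidityError("derived either-prevalence outside [0,1]")
    return np.clip(pE, 0.0, 1.0)
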