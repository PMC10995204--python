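"""Study orchestration: age conventions, strata, and table-shaped output.

Adult health surveys typically report condition prevalence from age 18
while the life table starts at birth.  The pipeline applies the study
conventions explicitly and loudly: prevalence below 15 is set to zero
as an external assumption (childhood prevalence of these conditions is
known to be very low), the 18–19 survey cell stands in for the whole
15–19 interval, and every such convention is logged once per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .comorbidity import (
    BOTH,
    CONDITIONS,
    DIABETES,
    EITHER,
    HYPERTENSION,
    ConditionSet,
    DEFAULT_IDENTITY_TOL,
    ValidationReport,
    derive_combined,
    validate_condition_set,
)
from .grids import OPEN, AgeGrid, GridError, Stratum
from .lifetable import (
    AxMode,
    DEFAULT_RADIX,
    LifeTable,
    SeparationFactor,
    build_life_table,
    read_mortality_csv,
    write_life_table_csv,
)
from .sullivan import (
    DifferenceTest,
    HealthExpectancyTable,
    PrevalenceSchedule,
    difference_test,
    health_expectancy,
    read_prevalence_csv,
)

logger = logging.getLogger("sullivan_hle")


class PipelineError(ValueError):
    """Configuration or orchestration failure."""


# ---------------------------------------------------------------------------
# Young-age conventions
# ---------------------------------------------------------------------------

def extend_prevalence_young_ages(
    prev: PrevalenceSchedule, full_grid: Optional[AgeGrid] = None
) -> PrevalenceSchedule:
    """Extend an adult prevalence schedule down to birth.

    Surveys reporting from age 18 yield a schedule starting at the
    18–19 cell.  That cell is mapped onto the full 15–19 interval, and
    the intervals below 15 are filled with zero prevalence flagged as
    assumed (no sampling variance, CI suppressed).  A schedule already
    on the full grid is returned unchanged.
    """
    full = full_grid if full_grid is not None else AgeGrid.default()
    if prev.grid == full:
        return prev

    starts = prev.grid.starts
    if starts[0] < 15.0 and not prev.grid == full:
        raise PipelineError(
            f"{prev.condition} ({prev.stratum}): input ages overlap the young-age "
            f"extension range (first interval starts at {starts[0]}); expected an "
            "adult schedule starting at 18–19 or a complete grid"
        )
    # adult form: 18–19 then intervals matching the full grid from 20 up
    i20 = full.index_of(20.0)
    i15 = full.index_of(15.0)
    expected_tail = list(zip(full.starts[i20:], full.widths[i20:]))
    got_tail = list(zip(starts[1:], prev.grid.widths[1:]))
    if not (starts[0] == 18.0 and prev.grid.widths[0] == 2.0 and got_tail == expected_tail):
        raise PipelineError(
            f"{prev.condition} ({prev.stratum}): cannot align adult grid "
            f"{prev.grid.labels()} with target grid {full.labels()}"
        )

    k = len(full)
    pi = np.zeros(k)
    n = np.full(k, np.nan)
    assumed = np.zeros(k, dtype=bool)
    assumed[:i15] = True  # zero prevalence below 15 is an assumption, not data
    pi[i15] = prev.pi[0]  # 18–19 cell stands in for the whole 15–19 interval
    n[i15] = prev.n_sample[0]
    pi[i20:] = prev.pi[1:]
    n[i20:] = prev.n_sample[1:]
    return PrevalenceSchedule(
        grid=full, condition=prev.condition, pi=pi, n_sample=n,
        assumed=assumed, stratum=prev.stratum,
    )


def extend_condition_set(cs: ConditionSet, full_grid: Optional[AgeGrid] = None) -> ConditionSet:
    return ConditionSet(
        hypertension=extend_prevalence_young_ages(cs.hypertension, full_grid),
        diabetes=extend_prevalence_young_ages(cs.diabetes, full_grid),
        either=extend_prevalence_young_ages(cs.either, full_grid),
        both=extend_prevalence_young_ages(cs.both, full_grid),
        derived_either=cs.derived_either,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Declarative description of one full study run."""

    mortality_csv: Union[str, Path]
    prevalence_csv: Union[str, Path]
    out_dir: Union[str, Path] = "hle_output"
    strata: Union[str, Sequence[dict]] = "all"  # 'all' or explicit label dicts
    ax_mode: AxMode = AxMode.FRACTION
    ax_value: float = 0.5
    ci_level: float = 0.95
    radix: float = DEFAULT_RADIX
    extend_young_ages: bool = True
    identity_tol: float = DEFAULT_IDENTITY_TOL
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw).difference(known)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "ax_mode" in raw:
            raw["ax_mode"] = AxMode(raw["ax_mode"])
        return cls(**raw)

    @property
    def separation_factor(self) -> SeparationFactor:
        return SeparationFactor(mode=self.ax_mode, value=self.ax_value)


@dataclass
class StudyResult:
    """Everything one run produced, keyed by stratum and condition."""

    life_tables: dict[Stratum, LifeTable]
    hle_tables: dict[tuple[Stratum, str], HealthExpectancyTable]
    differences: dict[tuple[Stratum, str, float], DifferenceTest]
    validations: dict[Stratum, ValidationReport]
    long_frame: pd.DataFrame


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _group_condition_sets(
    schedules: list[PrevalenceSchedule],
) -> dict[Stratum, ConditionSet]:
    by_stratum: dict[Stratum, dict[str, PrevalenceSchedule]] = {}
    for s in schedules:
        by_stratum.setdefault(s.stratum, {})[s.condition] = s
    out = {}
    for stratum, conds in by_stratum.items():
        missing = set(CONDITIONS).difference(conds)
        if missing == {EITHER} and not {HYPERTENSION, DIABETES, BOTH}.difference(conds):
            pH, pD, pB = (conds[c] for c in (HYPERTENSION, DIABETES, BOTH))
            logger.info(
                "stratum %s: 'either' not measured; derived by inclusion-exclusion",
                stratum,
            )
            conds[EITHER] = PrevalenceSchedule(
                grid=pH.grid, condition=EITHER,
                pi=derive_combined(pH.pi, pD.pi, pB.pi),
                n_sample=np.fmin(pH.n_sample, pD.n_sample),
                stratum=stratum,
            )
            derived = True
        elif missing:
            logger.warning("stratum %s: conditions %s missing; skipped", stratum, sorted(missing))
            continue
        else:
            derived = False
        out[stratum] = ConditionSet(
            hypertension=conds[HYPERTENSION], diabetes=conds[DIABETES],
            either=conds[EITHER], both=conds[BOTH], derived_either=derived,
        )
    return out


def _selected(stratum: Stratum, strata: Union[str, Sequence[dict]]) -> bool:
    if strata == "all":
        return True
    for selector in strata:
        if all(getattr(stratum, k) == v for k, v in selector.items()):
            return True
    return False


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full study described by ``cfg`` and write its outputs.

    For every stratum present in both inputs (and selected in the
    config): an abridged life table, the four condition-free expectancy
    tables, male−female difference tests per residence/division group,
    and a coherence report of the four prevalence series.  Outputs are
    one long-format CSV (the canonical artifact) plus per-condition
    facsimile tables and per-stratum life tables.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a = cfg.separation_factor
    logger.info("separation factor: mode=%s value=%s", cfg.ax_mode.value, cfg.ax_value)
    if cfg.extend_young_ages:
        logger.info(
            "young-age convention: prevalence 0 assumed below age 15; the 18-19 "
            "survey cell applied to the whole 15-19 interval"
        )

    mort = {m.stratum: m for m in read_mortality_csv(cfg.mortality_csv)}
    csets = _group_condition_sets(read_prevalence_csv(cfg.prevalence_csv))

    life_tables: dict[Stratum, LifeTable] = {}
    hle_tables: dict[tuple[Stratum, str], HealthExpectancyTable] = {}
    validations: dict[Stratum, ValidationReport] = {}

    for stratum in sorted(csets, key=str):
        if not _selected(stratum, cfg.strata):
            continue
        if stratum not in mort:
            logger.warning("stratum %s has prevalence but no mortality; skipped", stratum)
            continue
        cset = csets[stratum]
        if cfg.extend_young_ages:
            cset = extend_condition_set(cset)
        report = validate_condition_set(cset, tol=cfg.identity_tol)
        validations[stratum] = report
        if not report.ok:
            logger.warning("stratum %s failed coherence checks:\n%s", stratum, report.summary())
        lt = build_life_table(mort[stratum], a=a, radix=cfg.radix)
        life_tables[stratum] = lt
        for sched in cset:
            lt.grid.require_equal(sched.grid, context=f"stratum {stratum}")
            hle_tables[(stratum, sched.condition)] = health_expectancy(
                lt, sched, level=cfg.ci_level
            )

    if not hle_tables:
        raise PipelineError("no stratum produced output; check inputs and strata selection")

    differences = _sex_differences(hle_tables, cfg.ci_level)
    long_frame = _long_frame(hle_tables)

    _write_outputs(out_dir, life_tables, hle_tables, differences, validations, long_frame)
    return StudyResult(
        life_tables=life_tables, hle_tables=hle_tables,
        differences=differences, validations=validations, long_frame=long_frame,
    )


def _sex_differences(
    hle_tables: dict[tuple[Stratum, str], HealthExpectancyTable], level: float
) -> dict[tuple[Stratum, str, float], DifferenceTest]:
    out = {}
    for (stratum, cond), male_tab in hle_tables.items():
        if stratum.sex != "male":
            continue
        female = replace(stratum, sex="female")
        if (female, cond) not in hle_tables:
            continue
        female_tab = hle_tables[(female, cond)]
        group = replace(stratum, sex="total")
        for age in male_tab.grid.starts:
            out[(group, cond, age)] = difference_test(male_tab, female_tab, age, level=level)
    return out


def _long_frame(
    hle_tables: dict[tuple[Stratum, str], HealthExpectancyTable]
) -> pd.DataFrame:
    frames = [t.to_frame() for _, t in sorted(hle_tables.items(), key=lambda kv: str(kv[0]))]
    return pd.concat(frames, ignore_index=True)


def _facsimile(
    hle_tables: dict[tuple[Stratum, str], HealthExpectancyTable],
    differences: dict[tuple[Stratum, str, float], DifferenceTest],
    cond: str,
    group: Stratum,
) -> Optional[pd.DataFrame]:
    """One condition's printed-table view: male, female, difference, total, % with."""
    tabs = {}
    for sex in ("male", "female", "total"):
        key = (replace(group, sex=sex), cond)
        if key in hle_tables:
            tabs[sex] = hle_tables[key]
    if "total" not in tabs:
        return None
    total = tabs["total"]
    rows = []
    for i, age in enumerate(total.grid.starts):
        row = {"age_group": total.grid.labels()[i]}
        for sex in ("male", "female"):
            if sex in tabs:
                t = tabs[sex]
                row[sex] = t.hle[i]
                row[f"{sex}_ci_low"], row[f"{sex}_ci_high"] = t.ci_low[i], t.ci_high[i]
        d = differences.get((group, cond, age))
        if d is not None:
            row["difference"] = d.diff
            row["diff_ci_low"], row["diff_ci_high"] = d.ci_low, d.ci_high
            row["stars"] = d.stars
        row["total"] = total.hle[i]
        row["total_ci_low"], row["total_ci_high"] = total.ci_low[i], total.ci_high[i]
        row["pct_with"] = total.pct_with[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    num = df.select_dtypes(include=[float]).columns
    df[num] = df[num].round(1)
    return df


def _write_outputs(out_dir, life_tables, hle_tables, differences, validations, long_frame):
    long_frame.to_csv(out_dir / "health_expectancy_long.csv", index=False, float_format="%.12g")
    for stratum, lt in sorted(life_tables.items(), key=lambda kv: str(kv[0])):
        name = f"lifetable_{stratum.sex}_{stratum.residence}_{stratum.division}.csv"
        write_life_table_csv(lt, out_dir / name)
    groups = sorted({(replace(s, sex="total")) for (s, _) in hle_tables}, key=str)
    for group in groups:
        for cond in CONDITIONS:
            df = _facsimile(hle_tables, differences, cond, group)
            if df is not None:
                name = f"table_{cond}_{group.residence}_{group.division}.csv"
                df.to_csv(out_dir / name, index=False)
    summary = {
        str(s): {"errors": len(r.errors), "warnings": len(r.warnings), "detail": r.summary()}
        for s, r in sorted(validations.items(), key=lambda kv: str(kv[0]))
    }
    (Path(out_dir) / "validation.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Age-label conventions
# ---------------------------------------------------------------------------

def normalize_age_label(label: str) -> tuple[float, float]:
    """Parse an age-group label to (start, width), tolerating off-by-one typos.

    Accepts '0', '1-4', '80+', and labels like '74-79' whose implied
    width disagrees with a five-year grid by one year at the start —
    these are normalized to the standard interval ('74-79' -> 75–79).
    """
    label = label.strip().replace("–", "-")
    if label.endswith("+"):
        return float(label[:-1]), OPEN
    if "-" not in label:
        return float(label), 1.0
    lo_s, hi_s = label.split("-")
    lo, hi = float(lo_s), float(hi_s)
    width = hi - lo + 1.0
    if width in (1.0, 4.0, 5.0):
        return lo, width
    # off-by-one start typo against a five-year grid: trust the endpoint
    if (hi + 1.0) % 5 == 0:
        return hi - 4.0, 5.0
    raise GridError(f"cannot interpret age-group label {label!r}")
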