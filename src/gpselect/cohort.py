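"""Domain types, CSV input/output, record linkage and eligibility filtering.

The unit of analysis is the *application* for GP training, not the doctor:
one doctor may contribute several applications, and training-performance data
attach only to the successful one.  Applications and performance records are
linked exactly on the GMC identifier.

Internally a cohort is a :class:`pandas.DataFrame` with one row per included
application; ``NaN`` encodes a missing value.  Binary fields are carried as
``0.0``/``1.0`` floats so that missingness and model matrices need no special
cases.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._util import fmt_bool, month_index, parse_bool, round_half_up

__all__ = [
    "ApplicationRecord",
    "PerformanceRecord",
    "LinkedCohort",
    "AccountingSummary",
    "LoadResult",
    "SchemaError",
    "DuplicateIdentifierError",
    "DataIntegrityError",
    "load_applications",
    "write_applications",
    "load_performance",
    "write_performance",
    "link_and_filter",
    "accounting_summary",
    "IMPUTABLE_VARIABLES",
    "PREDICTOR_VARIABLES",
]

#: Variables with selection-induced missingness, imputed by the FCS engine.
#: ``stage3_competent`` rides along with ``stage3_total`` (it is missing in
#: exactly the same rows and the downstream 2015-process rule needs it).
IMPUTABLE_VARIABLES = [
    "withdrew",
    "stage3_total",
    "stage3_competent",
    "offer_accepted",
    "ltft",
    "oop",
    "arcp4",
    "fte_months",
]

#: Fully observed for every included application; always usable as predictors.
PREDICTOR_VARIABLES = ["round", "cps_score", "pd_score", "gender", "ethnicity_bme", "uk_pmq"]

_BINARY_VARS = {"withdrew", "stage3_competent", "offer_accepted", "ltft", "oop", "arcp4"}


class SchemaError(ValueError):
    """A required column is absent or the header does not match the schema."""


class DuplicateIdentifierError(ValueError):
    """Two performance records share one GMC identifier."""


class DataIntegrityError(ValueError):
    """A record violates an internal consistency rule."""


@dataclass
class ApplicationRecord:
    """One application for GP training (the unit of analysis)."""

    gmc_id: str | None
    year: int
    round: str  # "R1" or "R2" after loading; "R3" inputs are recoded to "R2"
    cps_score: float
    pd_score: float
    stage3_total: float | None = None
    stage3_competent: bool | None = None
    withdrew: bool | None = None
    offer_accepted: bool | None = None
    passed_stage1: bool = True
    took_stage2: bool = True
    gender: str = "F"
    ethnicity_bme: bool = False
    uk_pmq: bool = True

    @property
    def stage2_total(self) -> float:
        return self.cps_score + self.pd_score

    def __post_init__(self) -> None:
        if self.round == "R3":
            self.round = "R2"
        if self.round not in ("R1", "R2"):
            raise ValueError(f"round must be R1/R2/R3, got {self.round!r}")
        if self.stage3_total is None and self.stage3_competent is not None:
            raise DataIntegrityError(
                f"application {self.gmc_id!r}: stage3_competent present without stage3_total"
            )


@dataclass
class PerformanceRecord:
    """Training progression for an appointed trainee.

    All dates are integer months since January 2000.
    """

    gmc_id: str
    start_month: int
    ltft_months: float = 0.0
    oop_months: float = 0.0
    arcp4: bool | None = None
    registration_month: int | None = None
    censor_month: int = month_index("2015-08-27")

    def __post_init__(self) -> None:
        if self.ltft_months < 0 or self.oop_months < 0:
            raise DataIntegrityError(f"trainee {self.gmc_id}: negative LTFT/OOP time")
        if self.registration_month is not None:
            if self.registration_month < self.start_month:
                raise DataIntegrityError(
                    f"trainee {self.gmc_id}: registration precedes training start"
                )
            if self.arcp4:
                raise DataIntegrityError(
                    f"trainee {self.gmc_id}: registered despite release from training"
                )
        end = self.registration_month if self.registration_month is not None else self.censor_month
        if self.ltft_months + self.oop_months > max(end - self.start_month, 0) + 1e-9:
            raise DataIntegrityError(
                f"trainee {self.gmc_id}: LTFT + OOP exceed elapsed calendar time"
            )

    @property
    def calendar_months(self) -> int | None:
        if self.registration_month is None:
            return None
        return self.registration_month - self.start_month


class LoadResult(Sequence):
    """Records successfully parsed from a CSV plus a row-indexed rejects report."""

    def __init__(self, records: list, rejects: pd.DataFrame):
        self.records = records
        self.rejects = rejects

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator:
        return iter(self.records)


_APP_COLUMNS = [
    "gmc_id",
    "year",
    "round",
    "cps_score",
    "pd_score",
    "stage3_total",
    "stage3_competent",
    "withdrew",
    "offer_accepted",
    "passed_stage1",
    "took_stage2",
    "gender",
    "ethnicity_bme",
    "uk_pmq",
]

_PERF_COLUMNS = [
    "gmc_id",
    "start_date",
    "ltft_months",
    "oop_months",
    "arcp4",
    "registration_date",
    "censor_date",
]

_APP_MANDATORY = ["year", "round", "cps_score", "pd_score"]
_PERF_MANDATORY = ["gmc_id", "start_date"]


def _check_header(header: Sequence[str], mandatory: Sequence[str], what: str) -> None:
    missing = [c for c in mandatory if c not in header]
    if missing:
        raise SchemaError(f"{what} CSV is missing mandatory column(s): {', '.join(missing)}")


def _opt_float(cell: str) -> float | None:
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def load_applications(path: str | Path) -> LoadResult:
    """Read an applications CSV.

    Empty cells are missing values; rows coded Round 3 are recoded to Round 2.
    Unparseable rows are not silently dropped: they are collected into the
    returned :attr:`LoadResult.rejects` table, indexed by CSV row number.
    """
    records: list[ApplicationRecord] = []
    rejects: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        _check_header(reader.fieldnames, _APP_MANDATORY, "applications")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                records.append(
                    ApplicationRecord(
                        gmc_id=(row.get("gmc_id") or "").strip() or None,
                        year=int(row["year"]),
                        round=row["round"].strip(),
                        cps_score=float(row["cps_score"]),
                        pd_score=float(row["pd_score"]),
                        stage3_total=_opt_float(row.get("stage3_total", "")),
                        stage3_competent=parse_bool(row.get("stage3_competent", "")),
                        withdrew=parse_bool(row.get("withdrew", "")),
                        offer_accepted=parse_bool(row.get("offer_accepted", "")),
                        passed_stage1=parse_bool(row.get("passed_stage1", "true")) in (True, None),
                        took_stage2=parse_bool(row.get("took_stage2", "true")) in (True, None),
                        gender=(row.get("gender") or "F").strip(),
                        ethnicity_bme=bool(parse_bool(row.get("ethnicity_bme", "false"))),
                        uk_pmq=parse_bool(row.get("uk_pmq", "true")) in (True, None),
                    )
                )
            except (ValueError, KeyError) as exc:
                rejects.append({"row": i, "error": str(exc)})
    return LoadResult(records, pd.DataFrame(rejects, columns=["row", "error"]))


def write_applications(records: Iterable[ApplicationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_APP_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gmc_id or "",
                    r.year,
                    r.round,
                    repr(r.cps_score),
                    repr(r.pd_score),
                    "" if r.stage3_total is None else repr(r.stage3_total),
                    fmt_bool(r.stage3_competent),
                    fmt_bool(r.withdrew),
                    fmt_bool(r.offer_accepted),
                    fmt_bool(r.passed_stage1),
                    fmt_bool(r.took_stage2),
                    r.gender,
                    fmt_bool(r.ethnicity_bme),
                    fmt_bool(r.uk_pmq),
                ]
            )


def load_performance(path: str | Path) -> LoadResult:
    """Read a performance CSV. Dates are ISO-8601 and truncated to months."""
    records: list[PerformanceRecord] = []
    rejects: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        _check_header(reader.fieldnames, _PERF_MANDATORY, "performance")
        for i, row in enumerate(reader, start=2):
            try:
                reg = (row.get("registration_date") or "").strip()
                cen = (row.get("censor_date") or "").strip()
                kwargs = dict(
                    gmc_id=row["gmc_id"].strip(),
                    start_month=month_index(row["start_date"]),
                    ltft_months=_opt_float(row.get("ltft_months", "")) or 0.0,
                    oop_months=_opt_float(row.get("oop_months", "")) or 0.0,
                    arcp4=parse_bool(row.get("arcp4", "")),
                    registration_month=month_index(reg) if reg else None,
                )
                if cen:
                    kwargs["censor_month"] = month_index(cen)
                records.append(PerformanceRecord(**kwargs))
            except (ValueError, KeyError) as exc:
                rejects.append({"row": i, "error": str(exc)})
    return LoadResult(records, pd.DataFrame(rejects, columns=["row", "error"]))


def write_performance(records: Iterable[PerformanceRecord], path: str | Path) -> None:
    from ._util import month_to_iso

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PERF_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gmc_id,
                    month_to_iso(r.start_month),
                    repr(r.ltft_months),
                    repr(r.oop_months),
                    fmt_bool(r.arcp4),
                    "" if r.registration_month is None else month_to_iso(r.registration_month),
                    month_to_iso(r.censor_month),
                ]
            )


def fte_time(
    calendar_months: float,
    oop_months: float,
    ltft_months: float,
    ltft_factor: float = 1.67,
) -> float:
    """Full-time-equivalent training duration.

    Out-of-programme time is subtracted entirely; time spent less-than-full-time
    is scaled down by ``ltft_factor`` (1.67, i.e. LTFT counted at ~60% FTE).
    """
    if oop_months < 0 or ltft_months < 0:
        raise DataIntegrityError("negative OOP/LTFT time")
    if oop_months + ltft_months > calendar_months + 1e-9:
        raise DataIntegrityError(
            f"OOP ({oop_months}) + LTFT ({ltft_months}) exceed calendar time ({calendar_months})"
        )
    return (calendar_months - oop_months - ltft_months) + ltft_months / ltft_factor


class LinkedCohort:
    """Applications joined to performance outcomes, eligibility filters applied.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per included application. Missing values are ``NaN``.
    mask : pandas.DataFrame
        Boolean observed-value mask over :data:`IMPUTABLE_VARIABLES`
        (``True`` = observed).
    exclusions : dict
        Counts of raw rows removed by each eligibility filter.
    """

    def __init__(self, frame: pd.DataFrame, exclusions: dict | None = None):
        missing_cols = [c for c in PREDICTOR_VARIABLES + IMPUTABLE_VARIABLES if c not in frame]
        if missing_cols:
            raise SchemaError(f"cohort frame missing column(s): {', '.join(missing_cols)}")
        for col in PREDICTOR_VARIABLES:
            if frame[col].isna().any():
                raise DataIntegrityError(f"predictor column {col!r} has missing values")
        self.frame = frame.reset_index(drop=True)
        self.mask = self.frame[IMPUTABLE_VARIABLES].notna()
        self.exclusions = dict(exclusions or {})

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_years(self) -> int:
        return int(self.frame["year"].nunique())

    def copy(self) -> "LinkedCohort":
        return LinkedCohort(self.frame.copy(), self.exclusions)

    def is_complete(self) -> bool:
        """True when no imputable cell is missing (``fte_months`` may be
        structurally absent where ``arcp4`` is true)."""
        for var in IMPUTABLE_VARIABLES:
            miss = self.frame[var].isna()
            if var == "fte_months":
                miss &= self.frame["arcp4"] != 1.0
            if miss.any():
                return False
        return True


def _records_to_app_frame(apps: Iterable[ApplicationRecord]) -> pd.DataFrame:
    def b(v):
        return np.nan if v is None else float(v)

    rows = [
        {
            "gmc_id": a.gmc_id,
            "year": a.year,
            "round": a.round,
            "cps_score": a.cps_score,
            "pd_score": a.pd_score,
            "stage2_total": a.stage2_total,
            "stage3_total": np.nan if a.stage3_total is None else a.stage3_total,
            "stage3_competent": b(a.stage3_competent),
            "withdrew": b(a.withdrew),
            "offer_accepted": b(a.offer_accepted),
            "passed_stage1": bool(a.passed_stage1),
            "took_stage2": bool(a.took_stage2),
            "gender": a.gender,
            "ethnicity_bme": float(a.ethnicity_bme),
            "uk_pmq": float(a.uk_pmq),
        }
        for a in apps
    ]
    cols = [
        "gmc_id", "year", "round", "cps_score", "pd_score", "stage2_total",
        "stage3_total", "stage3_competent", "withdrew", "offer_accepted",
        "passed_stage1", "took_stage2", "gender", "ethnicity_bme", "uk_pmq",
    ]
    return pd.DataFrame(rows, columns=cols)


def link_and_filter(
    apps: Iterable[ApplicationRecord],
    perf: Iterable[PerformanceRecord] = (),
    ltft_factor: float = 1.67,
) -> LinkedCohort:
    """Link applications to performance records and apply eligibility filters.

    Excluded: applications without a GMC identifier, failing Stage 1, or
    withdrawing before Stage 2.  Performance attaches by exact GMC-number
    match, and only to the application with an accepted offer (a doctor's
    multiple unsuccessful applications remain as separate rows without
    outcome data).  Duplicate performance identifiers raise
    :class:`DuplicateIdentifierError`; performance records matching no
    application are ignored with a warning.
    """
    frame = _records_to_app_frame(apps)
    n_raw = len(frame)
    if n_raw == 0:
        frame = _records_to_app_frame([])

    excl = {}
    if n_raw:
        no_gmc = frame["gmc_id"].isna()
        failed_s1 = ~no_gmc & ~frame["passed_stage1"]
        no_s2 = ~no_gmc & frame["passed_stage1"] & ~frame["took_stage2"]
        excl = {
            "missing_gmc_id": int(no_gmc.sum()),
            "failed_stage1": int(failed_s1.sum()),
            "withdrew_before_stage2": int(no_s2.sum()),
        }
        frame = frame[~(no_gmc | failed_s1 | no_s2)].reset_index(drop=True)
    excl["included"] = len(frame)
    excl["raw_rows"] = n_raw

    # outcome columns, filled from performance where linkable
    frame["ltft"] = np.nan
    frame["oop"] = np.nan
    frame["arcp4"] = np.nan
    frame["fte_months"] = np.nan
    frame["ltft_months"] = np.nan
    frame["oop_months"] = np.nan

    perf = list(perf)
    seen: dict[str, PerformanceRecord] = {}
    for p in perf:
        if p.gmc_id in seen:
            raise DuplicateIdentifierError(f"duplicate performance record for GMC id {p.gmc_id}")
        seen[p.gmc_id] = p

    if len(frame):
        accepted = frame["offer_accepted"] == 1.0
        by_gmc: dict[str, int] = {}
        for idx in frame.index[accepted]:
            gid = frame.at[idx, "gmc_id"]
            by_gmc[gid] = idx  # at most one accepted application per doctor
        for gid, p in seen.items():
            idx = by_gmc.get(gid)
            if idx is None:
                warnings.warn(
                    f"performance record for GMC id {gid} matches no accepted application; ignored",
                    stacklevel=2,
                )
                continue
            frame.at[idx, "ltft"] = float(p.ltft_months > 0)
            frame.at[idx, "oop"] = float(p.oop_months > 0)
            frame.at[idx, "ltft_months"] = p.ltft_months
            frame.at[idx, "oop_months"] = p.oop_months
            if p.arcp4 is not None:
                frame.at[idx, "arcp4"] = float(p.arcp4)
            if p.registration_month is not None:
                frame.at[idx, "fte_months"] = fte_time(
                    p.calendar_months, p.oop_months, p.ltft_months, ltft_factor
                )

    return LinkedCohort(frame.drop(columns=["passed_stage1", "took_stage2"]), excl)


@dataclass
class AccountingSummary:
    """Application accounting per recruitment round over the study window."""

    included_r1: float
    included_r2: float
    withdrew_or_declined_r1: float
    withdrew_or_declined_r2: float
    n_years: int

    @property
    def max_fillable_r1(self) -> float:
        return self.included_r1 - self.withdrew_or_declined_r1

    @property
    def max_fillable_r2(self) -> float:
        return self.included_r2 - self.withdrew_or_declined_r2

    def annual_mean(self, total: float) -> int:
        if self.n_years <= 0:
            raise ValueError("n_years must be positive")
        return round_half_up(total / self.n_years)

    @classmethod
    def from_counts(
        cls,
        included_r1: float,
        withdrew_or_declined_r1: float,
        n_years: int,
        included_r2: float = 0.0,
        withdrew_or_declined_r2: float = 0.0,
    ) -> "AccountingSummary":
        if n_years <= 0:
            raise ValueError("n_years must be positive")
        return cls(included_r1, included_r2, withdrew_or_declined_r1, withdrew_or_declined_r2, n_years)


def _wd_count(frame: pd.DataFrame, rnd: str) -> float:
    sub = frame[frame["round"] == rnd]
    return float(((sub["withdrew"] == 1.0) | (sub["offer_accepted"] == 0.0)).sum())


def accounting_summary(
    cohort: LinkedCohort,
    imputations=None,
    n_years: int | None = None,
) -> AccountingSummary:
    """Included / withdrawn-or-declined / maximum-fillable counts per round.

    Withdrawn-or-declined means ``withdrew`` true or ``offer_accepted`` false.
    When those flags contain missing values an imputation set must be supplied
    and counts are averaged across the completed datasets.
    """
    if n_years is None:
        n_years = max(cohort.n_years, 1)
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    frame = cohort.frame
    inc_r1 = float((frame["round"] == "R1").sum())
    inc_r2 = float((frame["round"] == "R2").sum())

    has_missing = frame["withdrew"].isna().any() or frame["offer_accepted"].isna().any()
    if has_missing:
        if imputations is None:
            raise ValueError(
                "withdrawal/decline flags have missing values; supply an imputation set"
            )
        frames = [d.frame for d in imputations.datasets]
        wd_r1 = float(np.mean([_wd_count(f, "R1") for f in frames]))
        wd_r2 = float(np.mean([_wd_count(f, "R2") for f in frames]))
    else:
        wd_r1 = _wd_count(frame, "R1")
        wd_r2 = _wd_count(frame, "R2")
    return AccountingSummary(inc_r1, inc_r2, wd_r1, wd_r2, n_years)
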