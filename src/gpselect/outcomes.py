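"""Registration outcomes, pooling across imputations, and results analytics.

Training durations are measured in full-time-equivalent (FTE) months:
out-of-programme time is subtracted and less-than-full-time months are scaled
by 1/1.67 (~60% FTE).  A trainee counts as registering "within three years"
when their FTE time to registration is at most 36 months plus a two-month
grace period (inclusive thresholds), and analogously within five years;
release from training (ARCP Outcome 4) counts toward neither horizon.

The pooled results table holds, per (selection process x recruitment
target), the mean and standard deviation across the M completed datasets of
the annual number of selectees registering within each horizon.  The
analytics methods (:meth:`ResultsTable.registration_rate` and friends)
derive reported percentages from such a table; percentages round half-up to
whole percent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .cohort import LinkedCohort, fte_time  # re-exported: fte_time lives with the loaders
from .imputation import ImputationSet, pool_scalar
from .processes import ProcessKind, SelectedSet, SelectionRule, select

__all__ = [
    "FteThresholds",
    "OutcomeCounts",
    "ResultsTable",
    "ProcessComparison",
    "CellUnavailable",
    "fte_time",
    "registration_outcomes",
    "build_results_table",
    "load_table4",
    "DEFAULT_TARGETS",
]

#: The seven annual recruitment targets evaluated for every process.
DEFAULT_TARGETS = (1000, 1500, 2000, 2500, 3000, 3500, 4000)

_COLUMNS = ["process", "n_target", "mean_3y", "sd_3y", "mean_5y", "sd_5y", "fillable"]


class CellUnavailable(LookupError):
    """The requested (process, target) cell is absent or unfillable."""


@dataclass(frozen=True)
class FteThresholds:
    base_3y: float = 36.0
    base_5y: float = 60.0
    grace: float = 2.0
    ltft_factor: float = 1.67

    def __post_init__(self) -> None:
        if self.grace < 0:
            raise ValueError("grace must be non-negative")
        if self.ltft_factor < 1:
            raise ValueError("ltft_factor must be at least 1")

    @property
    def t3(self) -> float:
        return self.base_3y + self.grace

    @property
    def t5(self) -> float:
        return self.base_5y + self.grace


@dataclass(frozen=True)
class OutcomeCounts:
    kind: ProcessKind
    n_target: int
    n_filled: int
    reg_3y: int
    reg_5y: int

    def __post_init__(self) -> None:
        if not 0 <= self.reg_3y <= self.reg_5y <= self.n_filled:
            raise ValueError("expected 0 <= reg_3y <= reg_5y <= n_filled")


def registration_outcomes(
    selected: SelectedSet,
    dataset: LinkedCohort,
    thresholds: FteThresholds = FteThresholds(),
) -> OutcomeCounts:
    """Count selected applications registering within each horizon.

    Requires completed (imputed) outcome data for the selected rows; a
    released trainee or a structurally absent registration time counts
    toward neither horizon.
    """
    sub = dataset.frame.loc[selected.indices]
    if sub["arcp4"].isna().any():
        raise ValueError("selected records have missing arcp4; impute first")
    ok = sub["arcp4"] == 0.0
    fte = sub["fte_months"]
    reg3 = int((ok & fte.notna() & (fte <= thresholds.t3)).sum())
    reg5 = int((ok & fte.notna() & (fte <= thresholds.t5)).sum())
    return OutcomeCounts(selected.kind, selected.n_target, selected.n_filled, reg3, reg5)


@dataclass(frozen=True)
class ProcessComparison:
    d_reg_3y: float
    d_reg_5y: float
    d_extensions: float
    pct_reg_5y: float  # change relative to process_b, percent
    pct_extensions: float


class ResultsTable:
    """Pooled annual registration counts per (process, recruitment target)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"results table missing column(s): {missing}")
        frame = frame.copy()
        frame["process"] = frame["process"].map(lambda p: ProcessKind(p).value)
        self.frame = frame.reset_index(drop=True)

    # -- access ------------------------------------------------------------

    def cell(self, process: ProcessKind | str, n_target: int) -> pd.Series:
        key = ProcessKind(process).value
        rows = self.frame[(self.frame["process"] == key) & (self.frame["n_target"] == n_target)]
        if rows.empty:
            raise CellUnavailable(f"no cell for ({key}, {n_target})")
        row = rows.iloc[0]
        if not row["fillable"] or pd.isna(row["mean_5y"]):
            raise CellUnavailable(f"({key}, {n_target}) is not fillable")
        return row

    def targets(self, process: ProcessKind | str, fillable_only: bool = True) -> list[int]:
        key = ProcessKind(process).value
        rows = self.frame[self.frame["process"] == key]
        if fillable_only:
            rows = rows[rows["fillable"].astype(bool) & rows["mean_5y"].notna()]
        return sorted(int(t) for t in rows["n_target"])

    # -- analytics ---------------------------------------------------------

    def registration_rate(self, process, n_target: int, horizon: str = "5y") -> int:
        """Pooled registrations as a percent of posts filled, whole percent."""
        row = self.cell(process, n_target)
        return round_half_up(100.0 * row[f"mean_{horizon}"] / n_target)

    def average_registration_rate(self, process, horizon: str = "5y") -> int:
        """Per-target registration percentages averaged over every fillable
        target, then rounded (the 'regardless of the number selected' figure)."""
        pcts = [
            100.0 * self.cell(process, t)[f"mean_{horizon}"] / t for t in self.targets(process)
        ]
        if not pcts:
            raise CellUnavailable(f"no fillable cells for {process}")
        return round_half_up(float(np.mean(pcts)))

    def extension_proportion(self, process, n_target: int) -> int:
        """Share of 5-year registrants needing more than the 3-year threshold."""
        row = self.cell(process, n_target)
        if row["mean_5y"] <= 0:
            raise CellUnavailable("extension proportion undefined: no 5-year registrants")
        return round_half_up(100.0 * (row["mean_5y"] - row["mean_3y"]) / row["mean_5y"])

    def marginal_cohort_stats(self, process, n_low: int, n_high: int) -> tuple[int, int | None]:
        """Outcomes of the applicants ranked between two targets.

        Returns (5-year registration percent of the marginal cohort,
        extension percent among its 5-year registrants — ``None`` when there
        are no marginal registrants).
        """
        if n_high <= n_low:
            raise ValueError("n_high must exceed n_low")
        lo, hi = self.cell(process, n_low), self.cell(process, n_high)
        m5 = hi["mean_5y"] - lo["mean_5y"]
        m3 = hi["mean_3y"] - lo["mean_3y"]
        reg_pct = round_half_up(100.0 * m5 / (n_high - n_low))
        ext_pct = round_half_up(100.0 * (m5 - m3) / m5) if m5 > 0 else None
        return reg_pct, ext_pct

    def compare_processes(self, process_a, process_b, n_target: int) -> ProcessComparison:
        """Differences of pooled means, a minus b, with percent changes
        relative to process b (extensions = 5-year minus 3-year counts)."""
        a, b = self.cell(process_a, n_target), self.cell(process_b, n_target)
        ext_a = a["mean_5y"] - a["mean_3y"]
        ext_b = b["mean_5y"] - b["mean_3y"]
        return ProcessComparison(
            d_reg_3y=float(a["mean_3y"] - b["mean_3y"]),
            d_reg_5y=float(a["mean_5y"] - b["mean_5y"]),
            d_extensions=float(ext_a - ext_b),
            pct_reg_5y=float(100.0 * (a["mean_5y"] - b["mean_5y"]) / b["mean_5y"]),
            pct_extensions=float(100.0 * (ext_a - ext_b) / ext_b) if ext_b else float("nan"),
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        frame = pd.read_csv(path)
        frame["fillable"] = frame["fillable"].astype(bool)
        return cls(frame)

    def plot(self, ax=None, target_line: float | None = 3100.0):
        """Registrations against posts filled, one line per process and
        horizon, with the optimal-selection diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        for process in sorted(self.frame["process"].unique()):
            ts = self.targets(process)
            for horizon, style in (("3y", "-"), ("5y", "--")):
                ys = [self.cell(process, t)[f"mean_{horizon}"] for t in ts]
                ax.plot(ts, ys, style, label=f"{process} ({horizon})")
        lim = self.frame["n_target"].max()
        ax.plot([0, lim], [0, lim], ":", color="grey", label="optimal (gradient 1)")
        if target_line:
            ax.axhline(target_line, color="black", lw=0.8)
        ax.set_xlabel("training posts filled per year")
        ax.set_ylabel("GP registrations per year")
        ax.legend(fontsize=7)
        return ax


def build_results_table(
    imputations: ImputationSet,
    rules: Iterable[SelectionRule],
    targets: Sequence[int] = DEFAULT_TARGETS,
    thresholds: FteThresholds = FteThresholds(),
    by_year: bool = True,
    annualise: bool = True,
) -> ResultsTable:
    """Run every (rule, target) on each completed dataset and pool.

    Counts are divided by the number of application years when ``annualise``
    so cells read as annual means.  A cell is flagged unfillable when any
    completed dataset cannot fill the target.
    """
    rows = []
    n_years = max(imputations.datasets[0].n_years, 1) if annualise else 1
    for rule in rules:
        for target in targets:
            r3, r5, fillable = [], [], True
            for m_idx, dataset in enumerate(imputations.datasets):
                # fixed selection seed per imputation so pooled SD reflects
                # imputation variability, not selection noise
                rule_m = SelectionRule(rule.kind, rule.cut_score, rule.seed + m_idx, rule.rank_by)
                chosen = select(rule_m, dataset, target, by_year=by_year)
                if chosen.n_filled < chosen.n_target:
                    fillable = False
                    break
                counts = registration_outcomes(chosen, dataset, thresholds)
                r3.append(counts.reg_3y / n_years)
                r5.append(counts.reg_5y / n_years)
            if fillable:
                p3, p5 = pool_scalar(r3), pool_scalar(r5)
                rows.append([rule.kind.value, target, p3.mean, p3.sd, p5.mean, p5.sd, True])
            else:
                rows.append([rule.kind.value, target, np.nan, np.nan, np.nan, np.nan, False])
    return ResultsTable(pd.DataFrame(rows, columns=_COLUMNS))


def load_table4() -> ResultsTable:
    """The published pooled results table, shipped as a package fixture."""
    with importlib.resources.files("gpselect").joinpath("data/table4.csv").open("r") as fh:
        return ResultsTable.from_csv(fh)
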