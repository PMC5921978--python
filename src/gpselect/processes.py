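"""The four candidate selection processes and post-filling logic.

Applications that withdrew from the selection process or declined an offer
are excluded from every process.  Only the historical cut-score process uses
Round 2: under every other rule all posts are filled in Round 1.

Ranked rules break score ties with a seeded uniform draw, which keeps runs
reproducible and makes the selected set at target ``k`` a subset of the set
at ``k + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import LinkedCohort

__all__ = ["ProcessKind", "SelectionRule", "SelectedSet", "eligible_pool", "select", "max_fill"]


class ProcessKind(str, Enum):
    RANDOM = "random"
    PROCESS_2015 = "process_2015"
    STAGE2_ONLY = "stage2_only"
    STAGE3_ONLY = "stage3_only"


@dataclass(frozen=True)
class SelectionRule:
    """A selection process plus the knobs it needs.

    ``cut_score`` applies to each Stage 2 test under the historical process;
    ``seed`` drives random selection and tie-breaking.  When demand within a
    round exceeds supply the historical process ranks above-cut candidates by
    ``rank_by`` ("combined" = Stage 2 + Stage 3 totals).
    """

    kind: ProcessKind
    cut_score: float = 181.0
    seed: int = 0
    rank_by: str = "combined"  # "combined" | "stage2" | "stage3"

    def __post_init__(self) -> None:
        if self.kind == ProcessKind.PROCESS_2015 and self.cut_score <= 0:
            raise ValueError("cut_score must be positive for the historical process")
        if self.rank_by not in ("combined", "stage2", "stage3"):
            raise ValueError(f"unknown rank_by: {self.rank_by!r}")


@dataclass
class SelectedSet:
    """Row indices of applications filling posts."""

    indices: np.ndarray
    n_target: int
    n_filled: int
    kind: ProcessKind
    by_year: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_filled > self.n_target:
            raise ValueError("cannot fill more posts than targeted")

    def __len__(self) -> int:
        return self.n_filled


def eligible_pool(dataset: LinkedCohort, rnd: str) -> np.ndarray:
    """Row indices of the given round's applications that neither withdrew nor
    declined.  Requires a completed dataset (no missing decision flags)."""
    frame = dataset.frame
    if frame["withdrew"].isna().any() or frame["offer_accepted"].isna().any():
        raise ValueError("dataset has missing withdrawal/decline flags; impute first")
    keep = (frame["round"] == rnd) & (frame["withdrew"] == 0.0) & (frame["offer_accepted"] == 1.0)
    return frame.index[keep].to_numpy()


def _tiebreak(rule: SelectionRule, n: int) -> np.ndarray:
    return np.random.default_rng(rule.seed).random(n)


def _ranked(frame: pd.DataFrame, pool: np.ndarray, score_col, jitter: np.ndarray) -> np.ndarray:
    score = (
        frame.loc[pool, score_col].to_numpy(float)
        if isinstance(score_col, str)
        else score_col[pool]
    )
    order = np.lexsort((jitter[pool], -score))
    return pool[order]


def _select_in_year(
    rule: SelectionRule,
    frame: pd.DataFrame,
    year_mask: pd.Series,
    n_target: int,
    jitter: np.ndarray,
    rng: np.random.Generator,
    dataset: LinkedCohort,
) -> np.ndarray:
    def pool(rnd: str) -> np.ndarray:
        p = eligible_pool(dataset, rnd)
        return p[year_mask.to_numpy()[p]]

    if rule.kind == ProcessKind.RANDOM:
        r1 = pool("R1")
        take = min(n_target, len(r1))
        return rng.choice(r1, size=take, replace=False)
    if rule.kind == ProcessKind.STAGE2_ONLY:
        return _ranked(frame, pool("R1"), "stage2_total", jitter)[:n_target]
    if rule.kind == ProcessKind.STAGE3_ONLY:
        return _ranked(frame, pool("R1"), "stage3_total", jitter)[:n_target]

    # historical cut-score process: both tests above the cut and competent,
    # Round 1 filled before Round 2
    rank_col = {
        "combined": (frame["stage2_total"] + frame["stage3_total"]).to_numpy(float),
        "stage2": "stage2_total",
        "stage3": "stage3_total",
    }[rule.rank_by]
    chosen: list[np.ndarray] = []
    remaining = n_target
    for rnd in ("R1", "R2"):
        if remaining <= 0:
            break
        p = pool(rnd)
        ok = (
            (frame.loc[p, "cps_score"].to_numpy(float) >= rule.cut_score)
            & (frame.loc[p, "pd_score"].to_numpy(float) >= rule.cut_score)
            & (frame.loc[p, "stage3_competent"].to_numpy(float) == 1.0)
        )
        picked = _ranked(frame, p[ok], rank_col, jitter)[:remaining]
        chosen.append(picked)
        remaining -= len(picked)
    return np.concatenate(chosen) if chosen else np.empty(0, dtype=int)


def select(
    rule: SelectionRule,
    dataset: LinkedCohort,
    n_target: int,
    by_year: bool = True,
) -> SelectedSet:
    """Fill up to ``n_target`` posts (per application year when ``by_year``,
    mirroring annual recruitment rounds; in one pooled pass otherwise).

    ``n_filled < n_target`` signals that the rule could not fill the target.
    """
    if n_target < 0:
        raise ValueError("n_target must be non-negative")
    frame = dataset.frame
    if rule.kind in (ProcessKind.STAGE3_ONLY, ProcessKind.PROCESS_2015):
        if frame["stage3_total"].isna().any() or frame["stage3_competent"].isna().any():
            raise ValueError("dataset has missing Stage 3 values; impute first")
    jitter = _tiebreak(rule, len(frame))
    rng = np.random.default_rng(rule.seed)

    years = sorted(frame["year"].unique()) if by_year else [None]
    picked: list[np.ndarray] = []
    per_year: dict[int, int] = {}
    for year in years:
        mask = frame["year"] == year if year is not None else pd.Series(True, index=frame.index)
        sel = _select_in_year(rule, frame, mask, n_target, jitter, rng, dataset)
        picked.append(sel)
        if year is not None:
            per_year[int(year)] = len(sel)
    indices = np.concatenate(picked) if picked else np.empty(0, dtype=int)
    total_target = n_target * len(years)
    return SelectedSet(
        indices=indices,
        n_target=total_target,
        n_filled=len(indices),
        kind=rule.kind,
        by_year=per_year,
    )


def max_fill(rule: SelectionRule, dataset: LinkedCohort, by_year: bool = False) -> int:
    """Largest achievable ``n_filled`` for the rule on this dataset: the
    Round 1 pool size for rules without a cut, the count passing cut scores
    and competency (Rounds 1 and 2) for the historical process."""
    return select(rule, dataset, len(dataset.frame), by_year=by_year).n_filled
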