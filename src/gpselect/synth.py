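"""Synthetic applicant cohorts with selection-induced missingness.

The confidential selection/performance dataset cannot be redistributed, so
this module generates cohorts with the statistical structure the analysis
relies on: Stage 2 and Stage 3 scores correlated through a latent aptitude,
training outcomes (release from training, time to registration) that worsen
as aptitude falls, and the missingness pattern produced by a cut-score
selection process — Stage 3 observed only above the cut, training outcomes
observed only for appointed trainees.  Because every masking decision is a
function of observed scores, the missingness is missing-at-random by
construction.

Alongside the observable cohort a complete :class:`TruthTable` is returned,
providing ground truth for parameter-recovery tests of the imputation engine.

Default parameters are calibrated so that random selection from the eligible
pool registers roughly 52% of selectees within the 3-year FTE threshold and
79% within the 5-year threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import LinkedCohort

__all__ = ["GeneratorParams", "TruthTable", "generate_cohort", "apply_historical_selection", "oracle_outcomes"]

logger = logging.getLogger(__name__)

_TRUTH_COLS = [
    "stage3_total",
    "stage3_competent",
    "withdrew",
    "offer_accepted",
    "ltft",
    "oop",
    "ltft_months",
    "oop_months",
    "arcp4",
    "never_registered",
    "fte_months",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    Scores sit on an arbitrary points scale chosen so the historical cut of
    181 falls ~1.7 SD below the per-test mean, excluding a minority of
    applicants.  ``loading_*`` are correlations of scores with the latent
    aptitude.  Outcome coefficients act on standardised aptitude.
    """

    n_per_year: int = 6340
    n_years: int = 4
    first_year: int = 2011
    r2_fraction: float = 0.18
    latent_sd: float = 1.0
    score_mean: float = 250.0
    score_sd: float = 40.0
    loading_stage2: float = 0.6
    loading_stage3: float = 0.55
    stage3_mean: float = 76.0
    stage3_sd: float = 10.0
    competency_cut: float = 72.0  # stage3_total below this => not competent
    p_withdraw: float = 0.12
    p_decline: float = 0.09
    withdraw_slope: float = 0.0  # optional aptitude dependence (log-odds/SD)
    decline_slope: float = 0.0
    ltft_rate: float = 0.18
    oop_rate: float = 0.10
    ltft_duration_mean: float = 14.0
    oop_duration_mean: float = 8.0
    arcp4_intercept: float = -2.89  # logit scale; ~5% marginal release rate
    arcp4_slope: float = 0.55
    ontime_intercept: float = 0.21  # P(no extension beyond the grace period)
    ontime_slope: float = 0.75
    delay_shape: float = 1.3
    delay_scale: float = 16.0  # gamma scale of the extension length, months
    delay_slope: float = 0.30  # log-scale reduction per SD of aptitude
    p_never: float = 0.0
    grace: float = 2.0
    base_months: float = 36.0
    historical_cut: float = 181.0
    n_appointed_per_year: int = 3000
    p_female: float = 0.55
    p_bme: float = 0.40
    p_uk_pmq: float = 0.75
    female_effect: float = 0.0  # optional demographic effects on aptitude
    bme_effect: float = 0.0
    uk_pmq_effect: float = 0.0

    def validate(self) -> None:
        probs = {
            "r2_fraction": self.r2_fraction,
            "p_withdraw": self.p_withdraw,
            "p_decline": self.p_decline,
            "ltft_rate": self.ltft_rate,
            "oop_rate": self.oop_rate,
            "p_never": self.p_never,
            "p_female": self.p_female,
            "p_bme": self.p_bme,
            "p_uk_pmq": self.p_uk_pmq,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.score_sd <= 0 or self.stage3_sd <= 0 or self.latent_sd <= 0:
            raise ValueError("score/latent dispersions must be positive")
        if min(self.ltft_duration_mean, self.oop_duration_mean, self.delay_scale, self.delay_shape) <= 0:
            raise ValueError("durations and delay parameters must be positive")
        for name in ("loading_stage2", "loading_stage3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_per_year <= 0 or self.n_years <= 0:
            raise ValueError("cohort dimensions must be positive")


class TruthTable:
    """Complete (missingness-free) per-application outcomes.

    ``fte_months`` is absent exactly where the trainee is released from
    training (ARCP Outcome 4) or flagged never-registered; everything else is
    fully observed.
    """

    def __init__(self, frame: pd.DataFrame):
        expected = [c for c in _TRUTH_COLS if c not in frame.columns]
        if expected:
            raise ValueError(f"truth table missing column(s): {expected}")
        structural = (frame["arcp4"] == 1.0) | (frame["never_registered"] == 1.0)
        if frame.loc[~structural, "fte_months"].isna().any():
            raise ValueError("fte_months missing outside ARCP4/never-registered rows")
        if frame.loc[structural, "fte_months"].notna().any():
            raise ValueError("fte_months present in ARCP4/never-registered rows")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: GeneratorParams, seed: int = 0) -> tuple[pd.DataFrame, TruthTable]:
    """Draw a complete applicant cohort.

    Returns the applications frame (all columns observed — masking is applied
    separately by :func:`apply_historical_selection`) and the matching
    :class:`TruthTable`.  Deterministic given ``params`` and ``seed``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_per_year * params.n_years

    year = np.repeat(np.arange(params.first_year, params.first_year + params.n_years), params.n_per_year)
    rnd = np.where(rng.random(n) < params.r2_fraction, "R2", "R1")
    female = rng.random(n) < params.p_female
    bme = rng.random(n) < params.p_bme
    uk = rng.random(n) < params.p_uk_pmq

    u = rng.normal(0.0, params.latent_sd, n)
    u = u + params.female_effect * female + params.bme_effect * bme + params.uk_pmq_effect * uk
    z = u / params.latent_sd  # standardised aptitude drives all outcome models

    l2 = params.loading_stage2
    resid2 = np.sqrt(max(1.0 - l2 * l2, 0.0))
    cps = params.score_mean + params.score_sd * (l2 * z + resid2 * rng.normal(size=n))
    pd_score = params.score_mean + params.score_sd * (l2 * z + resid2 * rng.normal(size=n))
    l3 = params.loading_stage3
    resid3 = np.sqrt(max(1.0 - l3 * l3, 0.0))
    stage3 = params.stage3_mean + params.stage3_sd * (l3 * z + resid3 * rng.normal(size=n))
    competent = stage3 >= params.competency_cut

    withdrew = rng.random(n) < _sigmoid(
        np.log(params.p_withdraw / (1 - params.p_withdraw)) - params.withdraw_slope * z
    ) if params.p_withdraw not in (0.0, 1.0) else rng.random(n) < params.p_withdraw
    decline = rng.random(n) < _sigmoid(
        np.log(params.p_decline / (1 - params.p_decline)) - params.decline_slope * z
    ) if params.p_decline not in (0.0, 1.0) else rng.random(n) < params.p_decline

    arcp4 = rng.random(n) < _sigmoid(params.arcp4_intercept - params.arcp4_slope * z)
    never = (rng.random(n) < params.p_never) & ~arcp4

    on_time = rng.random(n) < _sigmoid(params.ontime_intercept + params.ontime_slope * z)
    extension = rng.gamma(params.delay_shape, params.delay_scale * np.exp(-params.delay_slope * z), n)
    delay = np.where(on_time, 0.0, params.grace + extension)
    fte = params.base_months + delay
    fte = np.where(arcp4 | never, np.nan, fte)

    ltft = rng.random(n) < params.ltft_rate
    oop = rng.random(n) < params.oop_rate
    ltft_months = np.where(ltft, np.minimum(rng.exponential(params.ltft_duration_mean, n), 48.0), 0.0)
    oop_months = np.where(oop, np.minimum(rng.exponential(params.oop_duration_mean, n), 24.0), 0.0)

    apps = pd.DataFrame(
        {
            "gmc_id": [f"G{seed % 97:02d}{i:07d}" for i in range(n)],
            "year": year,
            "round": rnd,
            "cps_score": cps,
            "pd_score": pd_score,
            "stage2_total": cps + pd_score,
            "stage3_total": stage3,
            "stage3_competent": competent.astype(float),
            "withdrew": withdrew.astype(float),
            "offer_accepted": (~decline).astype(float),
            "gender": np.where(female, "F", "M"),
            "ethnicity_bme": bme.astype(float),
            "uk_pmq": uk.astype(float),
            "ltft": ltft.astype(float),
            "oop": oop.astype(float),
            "ltft_months": ltft_months,
            "oop_months": oop_months,
            "arcp4": arcp4.astype(float),
            "fte_months": fte,
        }
    )
    truth = TruthTable(
        pd.DataFrame(
            {
                "stage3_total": stage3,
                "stage3_competent": competent.astype(float),
                "withdrew": withdrew.astype(float),
                "offer_accepted": (~decline).astype(float),
                "ltft": ltft.astype(float),
                "oop": oop.astype(float),
                "ltft_months": ltft_months,
                "oop_months": oop_months,
                "arcp4": arcp4.astype(float),
                "never_registered": never.astype(float),
                "fte_months": fte,
            }
        )
    )
    return apps, truth


def apply_historical_selection(
    apps: pd.DataFrame,
    truth: TruthTable,
    params: GeneratorParams,
) -> LinkedCohort:
    """Mask the complete cohort the way the historical cut-score process would.

    Stage 3 scores are hidden for applications below the cut on either Stage 2
    test; withdrawal is observable only above the cut (those applicants had a
    process to withdraw from); offers cascade down the combined Stage 2 +
    Stage 3 ranking, Round 1 before Round 2, until the annual appointment
    quota is met; training outcomes are observable for appointees only.

    Masking only hides values — it never alters them — so restoring the truth
    table reproduces the generated cohort exactly.
    """
    if len(apps) != len(truth):
        raise ValueError("applications and truth table must share an index")
    frame = apps.copy().reset_index(drop=True)
    n = len(frame)

    above_cut = (frame["cps_score"].to_numpy() >= params.historical_cut) & (
        frame["pd_score"].to_numpy() >= params.historical_cut
    )
    withdrew = truth.frame["withdrew"].to_numpy() == 1.0
    competent = truth.frame["stage3_competent"].to_numpy() == 1.0
    accepts = truth.frame["offer_accepted"].to_numpy() == 1.0

    # attended the selection centre: above cut and did not withdraw
    attended = above_cut & ~withdrew
    offered = np.zeros(n, dtype=bool)
    appointed = np.zeros(n, dtype=bool)

    score = frame["stage2_total"].to_numpy() + frame["stage3_total"].to_numpy()
    eligible = attended & competent
    for year in np.unique(frame["year"].to_numpy()):
        in_year = frame["year"].to_numpy() == year
        quota = params.n_appointed_per_year
        for rnd in ("R1", "R2"):
            if quota <= 0:
                break
            pool = np.flatnonzero(in_year & eligible & (frame["round"].to_numpy() == rnd))
            pool = pool[np.argsort(-score[pool], kind="stable")]
            for idx in pool:  # offers cascade down the ranking past decliners
                offered[idx] = True
                if accepts[idx]:
                    appointed[idx] = True
                    quota -= 1
                    if quota == 0:
                        break
        if quota > 0:
            n_eligible = int((in_year & eligible).sum())
            logger.warning(
                "year %s: appointment quota %d not met (eligible pool %d, filled %d)",
                year,
                params.n_appointed_per_year,
                n_eligible,
                params.n_appointed_per_year - quota,
            )

    frame.loc[~above_cut, ["stage3_total", "stage3_competent"]] = np.nan
    frame.loc[~attended, ["stage3_total", "stage3_competent"]] = np.nan
    frame.loc[~above_cut, "withdrew"] = np.nan
    frame.loc[~offered, "offer_accepted"] = np.nan
    outcome_cols = ["ltft", "oop", "ltft_months", "oop_months", "arcp4", "fte_months"]
    frame.loc[~appointed, outcome_cols] = np.nan

    excl = {"raw_rows": n, "included": n}
    return LinkedCohort(frame, excl)


def oracle_outcomes(truth: TruthTable, selected: Sequence[int], horizon: float) -> int:
    """Ground-truth count of selected applications registering within
    ``horizon`` FTE months (inclusive)."""
    idx = np.asarray(list(selected), dtype=int)
    if idx.size == 0:
        return 0
    fte = truth.frame["fte_months"].to_numpy()[idx]
    return int(np.sum(~np.isnan(fte) & (fte <= horizon)))
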