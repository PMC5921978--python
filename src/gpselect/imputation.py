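"""Fully-conditional-specification (chained-equations) multiple imputation.

Each variable with missing values is taken in turn as the dependent variable
with all other variables as predictors; missing cells are redrawn from the
fitted conditional model, and the cycle repeats.  Binary variables use
logistic regression with coefficient draws from the asymptotic posterior;
continuous variables use Bayesian linear regression followed by predictive
mean matching (PMM), so every imputed value is an observed donor value and
durations can never go negative.  Because selection restricts the range of
scores among those with observed outcomes, the conditional models
extrapolate from the always-observed predictors under a missing-at-random
assumption; no explicit truncation correction is applied.

Structural rule: the full-time-equivalent time to registration exists only
for trainees not released from training, so ``fte_months`` is imputed only
where ``arcp4`` (observed or currently imputed) is false and is structurally
absent where it is true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import IMPUTABLE_VARIABLES, LinkedCohort

__all__ = ["ImputationConfig", "ImputationSet", "PooledEstimate", "impute", "pool_scalar"]

logger = logging.getLogger(__name__)

#: Causal order of the training pathway, used as the default cycling order.
DEFAULT_VARIABLE_ORDER = tuple(IMPUTABLE_VARIABLES)

_CONTINUOUS_VARS = {"stage3_total", "fte_months"}


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 10
    n_iterations: int = 10
    pmm_donors: int = 5
    seed: int = 0
    variable_order: tuple[str, ...] = DEFAULT_VARIABLE_ORDER
    ridge: float = 1e-5  # fallback penalty when a conditional fit fails

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2 (imputation variability is undefined otherwise)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be at least 1")
        unknown = set(self.variable_order) - set(IMPUTABLE_VARIABLES)
        if unknown:
            raise ValueError(f"unknown imputable variable(s): {sorted(unknown)}")


@dataclass
class ImputationSet:
    """M completed copies of a cohort plus provenance and convergence traces."""

    datasets: list[LinkedCohort]
    config: ImputationConfig
    #: traces[var] has shape (m, n_iterations): mean of imputed cells per cycle.
    traces: dict[str, np.ndarray]
    #: fallback/singularity events logged during fitting
    events: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    mean: float
    sd: float
    p2_5: float
    p97_5: float


def pool_scalar(estimates: Sequence[float]) -> PooledEstimate:
    """Pool one scalar estimated on each completed dataset.

    Returns the arithmetic mean, the sample standard deviation across
    imputations (in effect the standard error of the pooled estimate) and the
    empirical 2.5th/97.5th percentiles as approximate 95% bounds.
    """
    x = np.asarray(list(estimates), dtype=float)
    if x.size < 2:
        raise ValueError("pooling requires at least 2 estimates")
    return PooledEstimate(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        p2_5=float(np.percentile(x, 2.5)),
        p97_5=float(np.percentile(x, 97.5)),
    )


# ---------------------------------------------------------------------------
# conditional models


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Penalised IRLS logistic fit; returns (beta, covariance).

    statsmodels' regularised fits do not expose a covariance matrix, so this
    fallback is computed directly: cov = (X'WX + lam*I)^-1 at convergence.
    """
    n, p = X.shape
    beta = np.zeros(p)
    I = np.eye(p) * lam
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = X.T @ (X * w[:, None]) + I
        g = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + I)
    return beta, cov


def _draw_binary(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    ridge: float,
    events: list[str],
    label: str,
) -> np.ndarray:
    """Impute a binary variable: fit logistic regression on the observed rows,
    draw coefficients from the asymptotic posterior, draw Bernoulli outcomes."""
    if y_obs.min() == y_obs.max():  # constant observed margin: no model to fit
        p = float(np.clip(y_obs.mean(), 1e-6, 1 - 1e-6))
        return (rng.random(X_mis.shape[0]) < p).astype(float)
    beta = cov = None
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("logistic fit did not converge (separation?)")
        cov = np.asarray(fit.cov_params())
        beta = np.asarray(fit.params)
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError("non-finite logistic fit")
    except Exception as exc:  # separation / singular design
        events.append(f"{label}: logistic fit failed ({exc}); ridge fallback")
        logger.info("ridge fallback for %s: %s", label, exc)
        beta, cov = _ridge_logit(X_obs, y_obs, max(ridge * X_obs.shape[0], 1e-4))
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        events.append(f"{label}: non-PSD covariance; diagonal draw")
        L = np.diag(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    beta_star = beta + L @ rng.standard_normal(len(beta))
    p = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ beta_star, -30, 30)))
    return (rng.random(X_mis.shape[0]) < p).astype(float)


def _draw_continuous_pmm(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    donors: int,
    ridge: float,
    events: list[str],
    label: str,
) -> np.ndarray:
    """Impute a continuous variable by Bayesian linear regression + type-1 PMM.

    Observed cases are scored with the least-squares coefficients, missing
    cases with a posterior draw; each missing case then receives the observed
    value of one of its ``donors`` nearest neighbours in predicted space.
    """
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + ridge * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    try:
        L = np.linalg.cholesky(XtX_inv * sigma2)
    except np.linalg.LinAlgError:
        events.append(f"{label}: singular linear design; diagonal draw")
        L = np.diag(np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0)))
    beta_star = beta_hat + L @ rng.standard_normal(p)

    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star

    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    k = min(donors, n)
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k sorted neighbours around each insertion point,
    # then the k closest of those; vectorised across all missing cells
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    dist = np.abs(sorted_pred[cand] - pred_mis[:, None])
    nearest = np.take_along_axis(cand, np.argsort(dist, axis=1, kind="stable")[:, :k], axis=1)
    pick = rng.integers(0, k, size=len(pred_mis))
    return sorted_y[nearest[np.arange(len(pred_mis)), pick]]


# ---------------------------------------------------------------------------
# engine


def _predictor_matrix(frame: pd.DataFrame, target: str) -> np.ndarray:
    """Design matrix for one conditional model: intercept, the always-observed
    predictors, and every other imputable variable at its current value.

    Structurally absent ``fte_months`` cells (released trainees) are filled
    with the observed mean purely for use as a predictor — ``arcp4`` itself is
    in the matrix, so the fill carries no extra information.
    """
    cols = [
        np.ones(len(frame)),
        (frame["round"] == "R2").to_numpy(float),
        frame["cps_score"].to_numpy(float),
        frame["pd_score"].to_numpy(float),
        (frame["gender"] == "F").to_numpy(float),
        frame["ethnicity_bme"].to_numpy(float),
        frame["uk_pmq"].to_numpy(float),
    ]
    for var in IMPUTABLE_VARIABLES:
        if var == target:
            continue
        v = frame[var].to_numpy(float)
        if np.isnan(v).any():
            fill = np.nanmean(v)
            v = np.where(np.isnan(v), 0.0 if np.isnan(fill) else fill, v)
        cols.append(v)
    X = np.column_stack(cols)
    # standardise score columns for numerical stability of the IRLS/Cholesky
    for j in (2, 3):
        sd = X[:, j].std()
        if sd > 0:
            X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    return X


def _initialise(frame: pd.DataFrame, mask: pd.DataFrame, rng: np.random.Generator) -> None:
    """Fill every missing imputable cell with a random draw from the observed
    margin of that variable (in place)."""
    for var in IMPUTABLE_VARIABLES:
        obs = frame.loc[mask[var], var].to_numpy(float)
        mis_idx = frame.index[~mask[var]]
        if len(mis_idx) == 0:
            continue
        if obs.size == 0:
            raise ValueError(f"variable {var!r} is 100% missing: nothing to impute from")
        frame.loc[mis_idx, var] = rng.choice(obs, size=len(mis_idx), replace=True)


def _apply_structural_rules(frame: pd.DataFrame, mask: pd.DataFrame) -> None:
    """fte_months exists only where arcp4 is false (observed or imputed)."""
    structurally_absent = (~mask["fte_months"]) & (frame["arcp4"] == 1.0)
    frame.loc[frame.index[structurally_absent], "fte_months"] = np.nan


def impute(cohort: LinkedCohort, config: ImputationConfig | None = None) -> ImputationSet:
    """Produce M completed copies of ``cohort`` by chained-equations imputation.

    Observed cells are never modified and are identical across all M datasets.
    Reproducible: the same cohort, config and seed give an identical result.
    """
    config = config or ImputationConfig()
    mask = cohort.mask
    order = [v for v in config.variable_order if not mask[v].all()]
    events: list[str] = []
    traces = {v: np.full((config.m, config.n_iterations), np.nan) for v in order}

    datasets: list[LinkedCohort] = []
    streams = np.random.default_rng(config.seed).spawn(config.m)
    for m_idx, rng in enumerate(streams):
        frame = cohort.frame.copy()
        _initialise(frame, mask, rng)
        for it in range(config.n_iterations):
            for var in order:
                mis = ~mask[var]
                if var == "fte_months":
                    # released trainees have no registration time to impute
                    mis = mis & (frame["arcp4"] != 1.0)
                    frame.loc[frame.index[(~mask[var]) & (frame["arcp4"] == 1.0)], var] = np.nan
                    if not mis.any():
                        continue
                    obs = mask[var]
                else:
                    obs = mask[var]
                X = _predictor_matrix(frame, var)
                X_obs, X_mis = X[obs.to_numpy()], X[mis.to_numpy()]
                # drop predictors constant on the fitting subsample (e.g.
                # offer_accepted is 1 for everyone with observed outcomes);
                # they are collinear with the intercept and break the fit
                keep = X_obs.std(axis=0) > 0
                keep[0] = True
                X_obs, X_mis = X_obs[:, keep], X_mis[:, keep]
                y_obs = frame.loc[obs, var].to_numpy(float)
                label = f"imp {m_idx + 1}, cycle {it + 1}, {var}"
                if var in _CONTINUOUS_VARS:
                    drawn = _draw_continuous_pmm(
                        X_obs, y_obs, X_mis, rng, config.pmm_donors, config.ridge, events, label
                    )
                else:
                    drawn = _draw_binary(X_obs, y_obs, X_mis, rng, config.ridge, events, label)
                frame.loc[frame.index[mis.to_numpy()], var] = drawn
                traces[var][m_idx, it] = float(np.mean(drawn)) if len(drawn) else np.nan
        _apply_structural_rules(frame, mask)
        completed = LinkedCohort(frame, cohort.exclusions)
        completed.mask = mask.copy()  # provenance: which cells were imputed
        datasets.append(completed)

    return ImputationSet(datasets=datasets, config=config, traces=traces, events=events)
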