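"""One-sample MR on individual-level data.

Weighted genetic risk scores, rank-based inverse-normal transforms, and
covariate-adjusted two-stage IV regression (univariable and two-score
multivariable) for continuous and binary outcomes.

Stage-2 standard errors are model-based (not 2SLS-corrected); a seeded
bootstrap SE option exists because uncorrected two-stage SEs are
anti-conservative for logistic outcomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import CohortData, DataError, PreconditionError

logger = logging.getLogger(__name__)


class CollinearityWarning(UserWarning):
    pass


@dataclass
class GRSVector:
    """Per-individual weighted genetic risk score."""

    scores: np.ndarray
    variant_ids: list[str]
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class IVRegressionResult:
    estimate: float
    se: float
    p: float
    model: str               # "univariable" | "multivariable"
    outcome_type: str        # "continuous" | "binary"
    n: int
    first_stage_f: float
    defined: bool = True     # False for degenerate (zero-variance) scores


def build_grs(cohort: CohortData, subset: list[tuple[str, float]]) -> GRSVector:
    """Exact weighted dosage sum per individual.

    Weights are the exposure betas of the subset, aligned to the
    exposure effect alleles.
    """
    ids = [v for v, _ in subset]
    missing = [v for v in ids if v not in cohort.dosages.columns]
    if missing:
        raise DataError(f"build_grs: variants absent from cohort: {missing[:5]}")
    weights = np.array([w for _, w in subset], dtype=float)
    dosage = cohort.dosages[ids].to_numpy(dtype=float)
    return GRSVector(scores=dosage @ weights, variant_ids=ids, weights=weights)


def rank_int(y: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset:
    ``Phi^-1((r_i - 3/8) / (n + 1/4))`` using average ranks for ties."""
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise PreconditionError("rank_int: need a 1-d vector with n >= 2")
    if np.ptp(arr) == 0:
        raise DataError("rank_int: constant vector")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(arr) + 0.25))


def _design(cohort: CohortData, covariates: list[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in cohort.covariates.columns]
    if missing:
        raise PreconditionError(f"missing covariate(s): {missing}")
    return cohort.covariates[covariates].to_numpy(dtype=float)


def _first_stage(exposure: np.ndarray, score: np.ndarray,
                 covs: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of exposure on score + covariates; returns fitted values and
    the partial F-statistic for the score."""
    X = sm.add_constant(np.column_stack([score, covs])) if covs.size \
        else sm.add_constant(score.reshape(-1, 1))
    fit = sm.OLS(exposure, X).fit()
    f_stat = float(fit.tvalues[1] ** 2)
    return np.asarray(fit.fittedvalues), f_stat


def _stage2(outcome: np.ndarray, fitted: np.ndarray, covs: np.ndarray,
            binary: bool) -> tuple[np.ndarray, np.ndarray]:
    """Second-stage fit; returns (params, bse) for the fitted-exposure
    column(s), which come first in the design."""
    fitted = np.atleast_2d(fitted.T).T
    X = sm.add_constant(np.column_stack([fitted, covs])) if covs.size \
        else sm.add_constant(fitted)
    if binary:
        try:
            fit = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation and kin
            raise DataError(f"logistic stage failed to converge: {exc}") from exc
        if not fit.mle_retvals.get("converged", True):
            raise DataError("logistic stage failed to converge")
    else:
        fit = sm.OLS(outcome, X).fit()
    k = fitted.shape[1]
    return np.asarray(fit.params[1:1 + k]), np.asarray(fit.bse[1:1 + k])


def _is_binary(y: np.ndarray) -> bool:
    vals = set(np.unique(y[~np.isnan(y)]).tolist())
    return vals <= {0.0, 1.0}


def iv_regression(
    cohort: CohortData,
    grs: GRSVector,
    exposure_name: str,
    outcome_name: str,
    covariates: list[str] | None = None,
    standardize_exposure: bool = True,
) -> IVRegressionResult:
    """Univariable two-stage IV regression.

    Stage 1 regresses the (optionally SD-standardized) exposure on the
    GRS plus covariates; stage 2 regresses the outcome on the stage-1
    fitted values plus covariates (linear for continuous outcomes,
    logistic for binary).  The estimate is the stage-2 coefficient on
    the fitted exposure, per SD of exposure when standardized.
    """
    covariates = covariates or []
    x = cohort.phenotypes[exposure_name].to_numpy(dtype=float)
    y = cohort.phenotypes[outcome_name].to_numpy(dtype=float)
    covs = _design(cohort, covariates)
    if standardize_exposure:
        x = (x - x.mean()) / x.std(ddof=0)
    binary = _is_binary(y)
    if binary and min((y == 1).sum(), (y == 0).sum()) < 10:
        logger.warning("iv_regression: <10 cases or controls; low power")

    fitted, f_stat = _first_stage(x, grs.scores, covs)
    params, bses = _stage2(y, fitted, covs, binary)
    est, se = float(params[0]), float(bses[0])
    p = 2 * stats.norm.sf(abs(est / se))
    return IVRegressionResult(
        estimate=est, se=se, p=float(p), model="univariable",
        outcome_type="binary" if binary else "continuous",
        n=len(y), first_stage_f=f_stat,
    )


def mvmr_two_scores(
    cohort: CohortData,
    grs_a: GRSVector,
    grs_b: GRSVector,
    exposure_name: str,
    outcome_name: str,
    covariates: list[str] | None = None,
    standardize_exposure: bool = True,
    collinearity_limit: float = 0.95,
) -> tuple[IVRegressionResult, IVRegressionResult]:
    """Two-score multivariable IV regression.

    Stage 1 is run separately per score (exposure ~ GRS_k + covariates);
    stage 2 regresses the outcome on both fitted exposures plus
    covariates jointly.  Each coefficient is the subset's direct effect
    per SD exposure.  Collinearity between the covariate-residualized
    fitted exposures above ``collinearity_limit`` raises a warning with
    the stage-2 condition number.
    """
    covariates = covariates or []
    x = cohort.phenotypes[exposure_name].to_numpy(dtype=float)
    y = cohort.phenotypes[outcome_name].to_numpy(dtype=float)
    covs = _design(cohort, covariates)
    if standardize_exposure:
        x = (x - x.mean()) / x.std(ddof=0)
    binary = _is_binary(y)

    degenerate = [np.ptp(g.scores) == 0 for g in (grs_a, grs_b)]
    if all(degenerate):
        raise DataError("mvmr_two_scores: both scores are constant")
    if any(degenerate):
        # one score carries no variation: fall back to univariable on the
        # informative score and flag the other as undefined
        live_idx = degenerate.index(False)
        live = (grs_a, grs_b)[live_idx]
        uni = iv_regression(cohort, live, exposure_name, outcome_name,
                            covariates, standardize_exposure)
        uni.model = "multivariable"
        dead = IVRegressionResult(
            estimate=float("nan"), se=float("nan"), p=float("nan"),
            model="multivariable", outcome_type=uni.outcome_type,
            n=len(y), first_stage_f=float("nan"), defined=False,
        )
        logger.warning("mvmr_two_scores: score %s has zero variance; "
                       "its coefficient is undefined", "AB"[1 - live_idx])
        return (uni, dead) if live_idx == 0 else (dead, uni)

    fitted_a, f_a = _first_stage(x, grs_a.scores, covs)
    fitted_b, f_b = _first_stage(x, grs_b.scores, covs)

    resid_a = _residualize(fitted_a, covs)
    resid_b = _residualize(fitted_b, covs)
    denom = resid_a.std() * resid_b.std()
    corr = float(np.mean(resid_a * resid_b) / denom) if denom > 0 else 1.0
    if abs(corr) > collinearity_limit:
        X2 = np.column_stack([fitted_a, fitted_b])
        cond = float(np.linalg.cond(X2 - X2.mean(axis=0)))
        warnings.warn(
            f"fitted exposures nearly collinear (|corr|={abs(corr):.3f}, "
            f"condition number {cond:.3g})", CollinearityWarning,
        )

    params, bses = _stage2(y, np.column_stack([fitted_a, fitted_b]), covs, binary)
    out = []
    for k, f_stat in zip(range(2), (f_a, f_b)):
        est, se = float(params[k]), float(bses[k])
        out.append(IVRegressionResult(
            estimate=est, se=se, p=float(2 * stats.norm.sf(abs(est / se))),
            model="multivariable",
            outcome_type="binary" if binary else "continuous",
            n=len(y), first_stage_f=f_stat,
        ))
    return out[0], out[1]


def _residualize(v: np.ndarray, covs: np.ndarray) -> np.ndarray:
    X = sm.add_constant(covs) if covs.size else np.ones((len(v), 1))
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta
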