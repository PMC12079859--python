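"""Summary-level MR estimators and diagnostics.

Implements the Wald ratio, fixed/multiplicative-random-effects IVW,
MR-Egger, weighted median, weighted mode, Cochran's Q heterogeneity
statistics (including the average heterogeneity Q / (Q_df - 1)),
Steiger directionality, and the PP_H4-weighted multivariable model for
tissue-partitioned exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DataError, PreconditionError
from .instruments import HarmonizedPair

logger = logging.getLogger(__name__)

_METHOD_MIN_SNPS = {
    "wald": 1, "ivw": 2, "egger_slope": 3, "egger_intercept": 3,
    "weighted_median": 3, "weighted_mode": 3, "mvmr": 2,
}


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snp: int

    def __post_init__(self) -> None:
        if self.method not in _METHOD_MIN_SNPS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


@dataclass
class HeterogeneityStats:
    Q: float
    Q_df: int
    Q_p: float
    I2: float
    Q_het: float | None     # Q / (Q_df - 1); undefined when Q_df <= 1
    mean_F: float
    total_R2: float | None  # requires eaf


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    steiger_p: float
    tie: bool = False


def _arrays(pairs: list[HarmonizedPair]):
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    return bx, by, sx, sy


def _zp(beta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(beta / se)))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate by/bx with first-order delta SE."""
    if pair.beta_exp == 0:
        raise ZeroDivisionError("wald_ratio: exposure beta is zero")
    beta = pair.beta_out / pair.beta_exp
    se = abs(pair.se_out / pair.beta_exp)
    return MREstimate("wald", beta, se, _zp(beta, se), 1)


def ivw(pairs: list[HarmonizedPair], model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of the
    outcome betas on the exposure betas through the origin, weights
    1/se_out².  The multiplicative random-effects model inflates the SE
    by max(1, sqrt(Q/Q_df))."""
    if model not in ("fixed", "random"):
        raise ValueError(f"ivw: unknown model {model!r}")
    if len(pairs) < 1 or (len(pairs) < 2 and model == "random"):
        raise PreconditionError("ivw: need >= 2 instruments")
    bx, by, _, sy = _arrays(pairs)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    if model == "random" and len(pairs) > 1:
        q = float(np.sum(w * (by - beta * bx) ** 2))
        scale = max(1.0, np.sqrt(q / (len(pairs) - 1)))
        se *= scale
    return MREstimate("ivw", beta, se, _zp(beta, se), len(pairs))


def mr_egger(pairs: list[HarmonizedPair]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of by on bx with an intercept,
    weights 1/se_out², after forcing exposure betas positive.  Returns
    (slope, intercept); the intercept measures average directional
    pleiotropy.  SEs are multiplicative random-effects (scaled by
    max(1, sqrt(sigma²)))."""
    if len(pairs) < 3:
        raise PreconditionError("mr_egger: need >= 3 instruments")
    bx, by, _, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    params = xtx_inv @ (WX.T @ by)
    resid = by - X @ params
    dof = len(pairs) - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(xtx_inv) * scale)
    slope = MREstimate("egger_slope", float(params[1]), float(ses[1]),
                       float(2 * stats.t.sf(abs(params[1] / ses[1]), dof)),
                       len(pairs))
    intercept = MREstimate("egger_intercept", float(params[0]), float(ses[0]),
                           float(2 * stats.t.sf(abs(params[0] / ses[0]), dof)),
                           len(pairs))
    return slope, intercept


def _ratio_weights(pairs: list[HarmonizedPair]):
    bx, by, _, sy = _arrays(pairs)
    ratios = by / bx
    # inverse variance of the per-SNP ratio (first-order delta)
    weights = bx**2 / sy**2
    return ratios, weights


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = int(np.max(np.nonzero(cum < 0.5)[0])) if (cum < 0.5).any() else -1
    if below == -1:
        return float(r[0])
    if below == len(r) - 1:
        return float(r[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(
    pairs: list[HarmonizedPair], n_boot: int = 1000, seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator with linear interpolation of the
    cumulative standardized weights to the 0.5 crossing; SE by seeded
    parametric bootstrap."""
    if len(pairs) < 3:
        raise PreconditionError("weighted_median: need >= 3 instruments")
    ratios, weights = _ratio_weights(pairs)
    est = _weighted_median(ratios, weights)
    se = _bootstrap_se(pairs, _weighted_median, n_boot, seed)
    return MREstimate("weighted_median", est, se, _zp(est, se), len(pairs))


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    h = factor * 0.9 * mad * len(ratios) ** (-0.2)
    if h <= 0:
        h = max(1e-8, 1e-3 * (np.ptp(ratios) or 1.0))
    return h


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float = 1.0) -> float:
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    h = _mode_bandwidth(ratios, bandwidth_factor)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    pairs: list[HarmonizedPair], bandwidth_factor: float = 1.0,
    n_boot: int = 1000, seed: int | None = None,
) -> MREstimate:
    """Mode of the inverse-variance-weighted Gaussian kernel density over
    per-SNP Wald ratios; SE by seeded parametric bootstrap."""
    if len(pairs) < 3:
        raise PreconditionError("weighted_mode: need >= 3 instruments")
    ratios, weights = _ratio_weights(pairs)
    est = _weighted_mode(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        pairs, lambda r, w: _weighted_mode(r, w, bandwidth_factor), n_boot, seed,
    )
    return MREstimate("weighted_mode", est, se, _zp(est, se), len(pairs))


def _bootstrap_se(pairs, estimator, n_boot, seed) -> float:
    """Parametric bootstrap: redraw each by ~ N(by, se_out), bx ~ N(bx, se_exp)."""
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = _arrays(pairs)
    weights = bx**2 / sy**2
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        bxb[bxb == 0] = 1e-12
        ests[b] = estimator(byb / bxb, weights)
    return float(np.std(ests, ddof=1))


def heterogeneity(pairs: list[HarmonizedPair], est: MREstimate) -> HeterogeneityStats:
    """Cochran's Q about the IVW estimate with per-ratio inverse-variance
    weights, I² floored at 0, the printed average heterogeneity
    Q/(Q_df - 1), per-SNP F statistics and total instrument R²."""
    if len(pairs) < 2:
        raise PreconditionError("heterogeneity: need >= 2 instruments")
    bx, by, sx, sy = _arrays(pairs)
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - est.beta) ** 2))
    q_df = len(pairs) - 1
    q_p = float(stats.chi2.sf(q, q_df))
    i2 = max(0.0, (q - q_df) / q) if q > 0 else 0.0
    q_het = q / (q_df - 1) if q_df > 1 else None
    f_per_snp = (bx / sx) ** 2
    eafs = [p.eaf_exp for p in pairs]
    total_r2 = None
    if all(e is not None for e in eafs):
        e = np.array(eafs, dtype=float)
        total_r2 = float(np.sum(2 * e * (1 - e) * bx**2))
    return HeterogeneityStats(
        Q=q, Q_df=q_df, Q_p=q_p, I2=float(i2), Q_het=q_het,
        mean_F=float(np.mean(f_per_snp)), total_R2=total_r2,
    )


def steiger(pairs: list[HarmonizedPair], n_exp: int, n_out: int) -> SteigerResult:
    """Directionality test comparing summed per-SNP variance explained in
    exposure versus outcome, r² = z²/(z² + n - 2), with a Fisher-z test
    on the implied correlations."""
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise PreconditionError("steiger: per-trait sample sizes required (> 3)")
    bx, by, sx, sy = _arrays(pairs)
    zx, zy = bx / sx, by / sy
    r2_exp = float(np.sum(zx**2 / (zx**2 + n_exp - 2)))
    r2_out = float(np.sum(zy**2 / (zy**2 + n_out - 2)))
    r2_exp = min(r2_exp, 1.0)
    r2_out = min(r2_out, 1.0)
    r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (np.arctanh(min(r_exp, 0.999999)) - np.arctanh(min(r_out, 0.999999))) / denom
    p = float(2 * stats.norm.sf(abs(z)))
    tie = bool(np.isclose(r2_exp, r2_out))
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out,
        direction_correct=bool(r2_exp > r2_out) or tie,
        steiger_p=p, tie=tie,
    )


def mvmr_pp4_weighted(
    pairs: list[HarmonizedPair],
    pp4: dict[str, tuple[float, float]],
    exclude_below: float | None = 0.9,
) -> tuple[MREstimate, MREstimate]:
    """PP_H4-weighted multivariable MR for two tissue-partitioned
    exposures.

    Builds two exposure columns bx·pp4_A and bx·pp4_B and fits a
    weighted (1/se_out²) regression of by on both without intercept.
    Instruments below ``exclude_below`` in both tissues are dropped
    (pass ``None`` to keep all).  Conditional F-statistics are attached
    as ``cond_f`` on each estimate."""
    for p in pairs:
        if p.variant_id not in pp4:
            raise PreconditionError(f"mvmr_pp4_weighted: no PP_H4 for {p.variant_id}")
        a, b = pp4[p.variant_id]
        if not (0 <= a <= 1 and 0 <= b <= 1):
            raise PreconditionError("mvmr_pp4_weighted: PP_H4 outside [0,1]")
    use = pairs
    if exclude_below is not None:
        use = [p for p in pairs
               if max(pp4[p.variant_id]) > exclude_below]
    if len(use) < 2:
        raise PreconditionError("mvmr_pp4_weighted: fewer than 2 usable instruments")
    bx, by, sx, sy = _arrays(use)
    wa = np.array([pp4[p.variant_id][0] for p in use])
    wb = np.array([pp4[p.variant_id][1] for p in use])
    bxa, bxb = bx * wa, bx * wb
    # a tissue whose weighted exposure column is identically zero drops out:
    # the other coefficient reduces to univariable IVW on its scaled column
    zero_cols = [not np.any(bxa), not np.any(bxb)]
    if all(zero_cols):
        raise DataError("mvmr_pp4_weighted: both exposure columns are zero")
    if any(zero_cols):
        live = 1 if zero_cols[0] else 0
        col = (bxa, bxb)[live]
        w = 1.0 / sy**2
        denom = float(np.sum(w * col**2))
        beta = float(np.sum(w * col * by)) / denom
        resid = by - beta * col
        sigma2 = float(np.sum(w * resid**2) / max(len(use) - 1, 1))
        se = float(np.sqrt(max(1.0, sigma2) / denom))
        live_est = MREstimate("mvmr", beta, se, _zp(beta, se), len(use))
        live_est.cond_f = float(np.sum((col / sy) ** 2) / len(use))
        dead = MREstimate("mvmr", float("nan"), 1.0, 1.0, len(use))
        dead.se = float("nan")
        dead.p = float("nan")
        dead.cond_f = float("nan")
        logger.warning("mvmr_pp4_weighted: tissue %s column is zero; "
                       "its coefficient is undefined", "AB"[1 - live])
        return (live_est, dead) if live == 0 else (dead, live_est)
    X = np.column_stack([bxa, bxb])
    w = 1.0 / sy**2
    xtwx = X.T @ (X * w[:, None])
    if np.linalg.cond(xtwx) > 1e10:
        raise DataError("mvmr_pp4_weighted: exposure columns are collinear "
                        "(pp4_A proportional to pp4_B)")
    params = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ params
    dof = max(len(use) - 2, 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov))

    cond_f = _conditional_f(bxa, bxb, sx * np.maximum(wa, 1e-6),
                            sx * np.maximum(wb, 1e-6))
    out = []
    for k in range(2):
        est = MREstimate("mvmr", float(params[k]), float(ses[k]),
                         _zp(float(params[k]), float(ses[k])), len(use))
        est.cond_f = cond_f[k]
        out.append(est)
    return out[0], out[1]


def _conditional_f(bxa, bxb, sa, sb) -> tuple[float, float]:
    """Instrument-strength F for each exposure conditional on the other
    (residual chi-square per instrument after projecting out the other
    exposure column)."""
    out = []
    for target, other, se in ((bxa, bxb, sa), (bxb, bxa, sb)):
        denom = float(other @ other)
        resid = target - (other * (float(target @ other) / denom) if denom > 0
                          else 0.0)
        k = len(target)
        out.append(float(np.sum((resid / se) ** 2) / k))
    return out[0], out[1]
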