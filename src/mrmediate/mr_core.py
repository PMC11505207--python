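"""Causal-effect estimators and the analytic sensitivity suite.

For a harmonized exposure-outcome pair with per-SNP effects
(beta_x_j, se_x_j) and (beta_y_j, se_y_j):

* the Wald ratio beta_y/beta_x is the single-SNP causal estimate;
* the inverse-variance-weighted (IVW) estimate is the zero-intercept
  weighted regression of outcome on exposure effects with weights
  1/se_y^2, equivalent to a fixed-effect meta-analysis of Wald ratios
  under first-order weights.  A multiplicative random-effects scale
  s^2 = Q/(J-1), floored at 1, inflates the SE under heterogeneity while
  never undercutting the fixed-effect SE;
* Cochran's Q measures heterogeneity of the per-SNP estimates
  (chi-square with J-1 df under homogeneity);
* MR-Egger re-fits the weighted regression with an intercept; a nonzero
  intercept indicates directional horizontal pleiotropy;
* leave-one-out re-estimates IVW dropping each SNP in turn to expose
  single-variant leverage.

p-values for slopes and intercepts are two-sided normal throughout,
the usual summary-level MR convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_io import Z_95, HarmonizedSet

_TINY_P = 5e-324  # keep p in (0, 1]


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


@dataclass
class MREstimate:
    """A causal effect estimate with normal-theory uncertainty."""

    method: str  # wald_ratio | ivw | egger_slope
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity test."""

    Q: float
    df: int
    pval: float


@dataclass
class EggerResult:
    """MR-Egger regression: slope estimate plus the intercept pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class LeaveOneOutRow:
    dropped_snp: str
    estimate: MREstimate


@dataclass
class LeaveOneOutResult:
    rows: list[LeaveOneOutRow]
    #: True when dropping any single SNP flips the sign of the estimate or
    #: moves its p-value across 0.05 relative to the full-set fit.
    influential: bool
    full: MREstimate


def _normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def _make_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    z = beta / se if se > 0 else math.inf * np.sign(beta)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pval=_normal_p(z) if se > 0 else _TINY_P,
        n_snp=n_snp,
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate beta_y/beta_x with first-order SE se_y/|beta_x|."""
    if beta_x == 0:
        raise ValueError("Wald ratio undefined for a null exposure effect (beta_x = 0)")
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be positive")
    return _make_estimate("wald_ratio", beta_y / beta_x, se_y / abs(beta_x), 1)


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effect
    se0 = 1/sqrt(sum(bx^2/sy^2)); the final SE is se0 * max(1, sqrt(Q/(J-1)))
    so heterogeneity inflates but never deflates the uncertainty.
    """
    bx, _, by, sy = h.arrays()
    n = len(bx)
    if n < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {n} for {h.exposure_id}->{h.outcome_id}"
        )
    w = 1.0 / sy**2
    sxx = float(np.sum(bx * bx * w))
    sxy = float(np.sum(bx * by * w))
    beta = sxy / sxx
    se0 = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, math.sqrt(q / (n - 1)))
    return _make_estimate("ivw", beta, se0 * scale, n)


def estimate_effect(h: HarmonizedSet) -> MREstimate:
    """IVW for >= 2 instruments; the Wald ratio for a single instrument."""
    if h.n_snp == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if h.n_snp == 1:
        bx, sx, by, sy = (float(a[0]) for a in h.arrays())
        return wald_ratio(bx, sx, by, sy)
    return ivw(h)


def cochran_q(h: HarmonizedSet, beta_hat: float) -> HeterogeneityStats:
    """Cochran's Q = sum((by - beta_hat*bx)^2 / sy^2), chi-square with J-1 df."""
    bx, _, by, sy = h.arrays()
    n = len(bx)
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    q = float(np.sum((by - beta_hat * bx) ** 2 / sy**2))
    df = n - 1
    return HeterogeneityStats(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    Rows are first oriented so every exposure effect is non-negative
    (joint sign flip of bx and by), then beta_y is regressed on beta_x with
    an intercept and weights 1/se_y^2.  Slope and intercept SEs carry the
    same multiplicative scale as IVW, floored at 1.  The intercept p-value
    is the directional-pleiotropy test.
    """
    bx, _, by, sy = h.arrays()
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 instruments, got {n} for {h.exposure_id}->{h.outcome_id}"
        )
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    base_se = np.sqrt(np.diag(fit.normalized_cov_params))  # unscaled (X'WX)^-1
    scale = max(1.0, math.sqrt(fit.scale))
    intercept, slope = fit.params
    intercept_se, slope_se = base_se * scale
    return EggerResult(
        slope=_make_estimate("egger_slope", slope, slope_se, n),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        intercept_pval=_normal_p(intercept / intercept_se),
    )


def leave_one_out(h: HarmonizedSet) -> LeaveOneOutResult:
    """IVW re-estimated with each SNP dropped in turn."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(h)
    rows: list[LeaveOneOutRow] = []
    influential = False
    for snp in h.df["SNP"]:
        est = ivw(h.drop_snps([snp]))
        rows.append(LeaveOneOutRow(dropped_snp=snp, estimate=est))
        sign_change = np.sign(est.beta) != np.sign(full.beta)
        crosses_alpha = (est.pval < 0.05) != (full.pval < 0.05)
        influential = influential or bool(sign_change or crosses_alpha)
    return LeaveOneOutResult(rows=rows, influential=influential, full=full)


def mr_table(entries: list[tuple[str, str, MREstimate]]) -> pd.DataFrame:
    """Forest-plot-ready table, one row per (exposure, outcome, method)."""
    recs = [
        {
            "exposure": exp,
            "outcome": out,
            "method": e.method,
            "nsnp": e.n_snp,
            "b": e.beta,
            "se": e.se,
            "lo_ci": e.ci_low,
            "up_ci": e.ci_high,
            "pval": e.pval,
            "or": e.or_value,
            "or_lci95": e.or_low,
            "or_uci95": e.or_high,
        }
        for exp, out, e in entries
    ]
    return pd.DataFrame.from_records(
        recs,
        columns=[
            "exposure", "outcome", "method", "nsnp", "b", "se",
            "lo_ci", "up_ci", "pval", "or", "or_lci95", "or_uci95",
        ],
    )
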