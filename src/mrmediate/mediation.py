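"""Two-step mediation analysis for Mendelian randomization estimates.

For an exposure -> mediator -> outcome triple with three independent MR
fits — total effect b of exposure on outcome, b1 of exposure on mediator,
b2 of mediator on outcome — the product-of-coefficients decomposition is

    indirect = b1 * b2            (effect transmitted through the mediator)
    direct   = b  - b1 * b2
    P        = indirect / b       (mediated proportion)

Standard errors are first-order delta-method (Sobel-type), treating the
three estimates as independent, which is appropriate when the three GWAS
samples do not overlap:

    se(indirect)^2 = b1^2 se2^2 + b2^2 se1^2
    var(P) = (b2/b)^2 se1^2 + (b1/b)^2 se2^2 + (P/b)^2 se_b^2

The delta-method CI for P is symmetric and only approximate: ratio
statistics are skewed, so coverage is near but not exactly nominal.
A triple whose indirect effect opposes the sign of the total effect is
flagged as inconsistent mediation (the mediated proportion is then not
interpretable as a fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .mr_core import MREstimate
from .summary_io import Z_95

_TINY_P = 5e-324


class AssemblyError(ValueError):
    """A mediation triple is missing one of its three component estimates."""


@dataclass
class MediationResult:
    """Decomposition of a total causal effect into mediated and direct parts."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta_step1: float
    se_step1: float
    beta_step2: float
    se_step2: float
    indirect: float
    indirect_se: float
    direct: float
    direct_se: float
    proportion: float
    proportion_se: float
    proportion_ci_low: float
    proportion_ci_high: float
    proportion_pval: float
    inconsistent: bool

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def proportion_ci_pct(self) -> tuple[float, float]:
        return 100.0 * self.proportion_ci_low, 100.0 * self.proportion_ci_high


def indirect_effect(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Product of coefficients b1*b2 with first-order (Sobel) SE."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    value = b1 * b2
    se = math.sqrt(b1**2 * se2**2 + b2**2 * se1**2)
    return value, se


def mediated_proportion(
    b_total: float,
    se_total: float,
    b1: float,
    se1: float,
    b2: float,
    se2: float,
) -> tuple[float, float, tuple[float, float], float]:
    """Mediated proportion P = b1*b2/b_total with delta-method uncertainty.

    Returns ``(P, se, (ci_low, ci_high), pval)`` on the fraction scale.
    """
    if b_total == 0:
        raise ValueError("mediated proportion undefined for a zero total effect")
    if min(se_total, se1, se2) <= 0:
        raise ValueError("standard errors must be positive")
    p = (b1 * b2) / b_total
    var = (
        (b2 / b_total) ** 2 * se1**2
        + (b1 / b_total) ** 2 * se2**2
        + (p / b_total) ** 2 * se_total**2
    )
    se = math.sqrt(var)
    ci = (p - Z_95 * se, p + Z_95 * se)
    pval = max(2.0 * stats.norm.sf(abs(p) / se), _TINY_P) if se > 0 else _TINY_P
    return p, se, ci, pval


def two_step_mediation(
    total: MREstimate,
    step1: MREstimate,
    step2: MREstimate,
    exposure_id: str,
    mediator_id: str,
    outcome_id: str,
) -> MediationResult:
    """Assemble the three pairwise MR fits into one mediation decomposition."""
    for name, est in (("total", total), ("step1", step1), ("step2", step2)):
        if est is None:
            raise AssemblyError(
                f"mediation triple {exposure_id}->{mediator_id}->{outcome_id}: "
                f"missing the {name} estimate"
            )

    ind, ind_se = indirect_effect(step1.beta, step1.se, step2.beta, step2.se)
    direct = total.beta - ind
    direct_se = math.sqrt(total.se**2 + ind_se**2)
    p, p_se, (p_lo, p_hi), p_pval = mediated_proportion(
        total.beta, total.se, step1.beta, step1.se, step2.beta, step2.se
    )
    inconsistent = ind != 0 and (ind > 0) != (total.beta > 0)
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_total=total.beta,
        se_total=total.se,
        beta_step1=step1.beta,
        se_step1=step1.se,
        beta_step2=step2.beta,
        se_step2=step2.se,
        indirect=ind,
        indirect_se=ind_se,
        direct=direct,
        direct_se=direct_se,
        proportion=p,
        proportion_se=p_se,
        proportion_ci_low=p_lo,
        proportion_ci_high=p_hi,
        proportion_pval=p_pval,
        inconsistent=inconsistent,
    )


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Tab-separated-ready mediation summary, one row per triple."""
    recs = [
        {
            "exposure": r.exposure_id,
            "mediator": r.mediator_id,
            "outcome": r.outcome_id,
            "b_total": r.beta_total,
            "b1": r.beta_step1,
            "b2": r.beta_step2,
            "indirect": r.indirect,
            "direct": r.direct,
            "prop_pct": r.proportion_pct,
            "prop_lci_pct": 100.0 * r.proportion_ci_low,
            "prop_uci_pct": 100.0 * r.proportion_ci_high,
            "prop_pval": r.proportion_pval,
            "inconsistent": r.inconsistent,
        }
        for r in results
    ]
    return pd.DataFrame.from_records(
        recs,
        columns=[
            "exposure", "mediator", "outcome", "b_total", "b1", "b2",
            "indirect", "direct", "prop_pct", "prop_lci_pct", "prop_uci_pct",
            "prop_pval", "inconsistent",
        ],
    )
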