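"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based check that per-SNP outcome effects are consistent with a
single causal slope.  Three components:

* **global test** — the observed leave-one-out residual sum of squares
  RSS = sum_j (by_j - bhat(-j)*bx_j)^2 / sy_j^2 is compared against its
  parametric-bootstrap distribution under the no-pleiotropy null, where
  pseudo effects are drawn per SNP as by* ~ N(bhat(-j)*bx_j, sy_j) and
  bx* ~ N(bx_j, sx_j);
* **outlier test** — each SNP's observed squared residual is compared to
  its own simulated distribution; per-SNP Monte-Carlo p-values are
  Bonferroni-adjusted across SNPs and flagged at 0.05;
* **distortion test** — the relative change in the IVW estimate after
  removing the flagged outliers is compared to the change from removing
  random SNP sets of the same size.

All Monte-Carlo p-values use the add-one rule (never exactly zero) and the
whole module is reproducible bit-for-bit from (data, n_sim, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mr_core import InsufficientInstrumentsError, MREstimate, ivw
from .summary_io import HarmonizedSet

MIN_SNPS = 4


@dataclass
class PressoSimState:
    """Simulated residual distributions retained for the outlier test."""

    snp_ids: list[str]
    resid2_obs: np.ndarray  # (J,) observed weighted squared residuals
    resid2_sim: np.ndarray  # (n_sim, J)
    rss_sim: np.ndarray  # (n_sim,)


@dataclass
class PressoResult:
    """Full MR-PRESSO output for one harmonized pair."""

    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int
    outlier_pvals: pd.Series | None = None  # Bonferroni-adjusted, indexed by SNP
    outliers: list[str] = field(default_factory=list)
    distortion_coef: float | None = None
    distortion_pval: float | None = None
    corrected: MREstimate | None = None
    sim_state: PressoSimState | None = None


def _loo_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn, via sum subtraction."""
    w = 1.0 / sy**2
    xy = bx * by * w
    xx = bx * bx * w
    return (xy.sum() - xy) / (xx.sum() - xx)


def _loo_betas_sim(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out IVW slopes for (n_sim, J) pseudo-data."""
    w = 1.0 / sy**2
    xy = bx * by * w
    xx = bx * bx * w
    return (xy.sum(axis=1, keepdims=True) - xy) / (xx.sum(axis=1, keepdims=True) - xx)


def presso_global(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Global heterogeneity test; retains per-SNP simulations for the outlier test."""
    bx, sx, by, sy = h.arrays()
    n = len(bx)
    if n < MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= {MIN_SNPS} instruments, got {n}"
        )
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")

    loo = _loo_betas(bx, by, sy)
    resid2_obs = (by - loo * bx) ** 2 / sy**2
    rss_obs = float(resid2_obs.sum())

    rng = np.random.default_rng(seed)
    by_star = rng.normal(loo * bx, sy, size=(n_sim, n))
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    loo_star = _loo_betas_sim(bx_star, by_star, sy)
    resid2_sim = (by_star - loo_star * bx_star) ** 2 / sy**2
    rss_sim = resid2_sim.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        n_sim=n_sim,
        seed=seed,
        sim_state=PressoSimState(
            snp_ids=list(h.df["SNP"]),
            resid2_obs=resid2_obs,
            resid2_sim=resid2_sim,
            rss_sim=rss_sim,
        ),
    )


def presso_outliers(
    h: HarmonizedSet, result: PressoResult, alpha: float = 0.05
) -> PressoResult:
    """Per-SNP outlier test on the simulations stored by :func:`presso_global`."""
    state = result.sim_state
    if state is None:
        raise RuntimeError("presso_outliers requires a PressoResult from presso_global")
    n = len(state.snp_ids)
    exceed = (state.resid2_sim >= state.resid2_obs[None, :]).sum(axis=0)
    raw_p = (1.0 + exceed) / (result.n_sim + 1.0)
    adj_p = np.minimum(1.0, raw_p * n)  # Bonferroni across SNPs
    result.outlier_pvals = pd.Series(adj_p, index=state.snp_ids, name="presso_outlier_p")
    result.outliers = [s for s, p in zip(state.snp_ids, adj_p) if p < alpha]
    return result


def presso_distortion(
    h: HarmonizedSet,
    result: PressoResult,
    n_sim: int | None = None,
) -> PressoResult:
    """Distortion test for the flagged outliers; no-op marker when none flagged."""
    if result.outlier_pvals is None:
        raise RuntimeError("presso_distortion requires presso_outliers to have run")
    if not result.outliers:
        return result  # nothing flagged: distortion not applicable
    n_sim = n_sim or result.n_sim
    h_clean = h.drop_snps(result.outliers)
    if h_clean.n_snp < 2:
        raise InsufficientInstrumentsError(
            "fewer than 2 instruments remain after outlier removal"
        )
    beta_all = ivw(h).beta
    corrected = ivw(h_clean)
    d_obs = (beta_all - corrected.beta) / abs(corrected.beta)

    bx, _, by, sy = h.arrays()
    n = len(bx)
    k = len(result.outliers)
    # seed offset keeps the distortion draws independent of the global draws
    rng = np.random.default_rng((result.seed + 1) % 2**31)
    w = 1.0 / sy**2
    xx = bx * bx * w
    xy = bx * by * w
    sxx, sxy = xx.sum(), xy.sum()
    d_sim = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(n, size=k, replace=False)
        beta_star = (sxy - xy[drop].sum()) / (sxx - xx[drop].sum())
        d_sim[i] = (beta_all - beta_star) / abs(beta_star)
    pval = (1.0 + float(np.sum(np.abs(d_sim) >= abs(d_obs)))) / (n_sim + 1.0)

    result.distortion_coef = float(d_obs)
    result.distortion_pval = pval
    result.corrected = corrected
    return result


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Run the global, outlier and distortion tests in sequence."""
    result = presso_global(h, n_sim=n_sim, seed=seed)
    result = presso_outliers(h, result, alpha=outlier_alpha)
    try:
        result = presso_distortion(h, result)
    except InsufficientInstrumentsError:
        # nearly everything was flagged; corrected fit left unset
        pass
    return result
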