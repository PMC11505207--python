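"""Synthetic two-sample GWAS summary statistics under a known causal model.

Three traits are simulated on an exposure -> mediator -> outcome causal
diagram with effects theta1 (exposure on mediator), theta2 (mediator on
outcome) and theta_direct (exposure on outcome not through the mediator),
so the true total effect is theta_direct + theta1*theta2 and the true
mediated proportion is theta1*theta2 / total.

Each trait carries its own set of J independent instruments; instrument
effects propagate down the diagram (an exposure instrument affects the
mediator through theta1 and the outcome through the total effect), while
effects never flow upstream.  Summary statistics are simulated directly at
the summary level — per-SNP standard errors follow the standard GWAS
approximation se = 1/sqrt(2*MAF*(1-MAF)*n) and observed effects are drawn
Normal(truth, se) independently per panel, mimicking three non-overlapping
cohorts.  p-values are two-sided normal.

Planted nuisance structure, each with a truth record for use as a test
oracle: weak instruments (expected F well below 10), palindromic A/T / G/C
SNPs, allele-swapped and strand-flipped records in the downstream panels,
LD blocks, null background SNPs spanning the selection threshold, and
balanced or directional pleiotropy including gross outliers with a
prescribed Wald-ratio inflation.

Effect alleles are oriented to the trait-increasing allele of the
instrumented trait (a lossless relabeling of strands), and instrument
magnitudes are drawn from the positive half of Normal(0, gamma_sd^2)
truncated to an expected-F window so that every planted instrument is
genuinely discoverable at the selection threshold while none dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instrument_selection import LDTable, _chrom_sort_key
from .summary_io import SummaryStats

#: Ordered non-palindromic allele pairs (effect, other).
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class SimulationParams:
    """Study conditions for one simulated exposure-mediator-outcome triple.

    Defaults describe a desk-scale but realistic molecular-trait setting:
    30 instruments per trait, three non-overlapping GWAS of 100,000
    individuals, and causal effects giving a total exposure->outcome effect
    of 0.3 with a fifth of it mediated.
    """

    J: int = 30
    n_exp: int = 100_000
    n_med: int = 100_000
    n_out: int = 100_000
    theta1: float = 0.25
    theta2: float = 0.25
    theta_direct: float = 0.2375
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.1
    #: Expected per-SNP F window for planted instruments.
    f_expected_range: tuple[float, float] = (100.0, 225.0)
    n_null_snps: int = 200
    frac_palindromic: float = 0.1
    frac_weak: float = 0.1
    n_outliers: int = 0
    outlier_ratio_scale: float = 5.0
    frac_swapped: float = 0.3
    frac_strand_flipped: float = 0.05
    ld_block: tuple[int, float] = (1, 0.0)
    seed: int = 0
    exposure_id: str = "SIM_EXPOSURE"
    mediator_id: str = "SIM_MEDIATOR"
    outcome_id: str = "SIM_OUTCOME"

    def validate(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if min(self.n_exp, self.n_med, self.n_out) < 2:
            raise ValueError("GWAS sample sizes must be positive")
        for name in ("pleio_frac", "frac_palindromic", "frac_weak",
                     "frac_swapped", "frac_strand_flipped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not all(map(math.isfinite, (self.theta1, self.theta2, self.theta_direct))):
            raise ValueError("theta parameters must be finite")
        if self.ld_block[0] < 1 or not 0.0 <= self.ld_block[1] <= 1.0:
            raise ValueError("ld_block must be (block_size >= 1, r2 in [0,1])")

    @property
    def true_total(self) -> float:
        return self.theta_direct + self.theta1 * self.theta2

    @property
    def true_indirect(self) -> float:
        return self.theta1 * self.theta2


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, the oracle for recovery tests."""

    valid_instrument_ids: list[str]
    mediator_instrument_ids: list[str]
    outcome_instrument_ids: list[str]
    planted_weak_ids: list[str]
    planted_palindromic_ids: list[str]
    planted_outlier_ids: list[str]
    theta1: float
    theta2: float
    theta_direct: float
    true_total: float
    true_indirect: float
    true_proportion: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _instrument_magnitudes(rng, se: np.ndarray, gamma_sd: float,
                           f_range: tuple[float, float]) -> np.ndarray:
    """Positive half-normal magnitudes truncated to the expected-F window."""
    lo = se * math.sqrt(f_range[0])
    hi = se * math.sqrt(f_range[1])
    a, b = lo / gamma_sd, hi / gamma_sd
    return stats.truncnorm.rvs(a, b, loc=0.0, scale=gamma_sd,
                               size=len(se), random_state=rng)


def simulate_ld_blocks(snps: pd.DataFrame, block_size: int, r2_within: float) -> LDTable:
    """Group position-sorted SNPs into LD blocks of fixed size per chromosome.

    Within-block pairs receive r^2 = ``r2_within``; cross-block pairs are
    absent from the table (implicitly independent).  ``block_size = 1``
    yields an empty table.
    """
    if not 0.0 <= r2_within <= 1.0:
        raise ValueError("r2_within must lie in [0,1]")
    table = LDTable()
    if block_size <= 1 or r2_within == 0.0:
        return table
    df = snps.copy()
    df["_ck"] = _chrom_sort_key(df["CHR"])
    df = df.sort_values(["_ck", "POS", "SNP"], kind="mergesort")
    for _, chrom_df in df.groupby("_ck", sort=False):
        ids = chrom_df["SNP"].tolist()
        for start in range(0, len(ids), block_size):
            block = ids[start:start + block_size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    table.add(block[i], block[j], r2_within)
    return table


def simulate_triple(
    params: SimulationParams,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, LDTable, TruthRecord]:
    """Simulate exposure, mediator and outcome panels plus LD and truth."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)

    n_weak = math.ceil(p.frac_weak * p.J)
    n_pal = math.ceil(p.frac_palindromic * p.J)
    counts = {
        "exp_inst": p.J,
        "weak": n_weak,
        "med_inst": p.J,
        "out_inst": p.J,
        "pal": n_pal,
        "null": p.n_null_snps,
    }
    total = sum(counts.values())

    ids = np.array([f"rs{100000 + i}" for i in range(total)])
    cat = np.concatenate([np.full(n, name) for name, n in counts.items()])

    # Genomic layout: blocks of ld_block[0] SNPs, members 10 kb apart,
    # blocks 20,000 kb apart and cycled over the 22 autosomes so that
    # distinct blocks are never within the default clumping window.
    block_size = p.ld_block[0]
    block_idx = np.arange(total) // block_size
    within = np.arange(total) % block_size
    chroms = (block_idx % 22 + 1).astype(str)
    pos = 1_000_000 + (block_idx // 22) * 20_000_000 + within * 10_000

    maf = rng.uniform(*p.maf_range, size=total)
    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * p.n_exp)
    se_med = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * p.n_med)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * p.n_out)

    is_exp = cat == "exp_inst"
    is_weak = cat == "weak"
    is_med = cat == "med_inst"
    is_out = cat == "out_inst"
    is_pal = cat == "pal"

    # True per-SNP effects on their instrumented trait.
    gamma = np.zeros(total)  # direct effect on exposure
    delta = np.zeros(total)  # direct effect on mediator
    eta = np.zeros(total)  # direct effect on outcome
    gamma[is_exp] = _instrument_magnitudes(rng, se_exp[is_exp], p.gamma_sd, p.f_expected_range)
    gamma[is_weak] = se_exp[is_weak] * math.sqrt(2.0)  # expected F ~ 2, well under 10
    delta[is_med] = _instrument_magnitudes(rng, se_med[is_med], p.gamma_sd, p.f_expected_range)
    eta[is_out] = _instrument_magnitudes(rng, se_out[is_out], p.gamma_sd, p.f_expected_range)

    # Horizontal pleiotropy on exposure instruments: direct SNP->outcome paths.
    alpha = np.zeros(total)
    exp_idx = np.nonzero(is_exp)[0]
    n_pleio = round(p.pleio_frac * p.J)
    pleio_idx = rng.choice(exp_idx, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    alpha[pleio_idx] = rng.normal(p.pleio_mean, p.pleio_sd, size=n_pleio)
    non_pleio = np.setdiff1d(exp_idx, pleio_idx)
    pool = non_pleio if len(non_pleio) >= p.n_outliers else exp_idx
    outlier_idx = rng.choice(pool, size=p.n_outliers, replace=False) if p.n_outliers else np.array([], int)
    # Outliers get a Wald ratio of outlier_ratio_scale times the true total.
    alpha[outlier_idx] = (p.outlier_ratio_scale - 1.0) * p.true_total * gamma[outlier_idx]

    truth_exp = gamma
    truth_med = p.theta1 * gamma + delta
    truth_out = p.true_total * gamma + p.theta2 * delta + eta + alpha

    # Alleles: uniform over non-palindromic ordered pairs, except planted
    # palindromic SNPs.
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=total)
    ea = np.array([_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx])
    pal_pair_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=int(is_pal.sum()))
    ea[is_pal] = [_PALINDROMIC_PAIRS[i][0] for i in pal_pair_idx]
    oa[is_pal] = [_PALINDROMIC_PAIRS[i][1] for i in pal_pair_idx]

    def _panel(truth, se, n, trait_id, downstream):
        beta = rng.normal(truth, se)
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 5e-324, 1.0)
        df = pd.DataFrame({
            "SNP": ids, "CHR": chroms, "POS": pos,
            "EA": ea.copy(), "OA": oa.copy(), "EAF": maf.copy(),
            "BETA": beta, "SE": se, "P": pval,
            "N": float(n),
        })
        if downstream:
            # Exercise harmonization: swap effect/other allele coding on a
            # random subset, and strand-flip a small subset (which becomes
            # incompatible with the exposure coding and is dropped there).
            swap = rng.random(total) < p.frac_swapped
            df.loc[swap, ["EA", "OA"]] = df.loc[swap, ["OA", "EA"]].to_numpy()
            df.loc[swap, "BETA"] = -df.loc[swap, "BETA"]
            df.loc[swap, "EAF"] = 1.0 - df.loc[swap, "EAF"]
            flip = (rng.random(total) < p.frac_strand_flipped) & ~is_pal
            df.loc[flip, "EA"] = df.loc[flip, "EA"].map(_COMPLEMENT)
            df.loc[flip, "OA"] = df.loc[flip, "OA"].map(_COMPLEMENT)
        return SummaryStats(trait_id=trait_id, trait_type="continuous", df=df)

    exposure = _panel(truth_exp, se_exp, p.n_exp, p.exposure_id, downstream=False)
    mediator = _panel(truth_med, se_med, p.n_med, p.mediator_id, downstream=True)
    outcome = _panel(truth_out, se_out, p.n_out, p.outcome_id, downstream=True)

    layout = exposure.df[["SNP", "CHR", "POS"]]
    ld = simulate_ld_blocks(layout, p.ld_block[0], p.ld_block[1])

    truth = TruthRecord(
        valid_instrument_ids=list(ids[is_exp]),
        mediator_instrument_ids=list(ids[is_med]),
        outcome_instrument_ids=list(ids[is_out]),
        planted_weak_ids=list(ids[is_weak]),
        planted_palindromic_ids=list(ids[is_pal]),
        planted_outlier_ids=list(ids[outlier_idx]),
        theta1=p.theta1,
        theta2=p.theta2,
        theta_direct=p.theta_direct,
        true_total=p.true_total,
        true_indirect=p.true_indirect,
        true_proportion=(
            p.true_indirect / p.true_total if p.true_total != 0 else math.nan
        ),
    )
    return exposure, mediator, outcome, ld, truth
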