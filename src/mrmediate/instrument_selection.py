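"""Selection of independent, strong genetic instruments from an exposure panel.

Instruments are chosen in three stages, in the order the screening is run:
a genome-wide association threshold (p < 1e-5 by default, suited to
molecular traits with modest GWAS sample sizes), greedy LD clumping
(r^2 < 0.01 within a 10,000 kb window) against an explicit pairwise LD
table, and a per-SNP instrument-strength filter F = (beta/se)^2 >= 10.
An audit of removals at each stage is kept so that every input SNP is
accounted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_io import SummaryStats

logger = logging.getLogger("mrmediate")


class LDTable:
    """Sparse symmetric table of pairwise LD r-squared values.

    Absent pairs default to r^2 = 0 (the SNPs are treated as independent);
    the number of defaulted lookups is counted in ``n_default_lookups`` so a
    run can report how much of its clumping relied on missing LD
    information.  r^2(x, x) = 1 implicitly.
    """

    def __init__(self, pairs=None):
        self._r2: dict[tuple[str, str], float] = {}
        self.n_default_lookups = 0
        if pairs is not None:
            for a, b, r2 in pairs:
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r^2 must lie in [0,1], got {r2} for ({a},{b})")
        if a != b:
            self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self._r2.get(self._key(a, b))
        if val is None:
            self.n_default_lookups += 1
            return 0.0
        return val

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path) -> "LDTable":
        """Read a tab-separated table with columns SNP_A, SNP_B, R2."""
        df = pd.read_csv(path, sep="\t")
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ValueError(f"LD table {path}: missing column {col!r}")
        return cls(zip(df["SNP_A"].astype(str), df["SNP_B"].astype(str), df["R2"]))

    def to_file(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"]).to_csv(path, sep="\t", index=False)


@dataclass
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline."""

    pval_threshold: float = 1e-5
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure plus a removal audit."""

    exposure_id: str
    df: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["SNP"])

    def __len__(self) -> int:
        return len(self.df)


def filter_by_pvalue(panel: SummaryStats, threshold: float = 1e-5) -> pd.DataFrame:
    """Rows with association p strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"p-value threshold must lie in (0,1], got {threshold}")
    kept = panel.df[panel.df["P"] < threshold].reset_index(drop=True)
    if kept.empty:
        logger.info("%s: no SNPs below p threshold %g", panel.trait_id, threshold)
    return kept


def f_statistic(beta, se):
    """Per-SNP instrument strength F = (beta/se)^2.

    Accepts scalars or arrays; the per-SNP form is the standard
    summary-level approximation to the first-stage F.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_weak_instruments(snps: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Retain SNPs with F >= f_min (strict exclusion of F < f_min)."""
    if snps.empty:
        return snps
    f = f_statistic(snps["BETA"].to_numpy(), snps["SE"].to_numpy())
    return snps[f >= f_min].reset_index(drop=True)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric ordering for chromosome labels, X/Y/MT after the autosomes."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return chrom.astype(str).map(
        lambda c: int(c) if c.isdigit() else special.get(c, 26)
    )


def clump(
    snps: pd.DataFrame,
    ld: LDTable,
    r2_max: float = 0.01,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    Candidates are ordered by p (ties broken by chromosome, position, then
    identifier, so results never depend on input row order).  The best
    remaining SNP is accepted and every remaining SNP on the same chromosome
    within ``window_kb`` kilobases with r^2 above ``r2_max`` is discarded;
    pairs beyond the window or on different chromosomes are never compared.
    """
    if snps.empty:
        return snps
    df = snps.copy()
    df["_ck"] = _chrom_sort_key(df["CHR"])
    df = df.sort_values(["P", "_ck", "POS", "SNP"], kind="mergesort").drop(columns="_ck")

    window_bp = float(window_kb) * 1000.0
    ids = df["SNP"].to_numpy()
    chroms = df["CHR"].astype(str).to_numpy()
    pos = df["POS"].to_numpy(float)

    alive = np.ones(len(df), dtype=bool)
    kept_idx: list[int] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        alive[i] = False
        in_window = (
            alive
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.nonzero(in_window)[0]:
            if ld.r2(ids[i], ids[j]) > r2_max:
                alive[j] = False
    return df.iloc[sorted(kept_idx)].reset_index(drop=True)


def select_instruments(
    panel: SummaryStats,
    ld: LDTable,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Compose the three filters: p-threshold -> LD clumping -> F filter."""
    cfg = config or SelectionConfig()
    n_input = panel.n_snps

    sig = filter_by_pvalue(panel, cfg.pval_threshold)
    clumped = clump(sig, ld, cfg.clump_r2, cfg.clump_window_kb)
    strong = filter_weak_instruments(clumped, cfg.f_min)

    audit = {
        "n_input": n_input,
        "removed_pvalue": n_input - len(sig),
        "removed_clump": len(sig) - len(clumped),
        "removed_weak": len(clumped) - len(strong),
        "n_retained": len(strong),
    }
    logger.info("select_instruments %s: %s", panel.trait_id, audit)
    return InstrumentSet(exposure_id=panel.trait_id, df=strong, audit=audit)
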