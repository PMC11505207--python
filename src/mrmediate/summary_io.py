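"""Reading, validating, writing and harmonizing GWAS summary statistics.

A summary-statistics panel is one genome-wide association study reduced to
one row per SNP: identifier, genomic coordinates, effect/other allele,
effect-allele frequency, effect size (log-odds for binary traits,
standardized units for continuous traits), its standard error, p-value and
sample size.  Two source dialects are supported alongside the package's own
generic tab-separated layout: the GWAS Catalog full-summary format and the
FinnGen release format.

Harmonization aligns an exposure panel and an outcome panel onto a shared
effect allele so that per-SNP effects are comparable: identically oriented
records are kept as-is, allele-swapped records have the outcome effect
sign-flipped, palindromic SNPs (A/T or G/C, strand-unresolvable) are
removed, and incompatible allele pairs are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mrmediate")

#: Two-sided 95% normal quantile; used everywhere a 95% CI is formed.
Z_95 = 1.959964

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the generic dialect.
GENERIC_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: Source-column -> generic-column maps for each supported dialect.
DIALECT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in GENERIC_COLUMNS},
    "finngen": {
        "rsids": "SNP",
        "#chrom": "CHR",
        "pos": "POS",
        "alt": "EA",
        "ref": "OA",
        "af_alt": "EAF",
        "beta": "BETA",
        "sebeta": "SE",
        "pval": "P",
    },
    "gwascatalog": {
        "variant_id": "SNP",
        "chromosome": "CHR",
        "base_pair_location": "POS",
        "effect_allele": "EA",
        "other_allele": "OA",
        "effect_allele_frequency": "EAF",
        "beta": "BETA",
        "standard_error": "SE",
        "p_value": "P",
    },
}

# Columns that may be absent as a whole (generic) or missing per-row.
_OPTIONAL_COLUMNS = {"EAF", "N"}


class DialectError(ValueError):
    """A file does not conform to the declared summary-statistics dialect."""


class EmptyPanelError(ValueError):
    """No valid SNP rows remain after validation."""


class HarmonizationError(ValueError):
    """Exposure and outcome panels share no usable SNPs."""


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id
        Accession-style identifier of the trait.
    trait_type
        ``"binary"`` (effects are log-odds) or ``"continuous"``.
    df
        One row per SNP with the generic columns
        ``SNP CHR POS EA OA EAF BETA SE P N``.  ``EAF``/``N`` may be NaN.
    drops
        Row counts removed at read time, keyed by reason.
    """

    trait_id: str
    trait_type: str = "continuous"
    df: pd.DataFrame = field(default_factory=pd.DataFrame)
    drops: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "SummaryStats":
        mask = self.df["SNP"].isin(set(snp_ids))
        return SummaryStats(self.trait_id, self.trait_type, self.df[mask].reset_index(drop=True))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a shared effect allele.

    ``df`` has one row per retained SNP with columns
    ``SNP, EA, OA, beta_exp, se_exp, beta_out, se_out`` (alleles in the
    exposure orientation) plus ``CHR``/``POS`` when available.  Every row's
    exposure and outcome effects refer to the same effect allele, and no
    palindromic allele pair is ever present.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    n_missing_outcome: int = 0

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        """Return a copy without the given SNPs (used for outlier removal)."""
        keep = ~self.df["SNP"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.df[keep].reset_index(drop=True),
            self.n_dropped_palindromic,
            self.n_dropped_incompatible,
            self.n_missing_outcome,
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.df
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or G/C (strand-unresolvable)."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"invalid allele pair {a1!r}/{a2!r}: alleles must be one of A,C,G,T")
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


def beta_from_or(or_value: float, l95: float, u95: float) -> tuple[float, float]:
    """Convert an odds ratio with 95% CI to a log-odds effect and its SE.

    ``beta = ln(OR)``; ``se = (ln(U95) - ln(L95)) / (2 * 1.959964)``.
    """
    if not (or_value > 0 and l95 > 0 and u95 > 0):
        raise ValueError("odds ratio and CI bounds must be positive")
    if not (l95 <= or_value <= u95):
        raise ValueError(f"require L95 <= OR <= U95, got {l95}, {or_value}, {u95}")
    beta = math.log(or_value)
    se = (math.log(u95) - math.log(l95)) / (2.0 * Z_95)
    return beta, se


def _require_columns(header: list[str], dialect: str) -> dict[str, str]:
    colmap = DIALECT_COLUMN_MAPS.get(dialect)
    if colmap is None:
        raise DialectError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECT_COLUMN_MAPS)}"
        )
    for src, dst in colmap.items():
        if dst in _OPTIONAL_COLUMNS:
            continue
        if src not in header:
            raise DialectError(
                f"dialect {dialect!r}: required column {src!r} (-> {dst}) missing from header"
            )
    return colmap


def read_summary_stats(
    path,
    dialect: str = "generic",
    trait_type: str = "continuous",
    trait_id: str | None = None,
) -> SummaryStats:
    """Read a summary-statistics file, validating and normalizing each row.

    Rows failing any per-SNP invariant (missing/invalid beta, se, p; se <= 0;
    non-biallelic or non-ACGT alleles; effect allele equal to other allele;
    duplicated identifier) are dropped and counted in ``drops``.  Alleles are
    uppercased.  ``EAF`` and ``N`` may be absent or missing per row.
    """
    header = list(pd.read_csv(path, sep="\t", nrows=0).columns)
    colmap = _require_columns(header, dialect)
    text_cols = {src for src, dst in colmap.items() if dst in ("SNP", "CHR", "EA", "OA")}
    raw = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA", "nan", ""],
        dtype={c: str for c in text_cols},
        float_precision="round_trip",
    )
    df = raw.rename(columns=colmap)
    df = df[[c for c in GENERIC_COLUMNS if c in df.columns]].copy()
    for c in _OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    for c in ("POS", "EAF", "BETA", "SE", "P", "N"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    df["CHR"] = df["CHR"].astype(str).str.upper().str.removeprefix("CHR")

    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
            logger.debug("%s: dropped %d rows (%s)", path, n, reason)
        return df[~mask]

    df = _drop(df["BETA"].isna() | df["SE"].isna() | df["P"].isna(), "missing_beta_se_p")
    df = _drop(~(df["SE"] > 0), "nonpositive_se")
    df = _drop(~((df["P"] > 0) & (df["P"] <= 1)), "pval_out_of_range")
    ok_alleles = df["EA"].isin(VALID_ALLELES) & df["OA"].isin(VALID_ALLELES)
    df = _drop(~ok_alleles, "non_biallelic_snp")  # indels / multi-allelic codes
    df = _drop(df["EA"] == df["OA"], "identical_alleles")
    bad_eaf = df["EAF"].notna() & ~((df["EAF"] >= 0) & (df["EAF"] <= 1))
    df = _drop(bad_eaf, "eaf_out_of_range")
    df = _drop(df["SNP"].duplicated(keep="first"), "duplicate_snp_id")

    if df.empty:
        raise EmptyPanelError(f"{path}: no valid SNP rows after validation")

    df = df[GENERIC_COLUMNS].reset_index(drop=True)
    tid = trait_id if trait_id is not None else str(path)
    return SummaryStats(trait_id=tid, trait_type=trait_type, df=df, drops=drops)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write a panel as tab-separated text with the generic header."""
    out = stats.df[GENERIC_COLUMNS].copy()
    # %.17g guarantees bit-exact float round-trips through the text format
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def harmonize(instruments, outcome: SummaryStats) -> HarmonizedSet:
    """Align instrument SNPs from an exposure panel with an outcome panel.

    For each instrument SNP present in the outcome panel:

    * same allele orientation -> outcome beta kept as-is;
    * effect/other alleles swapped -> outcome beta sign-flipped (and the
      outcome EAF complemented);
    * palindromic allele pair in either panel -> SNP removed, counted;
    * any other allele combination -> incompatible, removed, counted.

    Instruments absent from the outcome panel are dropped with a log entry;
    no LD-proxy search is attempted.  Palindromic SNPs are removed
    unconditionally — no allele-frequency rescue.
    """
    exp_id = getattr(instruments, "exposure_id", None) or getattr(instruments, "trait_id", "exposure")
    exp_df = instruments.df if hasattr(instruments, "df") else instruments
    if len(exp_df) == 0:
        raise HarmonizationError(f"no instruments supplied for exposure {exp_id!r}")

    out_df = outcome.df.set_index("SNP")
    merged = exp_df.merge(
        out_df[["EA", "OA", "BETA", "SE"]],
        left_on="SNP",
        right_index=True,
        how="inner",
        suffixes=("", "_out"),
    )
    n_missing = len(exp_df) - len(merged)
    if n_missing:
        absent = sorted(set(exp_df["SNP"]) - set(merged["SNP"]))
        logger.info(
            "harmonize %s->%s: %d instruments absent from outcome panel: %s",
            exp_id, outcome.trait_id, n_missing, ",".join(absent[:10]),
        )

    ea_x, oa_x = merged["EA"], merged["OA"]
    ea_y, oa_y = merged["EA_out"].str.upper(), merged["OA_out"].str.upper()

    pal_x = (ea_x + oa_x).isin(["AT", "TA", "GC", "CG"])
    pal_y = (ea_y + oa_y).isin(["AT", "TA", "GC", "CG"])
    palindromic = pal_x | pal_y
    same = (ea_x == ea_y) & (oa_x == oa_y) & ~palindromic
    swapped = (ea_x == oa_y) & (oa_x == ea_y) & ~palindromic
    incompatible = ~(same | swapped | palindromic)

    beta_out = merged["BETA_out"].where(~swapped, -merged["BETA_out"])

    keep = same | swapped
    rows = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "CHR": merged.get("CHR"),
            "POS": merged.get("POS"),
            "EA": ea_x,
            "OA": oa_x,
            "beta_exp": merged["BETA"].astype(float),
            "se_exp": merged["SE"].astype(float),
            "beta_out": beta_out.astype(float),
            "se_out": merged["SE_out"].astype(float),
        }
    )[keep].reset_index(drop=True)

    h = HarmonizedSet(
        exposure_id=exp_id,
        outcome_id=outcome.trait_id,
        df=rows,
        n_dropped_palindromic=int(palindromic.sum()),
        n_dropped_incompatible=int(incompatible.sum()),
        n_missing_outcome=n_missing,
    )
    if h.n_snp == 0:
        raise HarmonizationError(
            f"no usable SNPs shared between exposure {exp_id!r} and outcome {outcome.trait_id!r}"
        )
    return h
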