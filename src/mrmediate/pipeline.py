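"""Orchestration of the three-step causal screen.

Step 1 screens every exposure against every outcome with bidirectional MR
(forward and reverse fits); step 2 does the same for mediators, plus the
exposure -> mediator leg; step 3 assembles exposure -> mediator -> outcome
triples whose three legs are all significant and unidirectional, and
decomposes each with the mediation module.

For every pair the screen selects instruments from the exposure panel,
harmonizes them to the outcome panel, removes MR-PRESSO outliers, and
reports the outlier-corrected IVW estimate as primary (the uncorrected fit
is kept alongside), together with Cochran's Q, the MR-Egger intercept test,
the MR-PRESSO global p and a leave-one-out influence flag.  Multiple
testing is disclosed (a count of tests performed accompanies the tables),
never corrected: p-values are nominal.

Everything is deterministic given the input panels, the configuration and
its seed: per-pair Monte-Carlo seeds are derived from the run seed and the
trait identifiers, so output tables replay byte-identically.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .instrument_selection import LDTable, SelectionConfig, select_instruments
from .mediation import MediationResult, mediation_table, two_step_mediation
from .mr_core import (
    EggerResult,
    HeterogeneityStats,
    InsufficientInstrumentsError,
    LeaveOneOutResult,
    MREstimate,
    cochran_q,
    egger,
    estimate_effect,
    leave_one_out,
)
from .mr_presso import MIN_SNPS as PRESSO_MIN_SNPS
from .mr_presso import PressoResult, mr_presso
from .summary_io import HarmonizationError, SummaryStats, harmonize

logger = logging.getLogger("mrmediate")


@dataclass
class PipelineConfig:
    """Thresholds and reproducibility settings for a full run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    presso_nsim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")


@dataclass
class ScreenRow:
    """One direction of one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    direction: str  # forward | reverse
    estimate: MREstimate  # primary (outlier-corrected when PRESSO flags)
    raw_estimate: MREstimate
    heterogeneity: HeterogeneityStats | None
    egger_result: EggerResult | None
    presso: PressoResult | None
    loo: LeaveOneOutResult | None
    significant: bool
    n_outliers_removed: int = 0
    unidirectional: bool | None = None  # set by bidirectional_filter

    @property
    def egger_intercept_pval(self) -> float | None:
        return self.egger_result.intercept_pval if self.egger_result else None

    @property
    def presso_global_pval(self) -> float | None:
        return self.presso.global_pval if self.presso else None

    @property
    def loo_flag(self) -> bool | None:
        return self.loo.influential if self.loo else None


@dataclass
class SkippedPair:
    exposure_id: str
    outcome_id: str
    direction: str
    reason: str


def _pair_seed(config: PipelineConfig, exposure_id: str, outcome_id: str, direction: str) -> int:
    tag = f"{exposure_id}|{outcome_id}|{direction}".encode()
    return (config.seed * 1_000_003 + zlib.crc32(tag)) % 2**31


def run_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDTable,
    config: PipelineConfig,
    direction: str = "forward",
) -> ScreenRow | SkippedPair:
    """Screen one exposure against one outcome in one direction."""

    def _skip(reason: str) -> SkippedPair:
        logger.warning(
            "pair %s -> %s (%s) skipped: %s",
            exposure.trait_id, outcome.trait_id, direction, reason,
        )
        return SkippedPair(exposure.trait_id, outcome.trait_id, direction, reason)

    instruments = select_instruments(exposure, ld, config.selection)
    if len(instruments) == 0:
        return _skip("no instruments passed selection")
    try:
        h = harmonize(instruments, outcome)
    except HarmonizationError as exc:
        return _skip(str(exc))

    raw_estimate = estimate_effect(h)

    presso = None
    h_final = h
    outliers: list[str] = []
    if h.n_snp >= PRESSO_MIN_SNPS:
        presso = mr_presso(
            h,
            n_sim=config.presso_nsim,
            seed=_pair_seed(config, exposure.trait_id, outcome.trait_id, direction),
            outlier_alpha=config.presso_outlier_alpha,
        )
        presso.sim_state = None  # drop the bulky simulation arrays
        outliers = presso.outliers
        if outliers and h.n_snp - len(outliers) >= 1:
            h_final = h.drop_snps(outliers)
            logger.info(
                "pair %s -> %s (%s): removed %d MR-PRESSO outliers: %s",
                exposure.trait_id, outcome.trait_id, direction,
                len(outliers), ",".join(outliers),
            )

    estimate = estimate_effect(h_final)
    het = cochran_q(h_final, estimate.beta) if h_final.n_snp >= 2 else None
    try:
        egger_result = egger(h_final) if h_final.n_snp >= 3 else None
    except InsufficientInstrumentsError:
        egger_result = None
    loo = leave_one_out(h_final) if h_final.n_snp >= 3 else None

    return ScreenRow(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        direction=direction,
        estimate=estimate,
        raw_estimate=raw_estimate,
        heterogeneity=het,
        egger_result=egger_result,
        presso=presso,
        loo=loo,
        significant=bool(estimate.pval < config.alpha),
        n_outliers_removed=len(outliers),
    )


def bidirectional_filter(rows: list[ScreenRow]) -> list[ScreenRow]:
    """Annotate forward rows with the unidirectional-causality flag.

    A pair is unidirectional iff its forward fit is significant and its
    reverse fit is present and not significant.  Forward rows without a
    reverse counterpart keep ``unidirectional = None`` (undetermined).
    """
    reverse = {
        (r.outcome_id, r.exposure_id): r for r in rows if r.direction == "reverse"
    }
    for row in rows:
        if row.direction != "forward":
            continue
        rev = reverse.get((row.exposure_id, row.outcome_id))
        if rev is None:
            logger.warning(
                "pair %s -> %s: reverse fit missing, unidirectional flag undetermined",
                row.exposure_id, row.outcome_id,
            )
            row.unidirectional = None
        else:
            row.unidirectional = bool(row.significant and not rev.significant)
    return rows


def _causal_forward(rows: list[ScreenRow]) -> dict[tuple[str, str], ScreenRow]:
    return {
        (r.exposure_id, r.outcome_id): r
        for r in rows
        if r.direction == "forward"
    }


def assemble_triples(
    total_rows: list[ScreenRow],
    step1_rows: list[ScreenRow],
    step2_rows: list[ScreenRow],
) -> tuple[list[MediationResult], list[dict]]:
    """Join the three screens into mediation triples.

    A triple (exposure E, mediator M, outcome O) is assembled iff the
    E->O, E->M and M->O forward legs are all significant and
    unidirectional; otherwise the failing leg is recorded.
    """
    totals = _causal_forward(total_rows)
    step1 = _causal_forward(step1_rows)
    step2 = _causal_forward(step2_rows)

    results: list[MediationResult] = []
    rejected: list[dict] = []
    for (e, o), trow in sorted(totals.items()):
        for (e1, m) in sorted(step1):
            if e1 != e:
                continue
            s1, s2 = step1[(e, m)], step2.get((m, o))
            legs = {
                f"total {e}->{o}": trow,
                f"step1 {e}->{m}": s1,
                f"step2 {m}->{o}": s2,
            }
            failing = [
                name
                for name, row in legs.items()
                if row is None or not (row.significant and row.unidirectional)
            ]
            if failing:
                rejected.append(
                    {"exposure": e, "mediator": m, "outcome": o, "failing_legs": failing}
                )
                continue
            results.append(
                two_step_mediation(trow.estimate, s1.estimate, s2.estimate, e, m, o)
            )
    return results, rejected


@dataclass
class PipelineResult:
    screen_rows: list[ScreenRow]
    skipped: list[SkippedPair]
    mediation_results: list[MediationResult]
    rejected_triples: list[dict]
    n_tests: int  # MR fits performed (multiple-testing disclosure)

    def screen_table(self) -> pd.DataFrame:
        recs = []
        for r in self.screen_rows:
            e = r.estimate
            recs.append({
                "exposure": r.exposure_id,
                "outcome": r.outcome_id,
                "direction": r.direction,
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
                "q": r.heterogeneity.Q if r.heterogeneity else None,
                "q_pval": r.heterogeneity.pval if r.heterogeneity else None,
                "egger_intercept_pval": r.egger_intercept_pval,
                "presso_global_pval": r.presso_global_pval,
                "n_outliers_removed": r.n_outliers_removed,
                "loo_flag": r.loo_flag,
                "significant": r.significant,
                "unidirectional": r.unidirectional,
                "n_tests": self.n_tests,
            })
        return pd.DataFrame.from_records(recs)

    def mediation_df(self) -> pd.DataFrame:
        return mediation_table(self.mediation_results)

    def sidecar(self) -> dict:
        """JSON-serializable sensitivity details per screened pair."""
        out = {}
        for r in self.screen_rows:
            key = f"{r.exposure_id}->{r.outcome_id}:{r.direction}"
            out[key] = {
                "raw_b": r.raw_estimate.beta,
                "raw_se": r.raw_estimate.se,
                "raw_pval": r.raw_estimate.pval,
                "raw_nsnp": r.raw_estimate.n_snp,
                "presso": None
                if r.presso is None
                else {
                    "rss_obs": r.presso.rss_obs,
                    "global_pval": r.presso.global_pval,
                    "n_sim": r.presso.n_sim,
                    "seed": r.presso.seed,
                    "outliers": r.presso.outliers,
                    "outlier_pvals": None
                    if r.presso.outlier_pvals is None
                    else r.presso.outlier_pvals.to_dict(),
                    "distortion_coef": r.presso.distortion_coef,
                    "distortion_pval": r.presso.distortion_pval,
                },
            }
        out["skipped"] = [s.__dict__ for s in self.skipped]
        out["rejected_triples"] = self.rejected_triples
        return out


def run_pipeline(
    exposures: dict[str, SummaryStats],
    mediators: dict[str, SummaryStats],
    outcomes: dict[str, SummaryStats],
    ld: LDTable | dict[str, LDTable],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full three-step screen over trait collections."""
    config = config or PipelineConfig()

    def _ld_for(trait_id: str) -> LDTable:
        return ld[trait_id] if isinstance(ld, dict) else ld

    rows: list[ScreenRow] = []
    skipped: list[SkippedPair] = []
    n_tests = 0

    def _run(exp: SummaryStats, out: SummaryStats, direction: str) -> ScreenRow | None:
        nonlocal n_tests
        n_tests += 1
        res = run_pair(exp, out, _ld_for(exp.trait_id), config, direction)
        if isinstance(res, SkippedPair):
            skipped.append(res)
            return None
        rows.append(res)
        return res

    total_rows: list[ScreenRow] = []
    step1_rows: list[ScreenRow] = []
    step2_rows: list[ScreenRow] = []

    for e in exposures.values():
        for o in outcomes.values():
            fwd = _run(e, o, "forward")
            rev = _run(o, e, "reverse")
            total_rows += [r for r in (fwd, rev) if r]
    for e in exposures.values():
        for m in mediators.values():
            fwd = _run(e, m, "forward")
            rev = _run(m, e, "reverse")
            step1_rows += [r for r in (fwd, rev) if r]
    for m in mediators.values():
        for o in outcomes.values():
            fwd = _run(m, o, "forward")
            rev = _run(o, m, "reverse")
            step2_rows += [r for r in (fwd, rev) if r]

    for group in (total_rows, step1_rows, step2_rows):
        bidirectional_filter(group)

    mediation_results, rejected = assemble_triples(total_rows, step1_rows, step2_rows)
    return PipelineResult(
        screen_rows=rows,
        skipped=skipped,
        mediation_results=mediation_results,
        rejected_triples=rejected,
        n_tests=n_tests,
    )


def write_outputs(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write screen table, mediation table and the JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "screen": outdir / "screen.tsv",
        "mediation": outdir / "mediation.tsv",
        "sidecar": outdir / "sensitivity.json",
    }
    result.screen_table().to_csv(paths["screen"], sep="\t", index=False, na_rep="NA")
    result.mediation_df().to_csv(paths["mediation"], sep="\t", index=False, na_rep="NA")
    with open(paths["sidecar"], "w") as fh:
        json.dump(result.sidecar(), fh, indent=1, sort_keys=True)
    logger.info("wrote outputs to %s", outdir)
    return paths
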