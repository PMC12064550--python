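"""End-to-end orchestration: instrument selection through screening and mediation.

A single :class:`MrConfig` carries every threshold (defaults are the
conventional two-sample-MR settings: p <= 5e-5 instrument screen, LD
clumping at r2 < 0.01 within 10,000 kb, F > 10, alpha = 0.05, proxy
r2 >= 0.8) so one config reproduces a whole analysis. Batch runs isolate
failures: a single failing exposure is logged and skipped, never aborting
the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MedimrError, NoInstrumentsError
from .estimators import MrResult, all_methods
from .harmonize import HarmonizedSet, ProxyTable, harmonize
from .instruments import (
    DEFAULT_CLUMP_KB, DEFAULT_CLUMP_R2, DEFAULT_F_MIN, DEFAULT_P_MAX,
    LdMatrix, clump, filter_weak, select_by_pvalue,
)
from .screening import (
    MediationResult, ScreenRecord, assemble_pairs, screen_total_effects,
)
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SumStats

logger = logging.getLogger("medimr")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class MrConfig:
    """All analysis thresholds and estimator settings in one place."""

    p_max: float = DEFAULT_P_MAX
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: int = DEFAULT_CLUMP_KB
    f_min: float = DEFAULT_F_MIN
    alpha: float = 0.05
    proxy_r2_min: float = 0.8
    ivw_variant: str = "mre"
    n_boot: int = 1000
    phi: float = 1.0
    screen_on: str = "nominal"
    reverse_p_max: float = DEFAULT_P_MAX
    seed: int = 0


@dataclass
class PairAnalysis:
    """Everything computed for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    harmonized: HarmonizedSet
    results: dict[str, MrResult]
    sensitivity: SensitivityReport


def prepare_instruments(
    exposure: SumStats,
    outcome: SumStats,
    ld: LdMatrix | None = None,
    proxies: ProxyTable | None = None,
    config: MrConfig = MrConfig(),
    exclude_snps=None,
) -> HarmonizedSet:
    """select -> clump -> harmonize -> filter_weak for one pair.

    ``exclude_snps`` removes named SNPs before selection (used by the
    mediation step to keep the mediator's instruments independent of the
    exposure's).
    """
    sel = select_by_pvalue(exposure, config.p_max)
    if exclude_snps:
        drop = set(exclude_snps)
        sel = sel.subset((~sel.table["snp_id"].isin(drop)).to_numpy())
    if sel.n_snps == 0:
        raise NoInstrumentsError(exposure.trait_id, outcome.trait_id, stage="select")
    if ld is not None:
        sel, audit = clump(sel, ld, config.clump_r2, config.clump_kb)
        for w in audit.warnings:
            logger.info("clump[%s]: %s", exposure.trait_id, w)
    h = harmonize(sel, outcome, proxies=proxies, proxy_r2_min=config.proxy_r2_min)
    return filter_weak(h, config.f_min)


def analyze_pair(
    exposure: SumStats,
    outcome: SumStats,
    ld: LdMatrix | None = None,
    proxies: ProxyTable | None = None,
    config: MrConfig = MrConfig(),
    exclude_snps=None,
) -> PairAnalysis:
    """Full single-pair analysis: instruments, five estimators, diagnostics."""
    h = prepare_instruments(exposure, outcome, ld, proxies, config, exclude_snps)
    results = all_methods(
        h,
        ivw_variant=config.ivw_variant,
        n_boot=config.n_boot,
        phi=config.phi,
        seed=config.seed,
        binary_outcome=outcome.trait_type == "binary",
    )
    sens = (
        sensitivity_report(h, alpha=config.alpha, ivw_variant=config.ivw_variant)
        if h.n_snp >= 2
        else SensitivityReport(
            h.exposure_id, h.outcome_id, None, None, None, None, [], config.ivw_variant
        )
    )
    return PairAnalysis(exposure.trait_id, outcome.trait_id, h, results, sens)


def reverse_mr(
    exposure: SumStats,
    outcome: SumStats,
    ld: LdMatrix | None = None,
    config: MrConfig = MrConfig(),
) -> MrResult | None:
    """Outcome-as-exposure IVW; None when the outcome has no instruments."""
    cfg = replace(config, p_max=config.reverse_p_max)
    try:
        pa = analyze_pair(outcome, exposure, ld=ld, config=cfg)
    except (NoInstrumentsError, MedimrError):
        return None
    return pa.results.get("ivw")


@dataclass
class ScreenOutput:
    records: list[ScreenRecord]
    pairs: dict[str, PairAnalysis] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "exposure_id", "ivw_pval", "fdr_pval", "ivw_or",
            "direction_consistent", "pleiotropy_ok", "heterogeneity_ok",
            "reverse_ok", "verdict", "reason",
        ]
        return pd.DataFrame([
            {c: getattr(r, c) for c in cols} for r in self.records
        ], columns=cols)


def run_total_screen(
    exposures: list[SumStats],
    outcome: SumStats,
    ld: LdMatrix | None = None,
    proxies: ProxyTable | None = None,
    config: MrConfig = MrConfig(),
    do_reverse: bool = True,
) -> ScreenOutput:
    """Screen a batch of exposures against one outcome.

    Per exposure: instruments -> five estimators -> sensitivity ->
    screening gates; reverse-direction MR recorded descriptively.
    """
    batch: dict[str, tuple[dict[str, MrResult], SensitivityReport]] = {}
    reverse: dict[str, MrResult | None] = {}
    pairs: dict[str, PairAnalysis] = {}
    failures: dict[str, str] = {}
    for exp in exposures:
        try:
            pa = analyze_pair(exp, outcome, ld=ld, proxies=proxies, config=config)
        except MedimrError as e:
            logger.warning("exposure %s skipped: %s", exp.trait_id, e)
            failures[exp.trait_id] = str(e)
            continue
        pairs[exp.trait_id] = pa
        batch[exp.trait_id] = (pa.results, pa.sensitivity)
        reverse[exp.trait_id] = (
            reverse_mr(exp, outcome, ld=ld, config=config) if do_reverse else None
        )
    records = screen_total_effects(
        batch, reverse=reverse, alpha=config.alpha, screen_on=config.screen_on
    )
    for xid, why in failures.items():
        records.append(ScreenRecord(
            exposure_id=xid, ivw_pval=float("nan"), fdr_pval=float("nan"),
            ivw_or=float("nan"), direction_consistent=False, pleiotropy_ok=False,
            heterogeneity_ok=False, reverse_ok="untestable",
            verdict="excluded", reason=why,
        ))
    records.sort(key=lambda r: r.exposure_id)
    return ScreenOutput(records=records, pairs=pairs, failures=failures)


@dataclass
class MediationOutput:
    pairs: list[MediationResult]
    screen: ScreenOutput
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "exposure_id", "mediator_id", "outcome_id",
            "beta1", "se1", "pval1", "beta2", "se2", "pval2",
            "total", "se_total", "me", "se_me", "mp_pct", "se_mp_pct",
            "direct", "meaningful",
        ]
        return pd.DataFrame([
            {c: getattr(r, c) for c in cols} for r in self.pairs
        ], columns=cols)


def run_mediation(
    exposures: list[SumStats],
    mediators: list[SumStats],
    outcome: SumStats,
    ld: LdMatrix | None = None,
    config: MrConfig = MrConfig(),
    screen: ScreenOutput | None = None,
) -> MediationOutput:
    """Two-step mediation over every exposure x mediator candidate.

    Legs: total (X->Y, from the screen), beta1 (X->M), beta2 (M->Y with the
    exposure's instruments excluded from the mediator's, so the second step
    is not contaminated by the X->Y direct path). Pair assembly and the
    'meaningful' flag follow :func:`medimr.screening.assemble_pairs`.
    """
    if screen is None:
        screen = run_total_screen(
            exposures, outcome, ld=ld, config=config, do_reverse=False
        )
    totals = {
        xid: pa.results["ivw"] for xid, pa in screen.pairs.items()
        if "ivw" in pa.results
    }
    passed = [r.exposure_id for r in screen.records if r.verdict != "excluded"]
    exp_by_id = {e.trait_id: e for e in exposures}
    failures: dict[str, str] = {}

    # marginal mediator -> outcome leg
    med_out: dict[str, MrResult] = {}
    for med in mediators:
        try:
            pa = analyze_pair(med, outcome, ld=ld, config=config)
            med_out[med.trait_id] = pa.results["ivw"]
        except MedimrError as e:
            failures[f"{med.trait_id}->outcome"] = str(e)

    sig_m = [m for m, res in med_out.items() if res.pval < config.alpha]

    # exposure -> mediator and per-pair re-estimated beta2 legs
    exp_med: dict[tuple[str, str], MrResult] = {}
    pair_beta2: dict[tuple[str, str], MrResult] = {}
    med_by_id = {m.trait_id: m for m in mediators}
    for xid in passed:
        exp = exp_by_id.get(xid)
        if exp is None:
            continue
        x_instruments = set(
            select_by_pvalue(exp, config.p_max).table["snp_id"]
        )
        for mid in sig_m:
            med = med_by_id[mid]
            try:
                pa = analyze_pair(exp, med, ld=ld, config=config)
                exp_med[(xid, mid)] = pa.results["ivw"]
            except MedimrError as e:
                failures[f"{xid}->{mid}"] = str(e)
                continue
            try:
                pb = analyze_pair(
                    med, outcome, ld=ld, config=config, exclude_snps=x_instruments
                )
                pair_beta2[(xid, mid)] = pb.results["ivw"]
            except MedimrError as e:
                failures[f"{mid}->outcome|excl {xid}"] = str(e)

    pairs = assemble_pairs(
        screen.records, med_out, exp_med, totals,
        outcome_id=outcome.trait_id, alpha=config.alpha, pair_beta2=pair_beta2,
    )
    return MediationOutput(pairs=pairs, screen=screen, failures=failures)


def write_tsv(df: pd.DataFrame, path) -> Path:
    """Deterministic TSV output (10 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def results_frame(pairs: dict[str, PairAnalysis]) -> pd.DataFrame:
    """Tidy one-row-per-(exposure, outcome, method) results table."""
    rows = []
    for xid in sorted(pairs):
        pa = pairs[xid]
        for method, r in pa.results.items():
            rows.append({
                "exposure_id": pa.exposure_id,
                "outcome_id": pa.outcome_id,
                "method": method,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "n_snp": r.n_snp,
                "or_point": r.or_point,
                "or_low": r.or_low,
                "or_high": r.or_high,
            })
    return pd.DataFrame(rows)


def sensitivity_frame(pairs: dict[str, PairAnalysis]) -> pd.DataFrame:
    rows = []
    for xid in sorted(pairs):
        s = pairs[xid].sensitivity
        if s.q_ivw is None:
            continue
        row = {
            "exposure_id": s.exposure_id,
            "outcome_id": s.outcome_id,
            "q_ivw": s.q_ivw.q, "q_ivw_df": s.q_ivw.df, "q_ivw_pval": s.q_ivw.pval,
        }
        if s.q_egger is not None:
            row.update({
                "q_egger": s.q_egger.q, "q_egger_df": s.q_egger.df,
                "q_egger_pval": s.q_egger.pval,
                "egger_intercept": s.egger_intercept.estimate,
                "egger_intercept_se": s.egger_intercept.se,
                "egger_intercept_pval": s.egger_intercept.pval,
                "pleiotropy_flag": s.pleiotropy_flag,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def loo_frame(pairs: dict[str, PairAnalysis]) -> pd.DataFrame:
    rows = []
    for xid in sorted(pairs):
        s = pairs[xid].sensitivity
        for e in s.loo:
            rows.append({
                "exposure_id": s.exposure_id,
                "outcome_id": s.outcome_id,
                "left_out_snp": e.left_out_snp,
                "estimate": e.estimate,
                "se": e.se,
                "pval": e.pval,
            })
    return pd.DataFrame(rows)
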