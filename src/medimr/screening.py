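"""Exposure screening cascade and two-step mediation decomposition.

Screening gates, applied per exposure in order: IVW p below alpha;
direction consistency (all five methods' odds ratios on the same side
of 1); no Egger-intercept pleiotropy signal (p > alpha); no Cochran-Q
heterogeneity signal (p > alpha). Survivors are classified ``risk``
(every OR > 1) or ``protective`` (every OR < 1); Benjamini-Hochberg
FDR-adjusted p-values are recorded alongside the nominal ones, and a
reverse-direction MR result is carried as a descriptive flag.

Mediation uses the product of coefficients: with beta1 the
exposure-to-mediator effect, beta2 the mediator-to-outcome effect and
``total`` the exposure-to-outcome effect, the mediated effect is
me = beta1*beta2, the direct effect total - me, and the mediated
proportion me/total (reported signed, in percent). Standard errors use
the no-covariance (independent-samples) delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedProportionError, ValidationError
from .estimators import MrResult
from .sensitivity import SensitivityReport

FIVE_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass(frozen=True)
class ScreenRecord:
    """One exposure's passage through the screening cascade."""

    exposure_id: str
    ivw_pval: float
    fdr_pval: float
    ivw_or: float
    direction_consistent: bool
    pleiotropy_ok: bool
    heterogeneity_ok: bool
    reverse_ok: str  # "pass" | "fail" | "untestable"
    verdict: str  # "risk" | "protective" | "excluded"
    reason: str = ""


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients decomposition for one X -> M -> Y triplet."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    pval1: float
    beta2: float
    se2: float
    pval2: float
    total: float
    se_total: float
    me: float
    se_me: float
    mp_pct: float
    se_mp_pct: float
    direct: float
    meaningful: bool = False


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(results: dict[str, MrResult]) -> tuple[bool, str]:
    """(consistent, 'risk'|'protective'|'') across the five methods.

    On the log scale OR > 1 is estimate > 0, so consistency is a shared sign.
    """
    signs = [np.sign(results[m].estimate) for m in FIVE_METHODS]
    if all(s > 0 for s in signs):
        return True, "risk"
    if all(s < 0 for s in signs):
        return True, "protective"
    return False, ""


def screen_total_effects(
    batch: dict[str, tuple[dict[str, MrResult], SensitivityReport]],
    reverse: dict[str, MrResult | None] | None = None,
    alpha: float = 0.05,
    screen_on: str = "nominal",
) -> list[ScreenRecord]:
    """Apply the screening cascade to a batch of exposures.

    ``batch`` maps exposure_id to (five-method results, sensitivity report);
    ``reverse`` optionally maps exposure_id to the reverse-direction IVW
    result (None meaning untestable). ``screen_on`` chooses whether the
    significance gate uses the nominal IVW p-value (default) or the
    FDR-adjusted one. An exposure missing any of the five methods is
    recorded as excluded with the reason, never aborting the batch.
    """
    if screen_on not in ("nominal", "fdr"):
        raise ValidationError(f"screen_on must be 'nominal' or 'fdr', got {screen_on!r}")
    ids = list(batch)
    ivw_p = {}
    for xid in ids:
        results, _ = batch[xid]
        ivw_p[xid] = results["ivw"].pval if "ivw" in results else np.nan
    testable = [x for x in ids if np.isfinite(ivw_p[x])]
    fdr = dict(zip(testable, bh_fdr([ivw_p[x] for x in testable]))) if testable else {}

    records = []
    for xid in ids:
        results, sens = batch[xid]
        missing = [m for m in FIVE_METHODS if m not in results]
        rev = (reverse or {}).get(xid)
        if rev is None:
            reverse_ok = "untestable"
        else:
            reverse_ok = "pass" if rev.pval >= alpha else "fail"
        if missing:
            records.append(ScreenRecord(
                exposure_id=xid,
                ivw_pval=float(ivw_p.get(xid, np.nan)),
                fdr_pval=float(fdr.get(xid, np.nan)),
                ivw_or=float(np.exp(results["ivw"].estimate)) if "ivw" in results else np.nan,
                direction_consistent=False,
                pleiotropy_ok=False,
                heterogeneity_ok=False,
                reverse_ok=reverse_ok,
                verdict="excluded",
                reason=f"missing methods: {','.join(missing)}",
            ))
            continue

        p_gate = fdr[xid] if screen_on == "fdr" else ivw_p[xid]
        consistent, side = _direction(results)
        pleio_ok = sens.egger_intercept is not None and sens.egger_intercept.pval > alpha
        het_ok = sens.q_ivw.pval > alpha and (
            sens.q_egger is None or sens.q_egger.pval > alpha
        )

        reason = ""
        if not p_gate < alpha:
            reason = "ivw_not_significant"
        elif not consistent:
            reason = "direction_inconsistent"
        elif not pleio_ok:
            reason = "pleiotropy"
        elif not het_ok:
            reason = "heterogeneity"
        verdict = side if reason == "" else "excluded"

        records.append(ScreenRecord(
            exposure_id=xid,
            ivw_pval=float(ivw_p[xid]),
            fdr_pval=float(fdr[xid]),
            ivw_or=float(np.exp(results["ivw"].estimate)),
            direction_consistent=consistent,
            pleiotropy_ok=pleio_ok,
            heterogeneity_ok=het_ok,
            reverse_ok=reverse_ok,
            verdict=verdict,
            reason=reason,
        ))
    return records


def two_step_mediation(
    beta1: MrResult,
    beta2: MrResult,
    total: MrResult,
    exposure_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
    meaningful: bool = False,
) -> MediationResult:
    """Product-of-coefficients mediation decomposition.

    me = beta1*beta2 with Sobel (no-covariance) SE; mediated proportion
    mp = 100*me/total with a first-order ratio delta SE; direct = total - me.
    The three legs come from non-overlapping samples, so covariances are
    taken as zero.
    """
    if total.estimate == 0:
        raise UndefinedProportionError(
            "mediated proportion undefined: total effect is zero"
        )
    b1, s1 = beta1.estimate, beta1.se
    b2, s2 = beta2.estimate, beta2.se
    t, st = total.estimate, total.se
    me = b1 * b2
    se_me = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    mp = 100.0 * me / t
    se_mp = 100.0 * float(np.sqrt(se_me**2 / t**2 + me**2 * st**2 / t**4))
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=b1, se1=s1, pval1=beta1.pval,
        beta2=b2, se2=s2, pval2=beta2.pval,
        total=t, se_total=st,
        me=me, se_me=se_me,
        mp_pct=mp, se_mp_pct=se_mp,
        direct=t - me,
        meaningful=meaningful,
    )


def default_meaningful(beta1: MrResult, beta2: MrResult, alpha: float) -> bool:
    """A pair is 'meaningful' when both path estimates are nominally significant."""
    return beta1.pval < alpha and beta2.pval < alpha


def assemble_pairs(
    screened: list[ScreenRecord],
    mediator_outcome: dict[str, MrResult],
    exposure_mediator: dict[tuple[str, str], MrResult],
    totals: dict[str, MrResult],
    outcome_id: str = "",
    alpha: float = 0.05,
    pair_beta2: dict[tuple[str, str], MrResult] | None = None,
    meaningful_rule=default_meaningful,
) -> list[MediationResult]:
    """Cross screened exposures with significant mediators into mediation pairs.

    A pair (X, M) is assembled when X passed the screen, M's marginal
    mediator-to-outcome IVW is significant at ``alpha``, and the X-to-M leg
    is significant at ``alpha``. ``pair_beta2`` optionally supplies a
    per-pair re-estimated beta2 (e.g. with X's instruments excluded), which
    then feeds the decomposition and the meaningful flag in place of the
    marginal result.
    """
    passed = [r.exposure_id for r in screened if r.verdict != "excluded"]
    sig_m = [m for m, res in mediator_outcome.items() if res.pval < alpha]
    out = []
    for xid in passed:
        for mid in sig_m:
            b1 = exposure_mediator.get((xid, mid))
            if b1 is None or not b1.pval < alpha:
                continue
            b2 = (pair_beta2 or {}).get((xid, mid), mediator_outcome[mid])
            out.append(two_step_mediation(
                b1, b2, totals[xid],
                exposure_id=xid, mediator_id=mid, outcome_id=outcome_id,
                meaningful=meaningful_rule(b1, b2, alpha),
            ))
    return out
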