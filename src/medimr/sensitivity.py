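"""Heterogeneity, pleiotropy and influence diagnostics for one pair.

- Cochran's Q: weighted residual sum of squares around the IVW fit
  (df = J-1) or the Egger fit (Q', df = J-2); chi-square under homogeneity.
- MR-Egger intercept test: a non-zero intercept signals average directional
  pleiotropy; the conventional call is pleiotropy present when p < 0.05.
- Leave-one-out: the IVW estimate recomputed J times, each time dropping
  one SNP, to expose single-variant influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientSnpsError
from .estimators import MrResult, ivw, mr_egger
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class QTest:
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class LooEntry:
    left_out_snp: str
    estimate: float
    se: float
    pval: float


@dataclass(frozen=True)
class SensitivityReport:
    """Diagnostics for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    q_ivw: QTest
    q_egger: QTest | None
    egger_intercept: MrResult | None
    pleiotropy_flag: bool | None
    loo: list[LooEntry]
    ivw_variant: str = "mre"


def cochran_q(h: HarmonizedSet, model: str = "ivw") -> QTest:
    """Cochran's Q around the IVW (df J-1) or Egger (df J-2) fit."""
    bx, _, by, sy = h.arrays()
    J = len(bx)
    w = 1.0 / sy**2
    if model == "ivw":
        if J < 2:
            raise InsufficientSnpsError("cochran_q[ivw]", 2, J)
        b = np.sum(w * bx * by) / np.sum(w * bx * bx)
        q = float(np.sum(w * (by - b * bx) ** 2))
        df = J - 1
    elif model == "egger":
        if J < 3:
            raise InsufficientSnpsError("cochran_q[egger]", 3, J)
        s = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = s * bx, s * by
        sw, swx = np.sum(w), np.sum(w * bxo)
        swxx, swy, swxy = np.sum(w * bxo**2), np.sum(w * byo), np.sum(w * bxo * byo)
        det = sw * swxx - swx**2
        a = (swxx * swy - swx * swxy) / det
        b = (sw * swxy - swx * swy) / det
        q = float(np.sum(w * (byo - a - b * bxo) ** 2))
        df = J - 2
    else:
        raise ValueError(f"unknown model {model!r}")
    return QTest(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(
    h: HarmonizedSet, alpha: float = 0.05
) -> tuple[MrResult, bool]:
    """Egger intercept with the conventional pleiotropy call (p < alpha)."""
    _, intercept = mr_egger(h)
    return intercept, bool(intercept.pval < alpha)


def leave_one_out(h: HarmonizedSet, ivw_variant: str = "mre") -> list[LooEntry]:
    """IVW re-estimated with each SNP left out in turn."""
    if h.n_snp < 3:
        raise InsufficientSnpsError("leave_one_out", 3, h.n_snp)
    entries = []
    for snp in h.table["snp_id"]:
        res = ivw(h.drop_snp(snp), variant=ivw_variant)
        entries.append(
            LooEntry(left_out_snp=snp, estimate=res.estimate, se=res.se, pval=res.pval)
        )
    return entries


def sensitivity_report(
    h: HarmonizedSet, alpha: float = 0.05, ivw_variant: str = "mre"
) -> SensitivityReport:
    """Full diagnostic bundle; Egger parts are None when J < 3."""
    q_ivw = cochran_q(h, "ivw")
    if h.n_snp >= 3:
        q_egger = cochran_q(h, "egger")
        intercept, flag = egger_intercept_test(h, alpha)
        loo = leave_one_out(h, ivw_variant)
    else:
        q_egger, intercept, flag, loo = None, None, None, []
    return SensitivityReport(
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        q_ivw=q_ivw,
        q_egger=q_egger,
        egger_intercept=intercept,
        pleiotropy_flag=flag,
        loo=loo,
        ivw_variant=ivw_variant,
    )
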