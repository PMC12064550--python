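"""Monte-Carlo calibration and parameter-recovery studies on generator data.

These drive the package's self-checks: under the null (no pleiotropy, no
heterogeneity beyond sampling noise) the Egger intercept test should
reject at its nominal rate and Cochran's Q should average its degrees of
freedom; under a known mediation truth the pipeline should recover the
total effect, its CI coverage, and the mediated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import MedimrError
from .estimators import ivw
from .instruments import select_by_pvalue
from .pipeline import MrConfig, prepare_instruments
from .sensitivity import cochran_q, egger_intercept_test
from .simulate import SimTruth, simulate_triplet

_SEED_MOD = 2**31


def _rep_seed(seed: int, rep: int) -> int:
    return (seed * 1_000_003 + rep) % _SEED_MOD


@dataclass(frozen=True)
class CalibrationResult:
    n_reps: int
    egger_rejection_rate: float
    mean_q: float
    mean_q_df: float
    alpha: float = 0.05


def null_calibration(
    n_reps: int = 1000,
    J: int = 20,
    n: int = 20_000,
    seed: int = 0,
    alpha: float = 0.05,
    truth: SimTruth | None = None,
) -> CalibrationResult:
    """Egger-intercept type-I rate and mean Cochran's Q under the null.

    The default experiment is the global null — no pleiotropy and no causal
    effect — which isolates the intercept test's own size. With a causal
    effect present, finite instrument strength makes Egger regression
    mildly anti-conservative (exposure-measurement noise dilutes the slope
    and leaks into the intercept); pass a custom ``truth`` to measure that
    regime.

    The experiment diagnoses a J-instrument harmonized set: all J index
    SNPs are instruments by construction, so the selection screen is
    disabled (it would only shrink the degrees of freedom through
    selection noise, which is not what is being calibrated).
    """
    base = truth or SimTruth(
        theta_direct=0.0, b1=0.0, b2=0.0, J=J, j_med=0, n_exp=n, n_med=n, n_out=n
    )
    cfg = MrConfig(n_boot=0, p_max=1.0, f_min=0.0)
    rej = 0
    qs, dfs = [], []
    for rep in range(n_reps):
        trip = simulate_triplet(replace(base, seed=_rep_seed(seed, rep)))
        h = prepare_instruments(trip.exposure, trip.outcome, ld=trip.ld, config=cfg)
        q = cochran_q(h, "ivw")
        qs.append(q.q)
        dfs.append(q.df)
        _, flag = egger_intercept_test(h, alpha)
        rej += flag
    return CalibrationResult(
        n_reps=n_reps,
        egger_rejection_rate=rej / n_reps,
        mean_q=float(np.mean(qs)),
        mean_q_df=float(np.mean(dfs)),
        alpha=alpha,
    )


@dataclass(frozen=True)
class RecoveryResult:
    n_reps: int
    true_total: float
    true_mp_pct: float
    mean_total: float
    coverage_pct: float
    mean_mp_pct: float


def recovery_study(
    n_reps: int = 500,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> RecoveryResult:
    """Total-effect and mediated-proportion recovery under a known truth.

    Per replicate: simulate a triplet, run the instrument pipeline and IVW
    on each of the three legs (the mediator-to-outcome leg excludes the
    exposure's instruments), and record the total-effect estimate, whether
    its 95% CI covers the truth, and the estimated mediated proportion.
    """
    base = truth or SimTruth()
    cfg = MrConfig(n_boot=0)
    totals, covered, mps = [], 0, []
    n_ok = 0
    for rep in range(n_reps):
        t = replace(base, seed=_rep_seed(seed, rep))
        trip = simulate_triplet(t)
        try:
            h_xy = prepare_instruments(trip.exposure, trip.outcome, ld=trip.ld, config=cfg)
            total = ivw(h_xy)
            h_xm = prepare_instruments(trip.exposure, trip.mediator, ld=trip.ld, config=cfg)
            b1 = ivw(h_xm)
            x_instr = set(select_by_pvalue(trip.exposure, cfg.p_max).table["snp_id"])
            h_my = prepare_instruments(
                trip.mediator, trip.outcome, ld=trip.ld, config=cfg,
                exclude_snps=x_instr,
            )
            b2 = ivw(h_my)
        except MedimrError:  # pragma: no cover - not hit at these settings
            continue
        n_ok += 1
        totals.append(total.estimate)
        covered += total.ci_low <= t.theta_total <= total.ci_high
        mps.append(100.0 * b1.estimate * b2.estimate / total.estimate)
    return RecoveryResult(
        n_reps=n_ok,
        true_total=base.theta_total,
        true_mp_pct=base.mediated_proportion_pct,
        mean_total=float(np.mean(totals)),
        coverage_pct=100.0 * covered / n_ok,
        mean_mp_pct=float(np.mean(mps)),
    )
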