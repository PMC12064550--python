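"""Causal-effect estimators on a harmonized exposure-outcome set.

Five methods are provided, each combining per-SNP Wald ratios
(beta_out / beta_exp) under different validity assumptions:

- ``ivw``: inverse-variance weighted regression of beta_out on beta_exp
  through the origin, weights 1/se_out^2. The multiplicative
  random-effects variant (default) inflates the SE by
  max(1, sqrt(Q/(J-1))) to absorb heterogeneity; the point estimate is
  identical to fixed effects.
- ``mr_egger``: the same weighted regression with a free intercept, after
  orienting rows so every beta_exp >= 0. The slope is a
  pleiotropy-adjusted causal estimate; the intercept estimates average
  directional pleiotropy. Inference uses t with J-2 df.
- ``weighted_median``: the ratio at cumulative weight 0.5, consistent when
  valid instruments carry at least half the weight.
- ``simple_mode`` / ``weighted_mode``: the peak of a kernel-smoothed
  density of ratios, consistent when the largest cluster of ratios is
  valid. Bootstrap standard errors.

All estimates are on the outcome scale per unit exposure (log odds ratio
for a binary outcome, in which case the OR fields are filled in).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InsufficientSnpsError, ValidationError
from .harmonize import HarmonizedSet

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode", "wald")

MODE_GRID_POINTS = 512
MODE_GRID_SPAN_BW = 3.0


@dataclass(frozen=True)
class MrResult:
    """One estimator's causal estimate with 95% CI and p-value."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_point: float | None = None
    or_low: float | None = None
    or_high: float | None = None

    def with_or(self) -> "MrResult":
        """Fill exp-transformed fields (for a binary outcome on the log-OR scale)."""
        return replace(
            self,
            or_point=float(np.exp(self.estimate)),
            or_low=float(np.exp(self.ci_low)),
            or_high=float(np.exp(self.ci_high)),
        )


def _finish(method, estimate, se, pval, n_snp, crit=None) -> MrResult:
    crit = 1.959963984540054 if crit is None else crit  # normal 97.5% point
    return MrResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        pval=float(pval),
        n_snp=int(n_snp),
    )


def _normal_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))


def wald_ratio(beta_exp, se_exp, beta_out, se_out) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order delta SE."""
    if beta_exp == 0:
        raise ValidationError("wald_ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ratios_and_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and inverse-variance weights 1/se_ratio^2."""
    bx, _, by, sy = h.arrays()
    if np.any(bx == 0):
        raise ValidationError("zero exposure beta in harmonized set")
    r = by / bx
    se_r = sy / np.abs(bx)
    return r, 1.0 / se_r**2


def ivw(h: HarmonizedSet, variant: str = "mre") -> MrResult:
    """Inverse-variance weighted estimate.

    ``fixed`` uses the analytic weighted-least-squares SE (valid with one or
    more SNPs); ``mre`` (multiplicative random effects, the default) needs
    J >= 2 and scales the SE by max(1, sqrt(Q/(J-1))), never reporting less
    than the fixed-effects SE.
    """
    if variant not in ("fixed", "mre"):
        raise ValidationError(f"unknown IVW variant {variant!r}")
    bx, _, by, sy = h.arrays()
    J = len(bx)
    needed = 1 if variant == "fixed" else 2
    if J < needed:
        raise InsufficientSnpsError(f"ivw-{variant}", needed, J)
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    b = np.sum(w * bx * by) / sxx
    se = np.sqrt(1.0 / sxx)
    if variant == "mre":
        q = float(np.sum(w * (by - b * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (J - 1)))
    return _finish("ivw", b, se, _normal_p(b / se), J)


def _orient(bx, by):
    s = np.where(bx < 0, -1.0, 1.0)
    return s * bx, s * by


def mr_egger(h: HarmonizedSet) -> tuple[MrResult, MrResult]:
    """MR-Egger regression: returns (slope result, intercept result).

    Rows are oriented so all exposure betas are non-negative, then beta_out
    is regressed on beta_exp with an intercept, weights 1/se_out^2. SEs use
    the weighted-least-squares residual variance Q'/(J-2) (unfloored, as in
    the standard lm-based Egger regression, so the intercept test keeps its
    nominal size); p-values use t with J-2 df.
    """
    bx, _, by, sy = h.arrays()
    J = len(bx)
    if J < 3:
        raise InsufficientSnpsError("mr_egger", 3, J)
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValidationError("degenerate design in MR-Egger (constant beta_exp)")
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = by - a - b * bx
    q = float(np.sum(w * resid**2))
    infl = np.sqrt(q / (J - 2))
    se_a = np.sqrt(swxx / det) * infl
    se_b = np.sqrt(sw / det) * infl
    tcrit = float(stats.t.ppf(0.975, J - 2))

    def _t_p(est, se):
        if se == 0:
            return 1.0 if est == 0 else np.nextafter(0, 1)
        return float(2.0 * stats.t.sf(abs(est / se), J - 2))

    p_b = _t_p(b, se_b)
    p_a = _t_p(a, se_a)
    slope = _finish("egger", b, se_b, max(p_b, np.nextafter(0, 1)), J, crit=tcrit)
    intercept = _finish(
        "egger_intercept", a, se_a, max(p_a, np.nextafter(0, 1)), J, crit=tcrit
    )
    return slope, intercept


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w  # cumulative midpoint mass
    return float(np.interp(0.5, p, r))


def _bootstrap_se(h: HarmonizedSet, point_fn, n_boot: int, seed) -> float:
    """Parametric bootstrap: resample betas from N(observed, se), recompute."""
    if n_boot <= 0:
        return 0.0
    bx, sx, by, sy = h.arrays()
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxi = rng.normal(bx, sx)
        byi = rng.normal(by, sy)
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        est[i] = point_fn(byi / bxi, bxi, sy)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median estimate with parametric-bootstrap SE."""
    r, w = ratios_and_weights(h)
    J = len(r)
    if J < 3:
        raise InsufficientSnpsError("weighted_median", 3, J)
    b = _weighted_median_point(r, w)

    def point(ratios, bx, sy):
        return _weighted_median_point(ratios, (np.abs(bx) / sy) ** 2)

    se = _bootstrap_se(h, point, n_boot, seed)
    pval = _normal_p(b / se) if se > 0 else 1.0
    return _finish("weighted_median", b, se, pval, J)


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    sd = float(np.std(r, ddof=1))
    mad = float(np.median(np.abs(r - np.median(r)))) / 0.6744897501960817
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * len(r) ** (-1.0 / 5.0)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    h_bw = _mode_bandwidth(r, phi)
    if h_bw <= 0 or np.ptp(r) == 0:
        return float(r[0]) if np.ptp(r) == 0 else float(np.median(r))
    grid = np.linspace(r.min() - MODE_GRID_SPAN_BW * h_bw,
                       r.max() + MODE_GRID_SPAN_BW * h_bw, MODE_GRID_POINTS)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h_bw) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Mode-based estimate (simple or inverse-variance weighted kernel)."""
    r, w_iv = ratios_and_weights(h)
    J = len(r)
    if J < 3:
        raise InsufficientSnpsError("mode_estimate", 3, J)
    w = w_iv if weighted else np.ones(J)
    b = _mode_point(r, w / w.sum(), phi)

    def point(ratios, bx, sy):
        wi = (np.abs(bx) / sy) ** 2 if weighted else np.ones(len(ratios))
        return _mode_point(ratios, wi / wi.sum(), phi)

    se = _bootstrap_se(h, point, n_boot, seed)
    pval = _normal_p(b / se) if se > 0 else 1.0
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, b, se, pval, J)


def all_methods(
    h: HarmonizedSet,
    ivw_variant: str = "mre",
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int = 0,
    binary_outcome: bool = False,
) -> dict[str, MrResult]:
    """Run the five estimators, keyed by method name.

    With a single SNP only the Wald ratio is computable and is reported
    under ``ivw`` (to which fixed-effects IVW reduces at J = 1).
    """
    J = h.n_snp
    results: dict[str, MrResult] = {}
    if J == 1:
        results["ivw"] = ivw(h, variant="fixed")
    else:
        variant = ivw_variant if J >= 2 else "fixed"
        results["ivw"] = ivw(h, variant=variant)
    if J >= 3:
        slope, intercept = mr_egger(h)
        results["egger"] = slope
        results["egger_intercept"] = intercept
        results["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
        results["simple_mode"] = mode_estimate(
            h, weighted=False, phi=phi, n_boot=n_boot, seed=seed + 1
        )
        results["weighted_mode"] = mode_estimate(
            h, weighted=True, phi=phi, n_boot=n_boot, seed=seed + 2
        )
    if binary_outcome:
        results = {k: v.with_or() for k, v in results.items()}
    return results
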