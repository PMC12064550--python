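"""Synthetic GWAS summary statistics from a known causal mediation model.

The generator embodies a three-node structure: J index SNPs act on the
exposure X with effects gamma_j; X acts on the mediator M with effect b1
and on the outcome Y directly with effect theta_direct; M acts on Y with
effect b2, so the total X-to-Y effect is theta_total = theta_direct +
b1*b2. A further ``j_med`` SNPs act directly on M (and hence on Y through
b2); without them the mediator has no valid instruments of its own. Each
SNP's observed beta adds sampling noise with the analytic standard error
of a standardized-trait GWAS, se = 1/sqrt(2*n*maf*(1-maf)), so noise is
calibrated to sample size and allele frequency. Optional horizontal
pleiotropy adds per-SNP direct effects on Y (balanced or directional),
and LD blocks append correlated satellite SNPs whose effects attenuate
by r (the correlation, sqrt(r2)), matching the expectation of an
LD-tagged marginal effect.

All three tables share one snp_id universe, and everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .instruments import LdMatrix
from .sumstats import SumStats, from_frame

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Pleiotropy:
    """Per-SNP direct-on-outcome effects alpha_j.

    ``none``: alpha = 0; ``balanced``: alpha ~ N(0, sd^2);
    ``directional``: alpha ~ N(mean, sd^2).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(n)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, n)
        if self.kind == "directional":
            return rng.normal(self.mean, self.sd, n)
        raise ValidationError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one simulated X -> M -> Y study.

    ``theta_total`` is derived: theta_direct + b1*b2. ``J`` SNPs instrument
    the exposure, ``j_med`` SNPs instrument the mediator directly.
    ``gamma_sd`` is the SD of true per-SNP exposure effects; draws are
    floored in magnitude at sqrt(f_target)*se, conditioning each index
    SNP to be a genuine, discoverable instrument. The default f_target of
    33 is the instrument screen's own F (z for p = 5e-5 two-sided,
    squared, about 16.5) plus 95% one-sided discovery power
    ((4.06 + 1.645)^2), so instruments survive the screen rather than
    straddling it.
    """

    theta_direct: float = 0.08
    b1: float = 0.3
    b2: float = 0.4
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    J: int = 100
    j_med: int | None = None
    maf_range: tuple[float, float] = (0.05, 0.45)
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    pleiotropy_m: Pleiotropy = field(default_factory=Pleiotropy)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    gamma_sd: float = 0.05
    f_target: float = 33.0
    sampling_noise: bool = True
    outcome_binary: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ValidationError("sample sizes must be >= 100")
        if self.J < 3:
            raise ValidationError("J must be >= 3")
        if self.j_med is not None and self.j_med < 0:
            raise ValidationError("j_med must be >= 0")
        for size, r2 in self.ld_blocks:
            if size < 2 or not (0 <= r2 <= 1):
                raise ValidationError("ld_blocks entries must be (size >= 2, r2 in [0,1])")
        if len(self.ld_blocks) > self.J:
            raise ValidationError("more LD blocks than exposure index SNPs")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.b1 * self.b2

    @property
    def n_mediator_snps(self) -> int:
        return self.J if self.j_med is None else self.j_med

    @property
    def mediated_proportion_pct(self) -> float:
        return 100.0 * self.b1 * self.b2 / self.theta_total


@dataclass
class SimulatedTriplet:
    exposure: SumStats
    mediator: SumStats
    outcome: SumStats
    ld: LdMatrix
    snp_truth: pd.DataFrame  # per-SNP true effects, for recovery tests
    truth: SimTruth


def _analytic_se(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _floored(draws: np.ndarray, se: np.ndarray, f_target: float) -> np.ndarray:
    """Enforce |gamma| >= sqrt(f_target)*se, keeping each draw's sign."""
    floor = np.sqrt(f_target) * se
    sign = np.where(draws < 0, -1.0, 1.0)
    return sign * np.maximum(np.abs(draws), floor)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta) / se
    return np.clip(2.0 * stats.norm.sf(z), _P_FLOOR, 1.0)


def simulate_triplet(truth: SimTruth) -> SimulatedTriplet:
    """Generate (exposure, mediator, outcome) SumStats plus an LdMatrix.

    Fully deterministic in ``truth.seed``. With ``sampling_noise=False``
    observed betas equal the true effects exactly (standard errors stay at
    their analytic values), so every per-SNP outcome/exposure ratio on the
    exposure's instruments equals theta_total.
    """
    rng = np.random.default_rng(truth.seed)
    Jx, Jm = truth.J, truth.n_mediator_snps

    ids = [f"rs{i + 1}" for i in range(Jx + Jm)]
    kinds = ["x_index"] * Jx + ["m_index"] * Jm
    chroms = [str(1 + i % 22) for i in range(Jx + Jm)]
    pos = np.array(
        [1_000_000 + (i // 22) * 25_000_000 for i in range(Jx + Jm)], dtype=np.int64
    )
    maf = rng.uniform(*truth.maf_range, Jx + Jm)

    se_exp = _analytic_se(truth.n_exp, maf)
    se_med = _analytic_se(truth.n_med, maf)
    se_out = _analytic_se(truth.n_out, maf)

    gamma_x = _floored(rng.normal(0, truth.gamma_sd, Jx), se_exp[:Jx], truth.f_target)
    gamma_m = _floored(rng.normal(0, truth.gamma_sd, Jm), se_med[Jx:], truth.f_target)
    # pleiotropy is defined relative to the exposure-increasing allele (the
    # orientation MR-Egger estimates its intercept in); tying the sign to
    # gamma keeps "directional" directional after re-orientation, and leaves
    # the symmetric "balanced" distribution unchanged
    gx_sign = np.where(gamma_x < 0, -1.0, 1.0)
    alpha_y = truth.pleiotropy.draw(rng, Jx) * gx_sign
    alpha_m = truth.pleiotropy_m.draw(rng, Jx) * gx_sign

    true_exp = np.concatenate([gamma_x, np.zeros(Jm)])
    true_med = np.concatenate([truth.b1 * gamma_x + alpha_m, gamma_m])
    true_out = np.concatenate(
        [truth.theta_total * gamma_x + alpha_y, truth.b2 * gamma_m]
    )

    # LD blocks: block i hangs k-1 satellite SNPs off exposure index SNP i
    sat_rows = []
    blocks: list[tuple[list[int], float]] = []  # (matrix indices, r2)
    next_idx = Jx + Jm
    for bi, (size, r2) in enumerate(truth.ld_blocks):
        r = np.sqrt(r2)
        members = [bi]
        for k in range(size - 1):
            sat_rows.append({
                "id": f"rs{bi + 1}t{k + 1}",
                "kind": "x_satellite",
                "chrom": chroms[bi],
                "pos": int(pos[bi]) + (k + 1) * 1000,
                "maf": maf[bi],
                "true_exp": r * true_exp[bi],
                "true_med": r * true_med[bi],
                "true_out": r * true_out[bi],
            })
            members.append(next_idx)
            next_idx += 1
        blocks.append((members, r2))

    if sat_rows:
        sat = pd.DataFrame(sat_rows)
        ids = ids + sat["id"].tolist()
        kinds = kinds + sat["kind"].tolist()
        chroms = chroms + sat["chrom"].tolist()
        pos = np.concatenate([pos, sat["pos"].to_numpy(np.int64)])
        maf = np.concatenate([maf, sat["maf"].to_numpy(float)])
        true_exp = np.concatenate([true_exp, sat["true_exp"].to_numpy(float)])
        true_med = np.concatenate([true_med, sat["true_med"].to_numpy(float)])
        true_out = np.concatenate([true_out, sat["true_out"].to_numpy(float)])
        se_exp = _analytic_se(truth.n_exp, maf)
        se_med = _analytic_se(truth.n_med, maf)
        se_out = _analytic_se(truth.n_out, maf)

    n_tot = len(ids)
    if truth.sampling_noise:
        obs_exp = true_exp + rng.normal(0, se_exp)
        obs_med = true_med + rng.normal(0, se_med)
        obs_out = true_out + rng.normal(0, se_out)
    else:
        obs_exp, obs_med, obs_out = true_exp, true_med, true_out

    # alleles: effect A, other G everywhere (non-palindromic by construction)
    def table(beta, se, n):
        return pd.DataFrame({
            "snp_id": ids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": float(n),
        })

    exposure = from_frame(table(obs_exp, se_exp, truth.n_exp), "sim_exposure")
    mediator = from_frame(table(obs_med, se_med, truth.n_med), "sim_mediator")
    outcome = from_frame(
        table(obs_out, se_out, truth.n_out),
        "sim_outcome",
        "binary" if truth.outcome_binary else "continuous",
    )

    r2_mat = np.eye(n_tot)
    for members, r2 in blocks:
        for i in members:
            for j in members:
                if i != j:
                    r2_mat[i, j] = r2
    ld = LdMatrix(ids, r2_mat)

    snp_truth = pd.DataFrame({
        "snp_id": ids,
        "kind": kinds,
        "maf": maf,
        "true_exp": true_exp,
        "true_med": true_med,
        "true_out": true_out,
    })
    return SimulatedTriplet(exposure, mediator, outcome, ld, snp_truth, truth)


def truth_report(truth: SimTruth, path=None) -> str:
    """Serialize every true parameter (including derived ones) as YAML text."""
    rec = asdict(truth)
    rec["maf_range"] = list(truth.maf_range)
    rec["ld_blocks"] = [list(b) for b in truth.ld_blocks]
    rec["theta_total"] = truth.theta_total
    rec["mediated_proportion_pct"] = truth.mediated_proportion_pct
    text = yaml.safe_dump(rec, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_truth_report(source) -> SimTruth:
    """Inverse of :func:`truth_report` (accepts a YAML string or a path)."""
    text = Path(source).read_text() if isinstance(source, (Path,)) else str(source)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    rec = yaml.safe_load(text)
    theta_total = rec.pop("theta_total", None)
    rec.pop("mediated_proportion_pct", None)
    rec["maf_range"] = tuple(rec["maf_range"])
    rec["ld_blocks"] = tuple(tuple(b) for b in rec["ld_blocks"])
    rec["pleiotropy"] = Pleiotropy(**rec["pleiotropy"])
    rec["pleiotropy_m"] = Pleiotropy(**rec["pleiotropy_m"])
    truth = SimTruth(**rec)
    if theta_total is not None and abs(theta_total - truth.theta_total) > 1e-9:
        raise ValidationError("truth report violates theta_total = theta_direct + b1*b2")
    return truth
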