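"""Instrument selection: p-value screen, greedy LD clumping, instrument strength.

Instruments are SNPs strongly associated with the exposure (p <= 5e-5 by
default), pruned to quasi-independence by greedy clumping (r2 < 0.01 within
a 10,000 kb window by default) and required to be individually strong
(F > 10). The per-SNP F statistic is the squared Wald z, (beta/se)^2,
which needs neither sample size nor allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError, ValidationError
from .harmonize import HarmonizedSet
from .sumstats import SumStats

DEFAULT_P_MAX = 5e-5
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_KB = 10_000
DEFAULT_F_MIN = 10.0


@dataclass
class LdMatrix:
    """Pairwise squared correlations between SNPs (symmetric, unit diagonal)."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValidationError(f"LdMatrix shape {self.r2.shape} does not match {n} SNPs")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LdMatrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LdMatrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LdMatrix values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, path) -> "LdMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(float))

    def write(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )
        return path


@dataclass
class ClumpAudit:
    """Per-candidate disposition after clumping."""

    disposition: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def retained(self) -> list[str]:
        return [s for s, d in self.disposition.items() if d in ("retained", "no_ld_info")]


def select_by_pvalue(s: SumStats, p_max: float = DEFAULT_P_MAX) -> SumStats:
    """Subset to SNPs with pval <= p_max (boundary inclusive), order preserved."""
    return s.subset((s.table["pval"] <= p_max).to_numpy())


def clump(
    s: SumStats,
    ld: LdMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_KB,
) -> tuple[SumStats, ClumpAudit]:
    """Greedy LD clumping.

    Candidates are visited in order of ascending p-value (ties broken by
    snp_id); each retained SNP removes every not-yet-visited SNP on the same
    chromosome within ``window_kb`` that has r2 >= ``r2_max`` against it.
    SNPs missing from ``ld`` are retained with a ``no_ld_info`` flag and a
    warning rather than silently dropped.
    """
    audit = ClumpAudit()
    t = s.table
    order = t.assign(_row=np.arange(len(t))).sort_values(
        ["pval", "snp_id"], kind="stable"
    )
    removed: set[str] = set()
    window_bp = int(window_kb) * 1000

    entries = list(order.itertuples(index=False))
    for i, rec in enumerate(entries):
        if rec.snp_id in removed:
            continue
        if rec.snp_id not in ld:
            audit.disposition[rec.snp_id] = "no_ld_info"
            audit.warnings.append(f"{rec.snp_id}: no LD information, retained")
            continue
        audit.disposition[rec.snp_id] = "retained"
        for other in entries[i + 1:]:
            if other.snp_id in removed or other.snp_id not in ld:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(int(other.pos) - int(rec.pos)) > window_bp:
                continue
            if ld.lookup(rec.snp_id, other.snp_id) >= r2_max:
                removed.add(other.snp_id)
                audit.disposition[other.snp_id] = f"clumped_to:{rec.snp_id}"

    keep = ~t["snp_id"].isin(removed)
    return s.subset(keep.to_numpy()), audit


def f_statistic(beta_exp: float, se_exp: float) -> float:
    """Per-SNP instrument strength F = (beta/se)^2, the squared Wald z."""
    if se_exp <= 0:
        raise ValidationError(f"se_exp must be positive, got {se_exp}")
    return (beta_exp / se_exp) ** 2


def filter_weak(h: HarmonizedSet, f_min: float = DEFAULT_F_MIN) -> HarmonizedSet:
    """Drop weak instruments, keeping rows with F strictly above ``f_min``."""
    if h.n_snp == 0:
        raise NoInstrumentsError(h.exposure_id, h.outcome_id, stage="filter_weak")
    keep = h.table["f_stat"] > f_min
    if not keep.any():
        raise NoInstrumentsError(h.exposure_id, h.outcome_id, stage="filter_weak")
    sub = h.table.loc[keep].reset_index(drop=True)
    audit = dict(h.audit)
    for snp in h.table.loc[~keep, "snp_id"]:
        audit[snp] = "weak_f"
    return HarmonizedSet(
        h.exposure_id, h.outcome_id, sub,
        n_dropped_palindromic=h.n_dropped_palindromic,
        n_dropped_unmatched=h.n_dropped_unmatched,
        n_dropped_irreconcilable=h.n_dropped_irreconcilable,
        audit=audit,
    )
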