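"""Harmonization of exposure and outcome summary statistics.

Joins the two tables on shared SNPs and aligns the outcome effect to the
exposure's effect allele: if the outcome reports the same allele pair with
the roles swapped, the outcome beta's sign is flipped. Palindromic SNPs
(A/T or C/G) are excluded unconditionally because their strand cannot be
resolved from alleles alone. Optionally, an exposure SNP missing from the
outcome can be replaced by a proxy SNP in high LD (r2 >= 0.8 by default)
through a precomputed proxy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError, ValidationError
from .sumstats import SumStats, VALID_ALLELES

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

HARMONIZED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "pval_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out",
    "f_stat", "provenance",
]


def is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_PAIRS


@dataclass
class ProxyTable:
    """Precomputed LD proxies: rows of target/proxy SNP with r2 and the
    allele correspondence between the proxy's and the target's alleles."""

    table: pd.DataFrame

    REQUIRED = [
        "target_snp", "proxy_snp", "r2",
        "proxy_effect_allele", "target_effect_allele",
        "proxy_other_allele", "target_other_allele",
    ]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"ProxyTable missing columns: {missing}")
        r2 = pd.to_numeric(self.table["r2"], errors="coerce")
        if r2.isna().any() or (r2 < 0).any() or (r2 > 1).any():
            raise ValidationError("ProxyTable r2 must lie in [0, 1]")
        self.table = self.table.assign(r2=r2)
        for col in self.REQUIRED[3:]:
            vals = self.table[col].astype(str).str.upper()
            if not vals.isin(VALID_ALLELES).all():
                raise ValidationError(f"ProxyTable column {col} has non-ACGT alleles")
            self.table[col] = vals

    @classmethod
    def read(cls, path) -> "ProxyTable":
        return cls(pd.read_csv(Path(path), sep="\t"))

    def best_proxy(self, target_snp: str, r2_min: float) -> pd.Series | None:
        rows = self.table[
            (self.table["target_snp"] == target_snp) & (self.table["r2"] >= r2_min)
        ]
        if rows.empty:
            return None
        return rows.sort_values(["r2", "proxy_snp"], ascending=[False, True]).iloc[0]


@dataclass
class HarmonizedSet:
    """Estimator-ready exposure/outcome pairs sharing an effect allele per row.

    ``provenance`` per row is ``direct`` (alleles already aligned),
    ``flipped`` (outcome beta sign-flipped) or ``proxy`` (substituted SNP).
    ``f_stat`` is the per-SNP instrument strength (beta_exp/se_exp)^2.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_irreconcilable: int = 0
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"HarmonizedSet table missing columns: {missing}")
        if len(self.table):
            if not (self.table["se_exp"] > 0).all() or not (self.table["se_out"] > 0).all():
                raise ValidationError("HarmonizedSet requires positive standard errors")
            pal = [
                is_palindromic(a, b)
                for a, b in zip(self.table["effect_allele"], self.table["other_allele"])
            ]
            if any(pal):
                raise ValidationError("palindromic SNP present in HarmonizedSet")

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (
            t["beta_exp"].to_numpy(float),
            t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float),
            t["se_out"].to_numpy(float),
        )

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        sub = self.table[self.table["snp_id"] != snp_id].reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id, sub)

    def subset(self, snp_ids) -> "HarmonizedSet":
        sub = self.table[self.table["snp_id"].isin(list(snp_ids))].reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id, sub)


def _align_row(exp_ea, exp_oa, out_ea, out_oa, beta_out):
    """Return (aligned beta_out, provenance) or None if irreconcilable."""
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return beta_out, "direct"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return -beta_out, "flipped"
    return None


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    proxies: ProxyTable | None = None,
    proxy_r2_min: float = 0.8,
) -> HarmonizedSet:
    """Join exposure and outcome on shared SNPs with aligned effect alleles.

    Palindromic exposure SNPs are excluded before matching. An exposure SNP
    absent from the outcome is rescued through ``proxies`` when a proxy with
    r2 >= ``proxy_r2_min`` exists in the outcome; a direct match always wins
    over a proxy. Raises :class:`NoInstrumentsError` if nothing remains.
    """
    out_idx = outcome.table.set_index("snp_id")
    rows = []
    audit: dict[str, str] = {}
    n_pal = n_unmatched = n_irrec = 0

    for rec in exposure.table.itertuples(index=False):
        if is_palindromic(rec.effect_allele, rec.other_allele):
            n_pal += 1
            audit[rec.snp_id] = "palindromic"
            continue

        aligned = None
        provenance = None
        if rec.snp_id in out_idx.index:
            o = out_idx.loc[rec.snp_id]
            res = _align_row(
                rec.effect_allele, rec.other_allele,
                o["effect_allele"], o["other_allele"], float(o["beta"]),
            )
            if res is None:
                n_irrec += 1
                audit[rec.snp_id] = "irreconcilable_alleles"
                continue
            aligned, provenance = res
            se_out, pval_out = float(o["se"]), float(o["pval"])
        elif proxies is not None:
            p = proxies.best_proxy(rec.snp_id, proxy_r2_min)
            if p is not None and p["proxy_snp"] in out_idx.index:
                o = out_idx.loc[p["proxy_snp"]]
                # translate the outcome's alleles from proxy space to target space
                corr = {
                    p["proxy_effect_allele"]: p["target_effect_allele"],
                    p["proxy_other_allele"]: p["target_other_allele"],
                }
                oea, ooa = corr.get(o["effect_allele"]), corr.get(o["other_allele"])
                if oea is None or ooa is None:
                    n_irrec += 1
                    audit[rec.snp_id] = "proxy_allele_mismatch"
                    continue
                res = _align_row(
                    rec.effect_allele, rec.other_allele, oea, ooa, float(o["beta"])
                )
                if res is None:
                    n_irrec += 1
                    audit[rec.snp_id] = "proxy_allele_mismatch"
                    continue
                aligned, _ = res
                provenance = "proxy"
                se_out, pval_out = float(o["se"]), float(o["pval"])

        if aligned is None and provenance is None:
            n_unmatched += 1
            audit[rec.snp_id] = "absent_from_outcome"
            continue

        audit[rec.snp_id] = provenance
        rows.append({
            "snp_id": rec.snp_id,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "effect_allele": rec.effect_allele,
            "other_allele": rec.other_allele,
            "beta_exp": float(rec.beta),
            "se_exp": float(rec.se),
            "pval_exp": float(rec.pval),
            "eaf_exp": float(rec.eaf) if not pd.isna(rec.eaf) else np.nan,
            "beta_out": aligned,
            "se_out": se_out,
            "pval_out": pval_out,
            "f_stat": (float(rec.beta) / float(rec.se)) ** 2,
            "provenance": provenance,
        })

    if not rows:
        raise NoInstrumentsError(exposure.trait_id, outcome.trait_id, stage="harmonize")
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(
        exposure.trait_id, outcome.trait_id, table,
        n_dropped_palindromic=n_pal,
        n_dropped_unmatched=n_unmatched,
        n_dropped_irreconcilable=n_irrec,
        audit=audit,
    )
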