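"""GWAS summary-statistics tables: reading, validation, writing.

The on-disk dialect is tab-separated text with the canonical header

    snp_id chrom pos effect_allele other_allele eaf beta se pval n

one row per SNP, ``NA`` for missing optional values (``eaf``, ``n``).
Positions are 1-based base pairs. For binary traits ``beta`` is a
log odds ratio; for continuous traits it is in SD units per
effect-allele copy. Foreign headers (FinnGen, IEU OpenGWAS exports and
the like) are ingested through a ``column_map``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
]
OPTIONAL_COLUMNS = ["eaf", "n"]
VALID_ALLELES = frozenset({"A", "C", "G", "T"})
TRAIT_TYPES = ("continuous", "binary")

# numeric fields round-trip through text at this precision
_FLOAT_FMT = "%.10g"


@dataclass
class ReadReport:
    """Structured account of what validation did to an input table."""

    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    n_duplicates_resolved: int = 0
    drop_reasons: Counter = field(default_factory=Counter)

    def __str__(self) -> str:
        parts = [f"{self.n_valid}/{self.n_read} rows valid"]
        if self.n_dropped:
            reasons = ", ".join(f"{k}={v}" for k, v in sorted(self.drop_reasons.items()))
            parts.append(f"dropped {self.n_dropped} ({reasons})")
        if self.n_duplicates_resolved:
            parts.append(f"resolved {self.n_duplicates_resolved} duplicate snp_id")
        return "; ".join(parts)


@dataclass
class SumStats:
    """One trait's per-SNP association table.

    ``table`` holds the canonical columns; every row satisfies the record
    invariants (se > 0, pval in (0, 1], single-nucleotide alleles,
    effect_allele != other_allele, unique snp_id).
    """

    trait_id: str
    trait_type: str
    table: pd.DataFrame
    read_report: ReadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValidationError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"SumStats table missing columns: {missing}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def subset(self, mask) -> "SumStats":
        """New SumStats restricted to ``mask`` (boolean array or snp_id list)."""
        if isinstance(mask, (list, set, frozenset, pd.Index)):
            keep = self.table["snp_id"].isin(list(mask))
        else:
            keep = np.asarray(mask, dtype=bool)
        sub = self.table.loc[keep].reset_index(drop=True)
        return SumStats(self.trait_id, self.trait_type, sub)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    report = ReadReport(n_read=len(df))
    df = df.copy()

    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]

    df["snp_id"] = df["snp_id"].astype(str).str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    checks = {
        "missing_value": df[["snp_id", "pos", "beta", "se", "pval"]].notna().all(axis=1)
        & (df["snp_id"] != "")
        & (df["snp_id"].str.lower() != "nan"),
        "bad_allele": df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES),
        "same_alleles": df["effect_allele"] != df["other_allele"],
        "nonpositive_se": df["se"] > 0,
        "pval_out_of_range": (df["pval"] > 0) & (df["pval"] <= 1),
        "bad_eaf": df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)),
        "bad_pos": df["pos"] >= 1,
    }
    ok = pd.Series(True, index=df.index)
    for reason, passed in checks.items():
        passed = passed.fillna(False)
        newly_bad = ok & ~passed
        if newly_bad.any():
            report.drop_reasons[reason] += int(newly_bad.sum())
        ok &= passed
    df = df.loc[ok]

    # duplicate snp_id: keep the smallest p-value (deterministic: stable sort)
    if df["snp_id"].duplicated().any():
        n_before = len(df)
        df = (
            df.sort_values("pval", kind="stable")
            .drop_duplicates("snp_id", keep="first")
            .sort_index()
        )
        report.n_duplicates_resolved = n_before - len(df)

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = df[col].astype(np.float64)
    report.n_valid = len(df)
    report.n_dropped = report.n_read - report.n_valid - report.n_duplicates_resolved
    return df, report


def from_frame(
    df: pd.DataFrame, trait_id: str, trait_type: str = "continuous"
) -> SumStats:
    """Build a validated SumStats from an in-memory DataFrame.

    Rows violating the record invariants are dropped and counted in the
    attached :class:`ReadReport`; raises if no valid row remains.
    """
    clean, report = _validate_frame(df)
    if clean.empty:
        raise ValidationError(f"no valid summary-statistics rows for trait {trait_id!r}")
    return SumStats(trait_id, trait_type, clean, read_report=report)


def read_sumstats(
    path,
    trait_id: str,
    trait_type: str = "continuous",
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistics table.

    ``column_map`` maps dialect column names to canonical ones, e.g.
    ``{"rsids": "snp_id", "#chrom": "chrom", "sebeta": "se"}`` for FinnGen.
    Mandatory canonical columns must be present after mapping.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"summary-statistics file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", ""], keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing mandatory column(s) {missing} after applying column_map"
        )
    return from_frame(df, trait_id, trait_type)


def write_sumstats(s: SumStats, path) -> Path:
    """Write a SumStats to the canonical TSV dialect (``NA`` for missing).

    Numeric fields are written with 10 significant digits so that
    ``read_sumstats(write_sumstats(s))`` reproduces ``s`` field-for-field.
    """
    if s.n_snps == 0:
        raise ValidationError("refusing to write an empty SumStats")
    path = Path(path)
    out = s.table.copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else _FLOAT_FMT % v)
    out.to_csv(path, sep="\t", index=False)
    return path
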