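"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medimr.harmonize import HARMONIZED_COLUMNS, HarmonizedSet
from medimr.sumstats import SumStats, from_frame


def make_sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    """Rows of partial GWAS records; missing fields get sensible defaults."""
    out = []
    for i, r in enumerate(rows):
        base = {
            "snp_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1_000_000 * (i + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.01,
            "pval": 1e-8,
            "n": 10_000,
        }
        base.update(r)
        out.append(base)
    return pd.DataFrame(out)


def make_sumstats(rows: list[dict], trait_id="trait", trait_type="continuous") -> SumStats:
    return from_frame(make_sumstats_frame(rows), trait_id, trait_type)


def make_harmonized(
    beta_exp, se_exp, beta_out, se_out,
    exposure_id="X", outcome_id="Y",
) -> HarmonizedSet:
    """HarmonizedSet straight from effect arrays (non-palindromic alleles)."""
    beta_exp = np.asarray(beta_exp, float)
    se_exp = np.asarray(se_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    J = len(beta_exp)
    table = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(J)],
        "chrom": "1",
        "pos": np.arange(1, J + 1) * 1_000_000,
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": beta_exp,
        "se_exp": se_exp,
        "pval_exp": 1e-8,
        "eaf_exp": 0.3,
        "beta_out": beta_out,
        "se_out": se_out,
        "pval_out": 0.01,
        "f_stat": (beta_exp / se_exp) ** 2,
        "provenance": "direct",
    })[HARMONIZED_COLUMNS]
    return HarmonizedSet(exposure_id, outcome_id, table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
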