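"""Shared helpers for the test suite: record builders and oracle utilities."""

from __future__ import annotations

import numpy as np
import pytest

from pqtlmr.datatypes import LDMatrix, SummaryStatRecord, pvalue_from_z


def make_record(
    variant_id: str = "v0",
    chrom: str = "1",
    pos: int = 1_000_000,
    effect_allele: str = "A",
    other_allele: str = "G",
    eaf: float = 0.3,
    beta: float = 0.1,
    se: float = 0.05,
    n: int = 10_000,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
) -> SummaryStatRecord:
    """A valid record with the p-value derived from beta/se."""
    return SummaryStatRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=max(float(pvalue_from_z(beta / se)), 1e-300),
        n=n,
        trait_type=trait_type,
        case_fraction=case_fraction,
    )


def random_correlation_matrix(m: int, rng: np.random.Generator) -> np.ndarray:
    """A random positive-definite correlation matrix (sample correlation)."""
    x = rng.standard_normal((4 * m + 20, m))
    c = np.corrcoef(x, rowvar=False)
    return (c + c.T) / 2.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def ld_from(r: np.ndarray) -> LDMatrix:
    return LDMatrix([f"v{i}" for i in range(r.shape[0])], r)
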