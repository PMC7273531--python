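"""Selection of cis-pQTL instruments for Mendelian randomization.

A variant qualifies as an instrument for a protein when it (1) lies within
the cis-window (gene body plus flank, default 100 kb, inclusive on both
sides) with minor allele frequency strictly above the cutoff, (2) survives
greedy LD clumping at r-squared < 0.01 against previously chosen index
variants, and (3) has instrument F-statistic F = (gamma/sigma_x)^2 strictly
above the weak-instrument cutoff (default 15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .datatypes import LDMatrix, SummaryStatRecord

__all__ = [
    "GeneWindow",
    "Instrument",
    "filter_cis_maf",
    "ld_clump",
    "f_statistic",
    "select_instruments",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneWindow:
    """Gene body coordinates plus a cis flank (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.gene_id}: flank must be >= 0")

    def contains(self, pos: int) -> bool:
        return self.start - self.flank <= pos <= self.end + self.flank


@dataclass(frozen=True)
class Instrument:
    """A selected pQTL: exposure association and instrument strength."""

    protein_id: str
    variant: SummaryStatRecord
    gamma: float      # SNP-exposure beta
    sigma_x: float    # SNP-exposure SE
    f_stat: float

    def __post_init__(self) -> None:
        expected = f_statistic(self.gamma, self.sigma_x)
        if abs(self.f_stat - expected) > 1e-9 * max(expected, 1.0):
            raise ValueError(
                f"{self.protein_id}/{self.variant.variant_id}: f_stat {self.f_stat} "
                f"inconsistent with (gamma/sigma_x)^2 = {expected}"
            )

    @classmethod
    def from_record(cls, protein_id: str, rec: SummaryStatRecord) -> "Instrument":
        return cls(
            protein_id=protein_id,
            variant=rec,
            gamma=rec.beta,
            sigma_x=rec.se,
            f_stat=f_statistic(rec.beta, rec.se),
        )


def f_statistic(gamma: float, sigma_x: float) -> float:
    """Instrument F-statistic, (gamma / sigma_x) ** 2."""
    if sigma_x <= 0:
        raise ValueError(f"sigma_x must be > 0, got {sigma_x}")
    return (gamma / sigma_x) ** 2


def filter_cis_maf(
    records: Sequence[SummaryStatRecord],
    window: GeneWindow,
    maf_min: float = 0.05,
) -> list[SummaryStatRecord]:
    """Keep variants in the cis-window with MAF strictly above ``maf_min``.

    MAF is min(eaf, 1-eaf); the window boundary is inclusive on both sides.
    Input order is preserved. Records on another chromosome are an error.
    """
    for rec in records:
        if rec.chrom != window.chrom:
            raise ValueError(
                f"record {rec.variant_id} on chrom {rec.chrom}, "
                f"window {window.gene_id} on chrom {window.chrom}"
            )
    return [r for r in records if r.maf > maf_min and window.contains(r.pos)]


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    r2_max: float = 0.01,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: pick index variants by ascending p-value.

    Repeatedly take the remaining variant with the smallest p-value as an
    index variant, then discard all remaining variants with r-squared >=
    ``r2_max`` against it. The returned index set is mutually r² < r2_max.
    P-value ties are broken by (smaller position, lexicographic variant id),
    so the result does not depend on the input record order.
    """
    for rec in records:
        ld.index_of(rec.variant_id)  # raises KeyError naming missing variant
    remaining = sorted(records, key=lambda r: (r.pvalue, r.pos, r.variant_id))
    index_variants: list[SummaryStatRecord] = []
    while remaining:
        index = remaining.pop(0)
        index_variants.append(index)
        remaining = [
            r for r in remaining if ld.r2(index.variant_id, r.variant_id) < r2_max
        ]
    return index_variants


def select_instruments(
    records_by_protein: Mapping[str, Sequence[SummaryStatRecord]],
    windows: Mapping[str, GeneWindow],
    ld_by_protein: Mapping[str, LDMatrix],
    maf_min: float = 0.05,
    r2_max: float = 0.01,
    f_min: float = 15.0,
) -> list[Instrument]:
    """Full instrument selection: cis/MAF filter, LD clump, then F > f_min.

    Emits zero, one or many instruments per protein and logs record counts
    after each stage. Both the MAF and F cutoffs are strict inequalities.
    """
    instruments: list[Instrument] = []
    for protein_id in records_by_protein:
        records = records_by_protein[protein_id]
        window = windows[protein_id]
        ld = ld_by_protein[protein_id]
        cis = filter_cis_maf(records, window, maf_min=maf_min)
        clumped = ld_clump(cis, ld, r2_max=r2_max)
        kept = [
            Instrument.from_record(protein_id, rec)
            for rec in clumped
            if f_statistic(rec.beta, rec.se) > f_min
        ]
        logger.info(
            "%s: %d records -> %d cis/MAF -> %d clumped -> %d with F > %g",
            protein_id, len(records), len(cis), len(clumped), len(kept), f_min,
        )
        instruments.extend(kept)
    return instruments
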