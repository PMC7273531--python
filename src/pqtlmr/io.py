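"""Plain-text I/O: summary-statistic TSVs, dense LD matrices, result tables.

All formats are whitespace-friendly text so pipelines can be inspected and
diffed. Summary statistics use the exact column set of
:class:`~pqtlmr.datatypes.SummaryStatRecord` (extra columns are preserved on
read); the LD matrix is a dense whitespace-delimited matrix file with a
sidecar variant-id list.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import LDMatrix, SummaryStatRecord

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
]

REQUIRED_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "trait_type",
]
OPTIONAL_COLUMNS = ["case_fraction"]

_FLOAT_FMT = "%.10g"


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a TSV with the documented column set."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "trait_type": r.trait_type,
                "case_fraction": "" if r.case_fraction is None else r.case_fraction,
            }
        )
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sumstats(path: str | Path) -> list[SummaryStatRecord]:
    """Read a summary-statistic TSV, validating each row.

    Missing required columns raise naming the column; malformed rows raise
    with their 1-based data line number. Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cf = getattr(row, "case_fraction", None)
        if cf is not None and (isinstance(cf, float) and math.isnan(cf)):
            cf = None
        try:
            records.append(
                SummaryStatRecord(
                    variant_id=str(row.variant_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    eaf=float(row.eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=float(row.pvalue),
                    n=int(row.n),
                    trait_type=str(row.trait_type),
                    case_fraction=None if cf is None else float(cf),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at data line {i}: {exc}") from exc
    return records


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, ids_path: str | Path) -> None:
    """Dense whitespace-delimited matrix plus a sidecar variant-id list."""
    np.savetxt(matrix_path, ld.r, fmt=_FLOAT_FMT)
    Path(ids_path).write_text("\n".join(ld.variant_ids) + "\n")


def read_ld_matrix(matrix_path: str | Path, ids_path: str | Path) -> LDMatrix:
    r = np.loadtxt(matrix_path, ndmin=2)
    ids = Path(ids_path).read_text().split()
    return LDMatrix(ids, r)
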