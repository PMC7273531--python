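"""Core containers for locus-level summary statistics and LD.

Two in-memory objects travel through every stage of the pipeline: a
:class:`SummaryStatRecord` holding one variant's marginal association with one
trait, and an :class:`LDMatrix` holding the signed genotype correlations of a
locus. Both validate their own invariants on construction so downstream code
can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import math

import numpy as np
from scipy import special

__all__ = ["SummaryStatRecord", "LDMatrix", "pvalue_from_z"]

#: Tolerance for the positive-semi-definiteness check of an LD matrix.
PSD_TOL = 1e-8

#: Relative tolerance at which a stored p-value must agree with the
#: two-sided normal test recomputed from beta/se.
PVALUE_RTOL = 1e-6

#: Floor for stored p-values: extreme z-statistics underflow the two-sided
#: normal tail, so p-values are clipped here to stay inside (0, 1].
P_FLOOR = 1e-300


_SQRT2 = math.sqrt(2.0)


def pvalue_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal-tail p-value, 2*Phi(-|z|) = erfc(|z|/sqrt(2))."""
    if np.isscalar(z):
        return math.erfc(abs(z) / _SQRT2)
    return special.erfc(np.abs(z) / _SQRT2)


@dataclass
class SummaryStatRecord:
    """One variant's marginal association with one trait.

    ``beta`` is per effect allele: SD units of a standardized phenotype for
    quantitative traits, log-odds for case-control traits. ``case_fraction``
    is required if and only if ``trait_type == "case_control"``.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(
                f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}"
            )
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.case_fraction is None or not 0.0 < self.case_fraction < 1.0:
                raise ValueError(
                    f"{self.variant_id}: case_control records need case_fraction in (0,1)"
                )
        expected = max(float(pvalue_from_z(self.beta / self.se)), P_FLOOR)
        if expected > P_FLOOR and abs(self.pvalue - expected) > PVALUE_RTOL * expected:
            raise ValueError(
                f"{self.variant_id}: stored pvalue {self.pvalue} inconsistent with "
                f"beta/se (expected {expected})"
            )

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def flipped(self) -> "SummaryStatRecord":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


class LDMatrix:
    """Signed correlation matrix over an ordered list of variants at one locus.

    Invariants enforced at construction: symmetry, unit diagonal, entries in
    [-1, 1], positive semi-definite within ``PSD_TOL`` (a ridge ``eps*I`` is
    added once if the smallest eigenvalue is mildly negative; a matrix that
    stays non-PSD after the repair is rejected).
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        r: np.ndarray,
        ridge_eps: float = 1e-6,
    ) -> None:
        r = np.asarray(r, dtype=float)
        m = len(variant_ids)
        if r.shape != (m, m):
            raise ValueError(f"LD matrix shape {r.shape} does not match {m} variants")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise ValueError("LD entries must satisfy |r| <= 1")
        self.ridge_applied = 0.0
        lo = float(np.linalg.eigvalsh(r)[0])
        if lo < -PSD_TOL:
            r = r + ridge_eps * np.eye(m)
            r = r / np.sqrt(np.outer(np.diag(r), np.diag(r)))  # keep unit diagonal
            self.ridge_applied = ridge_eps
            lo = float(np.linalg.eigvalsh(r)[0])
            if lo < -PSD_TOL:
                raise ValueError(
                    f"LD matrix not positive semi-definite after ridge repair "
                    f"(smallest eigenvalue {lo:.3e})"
                )
        self.variant_ids = list(variant_ids)
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise ValueError("variant_ids must be unique")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not present in LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self.index_of(a), self.index_of(b)] ** 2)

    def subset(self, variant_ids: Iterable[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix([self.variant_ids[i] for i in idx], self.r[np.ix_(idx, idx)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"LDMatrix(m={self.m})"
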