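"""Two-sample Wald-ratio Mendelian randomization across a proteome.

With a single cis-pQTL instrument per protein the MR estimate is the Wald
ratio: the SNP-outcome beta divided by the SNP-exposure beta (gamma). Its
standard error uses the first-order delta method, se_outcome / |gamma|,
which ignores uncertainty in gamma; the instrument-strength filter (F > 15)
keeps the neglected second-order term small. Before the ratio is formed the
outcome association is harmonized to the exposure's effect allele, dropping
palindromic variants whose allele frequency is too close to 0.5 to resolve
strand. Proteome-wide results are screened at the Bonferroni threshold
0.05 / (number of proteins analyzed); the number of outcomes scanned does
not enter the correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .datatypes import SummaryStatRecord, pvalue_from_z
from .instruments import Instrument

__all__ = [
    "HarmonizedPair",
    "WaldEstimate",
    "harmonize",
    "wald_ratio",
    "proteome_scan",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)

#: Floor applied to p-values so extreme z-statistics stay inside (0, 1].
P_FLOOR = 1e-300

#: Palindromic variants with min(eaf, 1-eaf) above this in either study are
#: dropped: their strand cannot be resolved from allele frequency.
PALINDROMIC_EAF_MAX = 0.42

_PALINDROMES = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations oriented to one effect allele."""

    variant_id: str
    action_taken: str  # none | flipped | dropped_palindromic | dropped_incompatible
    beta_exposure: float | None = None
    se_exposure: float | None = None
    beta_outcome: float | None = None
    se_outcome: float | None = None

    @property
    def dropped(self) -> bool:
        return self.action_taken.startswith("dropped")


@dataclass(frozen=True)
class WaldEstimate:
    protein_id: str
    outcome_id: str
    variant_id: str
    ratio: float
    se_ratio: float
    pvalue: float
    passes_bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.se_ratio <= 0:
            raise ValueError("se_ratio must be > 0")
        expected = max(float(pvalue_from_z(self.ratio / self.se_ratio)), P_FLOOR)
        if abs(self.pvalue - expected) > 1e-9 * expected:
            raise ValueError(
                f"pvalue {self.pvalue} inconsistent with ratio/se_ratio "
                f"(expected {expected})"
            )


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in _PALINDROMES


def harmonize(
    exposure: SummaryStatRecord, outcome: SummaryStatRecord
) -> HarmonizedPair:
    """Orient the outcome association to the exposure's effect allele.

    Matching allele pairs pass through; swapped pairs flip the outcome beta
    (and eaf); palindromic variants that are frequency-ambiguous in either
    study are dropped, as are variants with incompatible alleles.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    e1, e2 = exposure.effect_allele.upper(), exposure.other_allele.upper()
    o1, o2 = outcome.effect_allele.upper(), outcome.other_allele.upper()
    if _is_palindromic(e1, e2) and (
        exposure.maf > PALINDROMIC_EAF_MAX or outcome.maf > PALINDROMIC_EAF_MAX
    ):
        return HarmonizedPair(exposure.variant_id, "dropped_palindromic")
    if (e1, e2) == (o1, o2):
        oriented, action = outcome, "none"
    elif (e1, e2) == (o2, o1):
        oriented, action = outcome.flipped(), "flipped"
    else:
        return HarmonizedPair(exposure.variant_id, "dropped_incompatible")
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        action_taken=action,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=oriented.beta,
        se_outcome=oriented.se,
    )


def wald_ratio(
    instr: Instrument,
    beta_outcome: float,
    se_outcome: float,
    outcome_id: str = "outcome",
) -> WaldEstimate:
    """Single-instrument Wald ratio with first-order delta-method SE.

    ratio = beta_outcome / gamma; se = se_outcome / |gamma|; two-sided
    normal p-value. A zero exposure beta is non-identifiable.
    """
    if instr.gamma == 0:
        raise ValueError(
            f"{instr.protein_id}: gamma = 0, Wald ratio not identifiable"
        )
    ratio = beta_outcome / instr.gamma
    se_ratio = se_outcome / abs(instr.gamma)
    p = max(float(pvalue_from_z(ratio / se_ratio)), P_FLOOR)
    return WaldEstimate(
        protein_id=instr.protein_id,
        outcome_id=outcome_id,
        variant_id=instr.variant.variant_id,
        ratio=ratio,
        se_ratio=se_ratio,
        pvalue=p,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def proteome_scan(
    instruments: Sequence[Instrument],
    outcome_stats: Mapping[str, Mapping[str, SummaryStatRecord]],
    n_proteins_tested: int,
    alpha: float = 0.05,
) -> list[WaldEstimate]:
    """Wald-ratio MR of every instrument against every outcome.

    ``outcome_stats`` maps outcome id -> (variant id -> outcome record).
    One estimate is produced per instrument x outcome where the outcome
    reports the instrument variant and harmonization keeps it; a missing
    variant is logged, not an error. ``passes_bonferroni`` is strict:
    p < alpha / n_proteins_tested.
    """
    threshold = bonferroni_threshold(alpha, n_proteins_tested)
    estimates: list[WaldEstimate] = []
    for instr in instruments:
        for outcome_id, by_variant in outcome_stats.items():
            rec = by_variant.get(instr.variant.variant_id)
            if rec is None:
                logger.info(
                    "%s: variant %s absent from outcome %s",
                    instr.protein_id, instr.variant.variant_id, outcome_id,
                )
                continue
            pair = harmonize(instr.variant, rec)
            if pair.dropped:
                logger.info(
                    "%s: variant %s dropped in harmonization (%s)",
                    instr.protein_id, instr.variant.variant_id, pair.action_taken,
                )
                continue
            est = wald_ratio(instr, pair.beta_outcome, pair.se_outcome, outcome_id)
            estimates.append(
                WaldEstimate(
                    protein_id=est.protein_id,
                    outcome_id=est.outcome_id,
                    variant_id=est.variant_id,
                    ratio=est.ratio,
                    se_ratio=est.se_ratio,
                    pvalue=est.pvalue,
                    passes_bonferroni=est.pvalue < threshold,
                )
            )
    return estimates
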