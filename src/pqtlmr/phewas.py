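"""Phenome-wide MR scan with a permutation-rank pleiotropy screen.

A prioritized protein's instrument is scanned against a large panel of
outcomes with the Wald ratio, Bonferroni-screened at 0.05 / n_outcomes.
Because Bonferroni across hundreds of outcomes is blunt, a rank-based
permutation screen compares the target protein's evidence on each outcome
with that of N background pQTL on the same outcome: with the target ranked
r-th (descending) among the N+1 statistics, the permutation p-value is
r / (N + 1), whose smallest attainable value 1/(N+1) is the power floor of
the screen. Benjamini-Hochberg FDR is applied across outcomes.

The ranking statistic is |z| = |ratio / se_ratio| by default: proteins
differ in instrument strength and outcome units, so raw effect estimates
are not comparable across pQTL, whereas |z| ranks evidence strength.
Ranking on |ratio| is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coloc import CLPPResult, ColocResult, colocalizes
from .instruments import Instrument
from .mr import WaldEstimate, proteome_scan

__all__ = [
    "PhewasRow",
    "PermutationRow",
    "phewas_scan",
    "permutation_rank_p",
    "bh_fdr",
    "followup_coloc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhewasRow:
    protein_id: str
    outcome_id: str
    outcome_category: str
    variant_id: str
    ratio: float
    se_ratio: float
    pvalue: float
    passes_bonferroni: bool


@dataclass(frozen=True)
class PermutationRow:
    protein_id: str
    outcome_id: str
    target_statistic: float
    rank: int            # 1-based, descending, target included
    n_background: int
    p_permuted: float
    q_fdr: float = float("nan")

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n_background + 1:
            raise ValueError(f"rank {self.rank} outside 1..{self.n_background + 1}")
        if not 0 < self.p_permuted <= 1:
            raise ValueError(f"p_permuted {self.p_permuted} outside (0,1]")


def phewas_scan(
    instr: Instrument,
    outcome_stats: Mapping[str, Mapping[str, object]],
    n_outcomes: int,
    outcome_categories: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[PhewasRow]:
    """Wald-ratio MR of one instrument against every outcome in a phenome.

    One row per outcome carrying the instrument's variant; outcomes missing
    the variant are omitted and logged. The Bonferroni flag is strict:
    p < alpha / n_outcomes.
    """
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    estimates = proteome_scan(
        [instr], outcome_stats, n_proteins_tested=n_outcomes, alpha=alpha
    )
    categories = outcome_categories or {}
    return [
        PhewasRow(
            protein_id=e.protein_id,
            outcome_id=e.outcome_id,
            outcome_category=categories.get(e.outcome_id, "uncategorized"),
            variant_id=e.variant_id,
            ratio=e.ratio,
            se_ratio=e.se_ratio,
            pvalue=e.pvalue,
            passes_bonferroni=e.passes_bonferroni,
        )
        for e in estimates
    ]


def _ranking_statistic(est: WaldEstimate, statistic: str) -> float:
    if statistic == "abs_z":
        return abs(est.ratio / est.se_ratio)
    if statistic == "abs_ratio":
        return abs(est.ratio)
    raise ValueError(f"unknown ranking statistic {statistic!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1. Every p must lie in
    (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValueError(f"p-value outside (0,1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def permutation_rank_p(
    target_estimates: Mapping[str, WaldEstimate],
    background_estimates: Mapping[str, Mapping[str, WaldEstimate]],
    statistic: str = "abs_z",
    min_background_coverage: float = 0.5,
) -> list[PermutationRow]:
    """Rank-based permutation p-values for one target protein.

    ``target_estimates`` maps outcome id -> the target's estimate;
    ``background_estimates`` maps background pQTL id -> (outcome id ->
    estimate). Per outcome, the target's statistic is ranked (descending,
    ties counted conservatively against the target) among the background
    values plus itself; p = rank / (N + 1). Outcomes covered by fewer than
    ``min_background_coverage`` of the background pQTL are excluded and
    logged. BH-FDR q-values are appended across the retained outcomes.
    """
    n_total_background = len(background_estimates)
    if n_total_background < 1:
        raise ValueError("at least one background pQTL is required")
    rows: list[PermutationRow] = []
    protein_id = next(iter(target_estimates.values())).protein_id if target_estimates else ""
    for outcome_id in target_estimates:
        target_stat = _ranking_statistic(target_estimates[outcome_id], statistic)
        background = [
            _ranking_statistic(ests[outcome_id], statistic)
            for ests in background_estimates.values()
            if outcome_id in ests
        ]
        if len(background) < min_background_coverage * n_total_background:
            logger.info(
                "outcome %s covered by %d/%d background pQTL: excluded",
                outcome_id, len(background), n_total_background,
            )
            continue
        n = len(background)
        rank = 1 + sum(b >= target_stat for b in background)
        rows.append(
            PermutationRow(
                protein_id=protein_id,
                outcome_id=outcome_id,
                target_statistic=target_stat,
                rank=rank,
                n_background=n,
                p_permuted=rank / (n + 1),
            )
        )
    if rows:
        qvals = bh_fdr([row.p_permuted for row in rows])
        rows = [
            PermutationRow(
                protein_id=row.protein_id,
                outcome_id=row.outcome_id,
                target_statistic=row.target_statistic,
                rank=row.rank,
                n_background=row.n_background,
                p_permuted=row.p_permuted,
                q_fdr=float(q),
            )
            for row, q in zip(rows, qvals)
        ]
    return rows


def followup_coloc(
    flagged_rows: Sequence[PermutationRow],
    locus_results: Mapping[str, tuple[ColocResult, CLPPResult]],
    ppa_min: float = 0.8,
    clpp_min: float = 0.01,
) -> list[dict]:
    """Colocalization follow-up of outcomes flagged by the permutation screen.

    ``locus_results`` maps outcome id -> (ColocResult, CLPPResult) computed
    for the target locus against that outcome. Returns one report dict per
    flagged row with the dual-evidence decision attached.
    """
    reports = []
    for row in flagged_rows:
        if row.outcome_id not in locus_results:
            raise KeyError(f"no locus results for flagged outcome {row.outcome_id!r}")
        coloc_result, clpp_result = locus_results[row.outcome_id]
        decision, reason = colocalizes(coloc_result, clpp_result, ppa_min, clpp_min)
        reports.append(
            {
                "protein_id": row.protein_id,
                "outcome_id": row.outcome_id,
                "p_permuted": row.p_permuted,
                "q_fdr": row.q_fdr,
                "pp_h4": coloc_result.pp_h4,
                "locus_clpp": clpp_result.locus_clpp,
                "decision": decision,
                "reason": reason,
            }
        )
    return reports
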