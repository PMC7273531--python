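"""Summary-level simulation of pQTL and outcome-GWAS statistics with known truth.

Statistics are simulated directly at the summary level rather than through
individual genotypes: given a locus LD matrix ``R`` and per-allele joint
causal effects ``b``, the marginal z-score vector is drawn as

    z ~ MVN( R @ (b / se),  R )

which is the standard large-sample model for GWAS summary statistics and the
model assumed by the approximate-Bayes-factor and fine-mapping machinery
downstream. Betas and standard errors are back-computed from z using the
asymptotic SE of a per-allele effect on a standardized phenotype under HWE,

    se_j = 1 / sqrt(2 * n * eaf_j * (1 - eaf_j)),

with an extra ``1/sqrt(case_fraction * (1 - case_fraction))`` factor for
case-control (log-odds) traits.

Four locus scenarios encode the causal structures that the colocalization
methods must distinguish: ``shared`` (one variant drives protein and outcome,
the outcome effect mediated with slope theta), ``distinct`` (protein and
outcome have different causal variants — linkage, not colocalization),
``exposure_only`` (pQTL present, outcome null) and ``null`` (no signal at
all). A single causal variant per trait per locus is the default, matching
the single-pQTL setting the pipeline targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import LDMatrix, SummaryStatRecord, pvalue_from_z

__all__ = [
    "AR1Structure",
    "BlockStructure",
    "SyntheticScenario",
    "TruthRecord",
    "LocusPair",
    "ProteomeStudy",
    "simulate_ld_matrix",
    "simulate_locus_pair",
    "simulate_proteome_study",
    "exposure_beta_for_f",
]

SCENARIOS = ("shared", "distinct", "exposure_only", "null")

# Non-palindromic allele pairs only, unless palindromic injection is requested.
_NON_PALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_P_FLOOR = 1e-300  # keep stored p-values inside (0, 1]


@dataclass(frozen=True)
class AR1Structure:
    """AR(1) LD: r_ij = rho ** |i - j|."""

    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"AR(1) rho must satisfy |rho| < 1, got {self.rho}")


@dataclass(frozen=True)
class BlockStructure:
    """Block LD: within-block correlation ``within_r``, zero across blocks."""

    sizes: tuple[int, ...]
    within_r: float

    def __post_init__(self) -> None:
        if not -1.0 < self.within_r <= 1.0:
            raise ValueError(f"within_r must be in (-1, 1], got {self.within_r}")
        if any(s < 1 for s in self.sizes):
            raise ValueError("block sizes must be >= 1")


def simulate_ld_matrix(
    m: int,
    structure: AR1Structure | BlockStructure,
    seed: int | None = None,
) -> LDMatrix:
    """Build a locus LD matrix with the requested structure.

    Both supported structures are deterministic closed forms; ``seed`` is
    accepted for interface uniformity with the stochastic generators.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if isinstance(structure, AR1Structure):
        idx = np.arange(m)
        r = structure.rho ** np.abs(idx[:, None] - idx[None, :])
    elif isinstance(structure, BlockStructure):
        if sum(structure.sizes) != m:
            raise ValueError(
                f"block sizes sum to {sum(structure.sizes)}, expected m={m}"
            )
        r = np.eye(m)
        start = 0
        for size in structure.sizes:
            block = np.full((size, size), structure.within_r)
            np.fill_diagonal(block, 1.0)
            r[start : start + size, start : start + size] = block
            start += size
    else:
        raise TypeError(f"unsupported LD structure: {structure!r}")
    variant_ids = [f"v{i:04d}" for i in range(m)]
    return LDMatrix(variant_ids, r)


def exposure_beta_for_f(f_target: float, n: int, eaf: float) -> float:
    """Per-allele exposure beta giving expected instrument F == ``f_target``.

    Since F = (beta/se)^2 and se = 1/sqrt(2 n eaf (1-eaf)), the required
    beta is sqrt(F / (2 n eaf (1-eaf))).
    """
    return math.sqrt(f_target / (2.0 * n * eaf * (1.0 - eaf)))


@dataclass
class SyntheticScenario:
    """Complete parameterization of one simulated locus pair.

    ``theta`` is the causal effect of the protein on the outcome (outcome
    units per SD of protein); in a shared scenario the outcome causal beta is
    ``theta * beta_exposure`` at the shared variant. ``target_f`` optionally
    overrides ``beta_exposure`` so the exposure causal variant has expected
    F-statistic equal to the target given its realized allele frequency.
    """

    scenario: str = "shared"
    m: int = 100
    causal_exposure_index: int | None = None
    causal_outcome_index: int | None = None
    beta_exposure: float = 1.0
    theta: float = 0.3
    n_exposure: int = 144
    n_outcome: int = 50_000
    ld_structure: AR1Structure | BlockStructure = field(
        default_factory=lambda: AR1Structure(0.5)
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    target_f: float | None = None
    outcome_trait_type: str = "quantitative"
    case_fraction: float | None = None
    palindromic_fraction: float = 0.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 1_000
    variant_prefix: str = "v"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        lo, hi = self.maf_range
        if not (0.05 - 1e-12 <= lo <= hi <= 0.5 + 1e-12):
            raise ValueError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        if self.causal_exposure_index is None:
            self.causal_exposure_index = self.m // 2
        if self.causal_outcome_index is None:
            if self.scenario == "distinct":
                self.causal_outcome_index = 0 if self.m == 1 else (self.m - 1) // 4
                if self.causal_outcome_index == self.causal_exposure_index:
                    self.causal_outcome_index = (self.causal_exposure_index + 1) % self.m
            else:
                self.causal_outcome_index = self.causal_exposure_index
        if not 0 <= self.causal_exposure_index < self.m:
            raise ValueError("causal_exposure_index out of range")
        if not 0 <= self.causal_outcome_index < self.m:
            raise ValueError("causal_outcome_index out of range")
        if self.scenario == "shared" and self.causal_exposure_index != self.causal_outcome_index:
            raise ValueError("shared scenario requires identical causal indices")
        if self.scenario == "distinct" and self.causal_exposure_index == self.causal_outcome_index:
            raise ValueError("distinct scenario requires different causal indices")
        if self.outcome_trait_type == "case_control" and self.case_fraction is None:
            self.case_fraction = 0.5


@dataclass
class TruthRecord:
    """Ground truth of one simulated locus pair, for recovery tests."""

    protein_id: str
    scenario: str
    theta: float  # true Wald ratio at the shared variant (nan if undefined)
    causal_exposure_index: int | None
    causal_outcome_index: int | None
    beta_exposure_causal: float
    beta_outcome_causal: float
    seed: int


@dataclass
class LocusPair:
    """One simulated locus: exposure stats, outcome stats, LD and truth."""

    protein_id: str
    exposure: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    ld: LDMatrix
    truth: TruthRecord


def _draw_alleles(rng: np.random.Generator, m: int, palindromic_fraction: float):
    pairs = []
    for _ in range(m):
        if palindromic_fraction > 0 and rng.random() < palindromic_fraction:
            pairs.append(_PALINDROMIC[rng.integers(len(_PALINDROMIC))])
        else:
            pairs.append(_NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))])
    return pairs


def _marginal_stats(
    scn: SyntheticScenario,
    ld_chol: np.ndarray,
    ld_r: np.ndarray,
    eaf: np.ndarray,
    alleles: list[tuple[str, str]],
    b_joint: np.ndarray,
    n: int,
    trait_type: str,
    case_fraction: float | None,
    rng: np.random.Generator,
) -> list[SummaryStatRecord]:
    m = scn.m
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    if trait_type == "case_control":
        se = se / math.sqrt(case_fraction * (1.0 - case_fraction))
    mean = ld_r @ (b_joint / se)
    z = mean + ld_chol @ rng.standard_normal(m)
    beta = z * se
    pvals = np.maximum(pvalue_from_z(z), _P_FLOOR)
    records = []
    for i in range(m):
        records.append(
            SummaryStatRecord(
                variant_id=f"{scn.variant_prefix}{i:04d}",
                chrom=scn.chrom,
                pos=scn.pos_start + i * scn.pos_step,
                effect_allele=alleles[i][0],
                other_allele=alleles[i][1],
                eaf=float(eaf[i]),
                beta=float(beta[i]),
                se=float(se[i]),
                pvalue=float(pvals[i]),
                n=n,
                trait_type=trait_type,
                case_fraction=case_fraction,
            )
        )
    return records


def simulate_locus_pair(
    scn: SyntheticScenario,
    protein_id: str = "P0001",
    ld: LDMatrix | None = None,
    ld_chol: np.ndarray | None = None,
) -> LocusPair:
    """Simulate exposure and outcome summary statistics for one locus.

    The exposure (protein) and outcome studies are independent samples, so
    their z-score noise is drawn independently — the two-sample MR setting.
    Deterministic given ``scn.seed``. ``ld``/``ld_chol`` may be supplied to
    reuse a factorization across many loci with the same structure.
    """
    rng = np.random.default_rng(scn.seed)
    if ld is None:
        base_ld = simulate_ld_matrix(scn.m, scn.ld_structure)
        ld = LDMatrix(
            [f"{scn.variant_prefix}{i:04d}" for i in range(scn.m)], base_ld.r
        )
    elif ld.m != scn.m:
        raise ValueError(f"supplied LD has m={ld.m}, scenario has m={scn.m}")
    if ld_chol is None:
        ld_chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(scn.m))

    maf = rng.uniform(scn.maf_range[0], scn.maf_range[1], size=scn.m)
    flip = rng.random(scn.m) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    alleles = _draw_alleles(rng, scn.m, scn.palindromic_fraction)

    ci, co = scn.causal_exposure_index, scn.causal_outcome_index
    if scn.target_f is not None:
        beta_x = exposure_beta_for_f(scn.target_f, scn.n_exposure, float(eaf[ci]))
    else:
        beta_x = scn.beta_exposure

    b_exp = np.zeros(scn.m)
    b_out = np.zeros(scn.m)
    theta_true = math.nan
    if scn.scenario in ("shared", "distinct", "exposure_only"):
        b_exp[ci] = beta_x
    if scn.scenario == "shared":
        b_out[co] = scn.theta * beta_x
        theta_true = scn.theta
    elif scn.scenario == "distinct":
        b_out[co] = scn.theta * beta_x

    exposure = _marginal_stats(
        scn, ld_chol, ld.r, eaf, alleles, b_exp, scn.n_exposure,
        "quantitative", None, rng,
    )
    outcome = _marginal_stats(
        scn, ld_chol, ld.r, eaf, alleles, b_out, scn.n_outcome,
        scn.outcome_trait_type, scn.case_fraction, rng,
    )
    truth = TruthRecord(
        protein_id=protein_id,
        scenario=scn.scenario,
        theta=theta_true,
        causal_exposure_index=ci if scn.scenario != "null" else None,
        causal_outcome_index=co if scn.scenario in ("shared", "distinct") else None,
        beta_exposure_causal=beta_x if scn.scenario != "null" else 0.0,
        beta_outcome_causal=float(b_out[co]) if scn.scenario in ("shared", "distinct") else 0.0,
        seed=scn.seed,
    )
    return LocusPair(protein_id, exposure, outcome, ld, truth)


@dataclass
class ProteomeStudy:
    """A collection of simulated locus pairs keyed by protein id."""

    loci: list[LocusPair]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def truth_for(self, protein_id: str) -> TruthRecord:
        for lp in self.loci:
            if lp.protein_id == protein_id:
                return lp.truth
        raise KeyError(f"unknown protein {protein_id!r}")


def _allocate(n: int, proportions: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n proteins to scenarios, deterministic."""
    if n == 0:
        return []
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"scenario proportions must sum to 1, got {total}")
    for key in proportions:
        if key not in SCENARIOS:
            raise ValueError(f"unknown scenario {key!r}")
    keys = sorted(proportions)  # deterministic order
    exact = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(exact[k])) for k in keys}
    remaining = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_remainder[:remaining]:
        counts[k] += 1
    labels: list[str] = []
    for k in keys:
        labels.extend([k] * counts[k])
    return labels


def simulate_proteome_study(
    n_proteins: int,
    proportions: dict[str, float],
    base: SyntheticScenario | None = None,
    seed: int = 0,
) -> ProteomeStudy:
    """Simulate a proteome of independent loci with a given scenario mix.

    ``base`` supplies the shared simulation parameters (m, LD structure,
    sample sizes, effect sizes); each protein gets a child seed derived from
    ``seed`` and its own scenario label from the largest-remainder allocation
    of ``proportions``. LD factorizations are reused across proteins sharing
    a structure.
    """
    if base is None:
        base = SyntheticScenario()
    labels = _allocate(n_proteins, proportions)
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_proteins, 1))
    ld = simulate_ld_matrix(base.m, base.ld_structure)
    ld_chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(base.m))
    loci = []
    for i, label in enumerate(labels):
        pid = f"P{i + 1:04d}"
        scn = SyntheticScenario(
            scenario=label,
            m=base.m,
            beta_exposure=base.beta_exposure,
            theta=base.theta if label != "null" else 0.0,
            n_exposure=base.n_exposure,
            n_outcome=base.n_outcome,
            ld_structure=base.ld_structure,
            maf_range=base.maf_range,
            seed=int(child_seeds[i] % (2**31)),
            target_f=base.target_f,
            outcome_trait_type=base.outcome_trait_type,
            case_fraction=base.case_fraction,
            palindromic_fraction=base.palindromic_fraction,
            chrom=base.chrom,
            pos_start=base.pos_start,
            pos_step=base.pos_step,
            variant_prefix=f"{pid}_{base.variant_prefix}",
        )
        loci.append(simulate_locus_pair(scn, protein_id=pid, ld=None, ld_chol=ld_chol))
    return ProteomeStudy(loci)
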