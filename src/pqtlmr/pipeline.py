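"""End-to-end orchestration: simulate, select, scan, colocalize, phewas.

``run_pipeline`` executes the full analysis on a synthetic proteome with a
known scenario mix and writes every result as a TSV, plus a JSON run
manifest recording the config snapshot and stage-by-stage record counts.
All randomness descends from one master seed through per-stage child seeds,
so reruns with the same config are byte-identical and individual stages are
reproducible in isolation.

Stages, mirroring the analysis flow the package implements:

1. simulate a proteome of cis loci (exposure pQTL + outcome GWAS + LD);
2. select instruments (cis/MAF filter, LD clump at r² < 0.01, F > 15);
3. proteome-wide Wald-ratio MR against the outcome, Bonferroni-screened at
   0.05 / n_proteins;
4. dual colocalization (ABF posteriors + CLPP) of every Bonferroni pass;
5. phenome-wide MR of every colocalized protein across a synthetic null
   phenome, with the rank-permutation screen against background pQTL and
   BH-FDR;
6. colocalization follow-up of permutation-flagged outcomes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import (
    W_CASE_CONTROL,
    W_QUANTITATIVE,
    ColocPriors,
    coloc_pp,
    colocalizes,
    ecaviar_clpp,
)
from .datatypes import SummaryStatRecord, pvalue_from_z
from .instruments import GeneWindow, select_instruments
from .io import write_sumstats
from .mr import proteome_scan, wald_ratio
from .phewas import followup_coloc, permutation_rank_p, phewas_scan
from .simulate import AR1Structure, SyntheticScenario, simulate_proteome_study

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report_tables"]

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable to YAML and back."""

    # synthetic study
    n_proteins: int = 100
    m_variants: int = 100
    ar1_rho: float = 0.5
    prop_shared: float = 0.1
    prop_distinct: float = 0.1
    prop_exposure_only: float = 0.7
    prop_null: float = 0.1
    n_exposure: int = 144
    n_outcome: int = 50_000
    theta: float = 0.3
    target_f: float = 150.0
    maf_min_sim: float = 0.05
    maf_max_sim: float = 0.5
    outcome_trait_type: str = "quantitative"
    case_fraction: float = 0.5
    # instrument selection
    maf_min: float = 0.05
    r2_max: float = 0.01
    f_min: float = 15.0
    cis_flank: int = 100_000
    # MR screening
    alpha: float = 0.05
    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w_quantitative: float = W_QUANTITATIVE
    coloc_w_case_control: float = W_CASE_CONTROL
    ecaviar_prior_gamma: float = 0.01
    ecaviar_ncp_sd: float = 5.2
    ecaviar_max_causal: int = 1
    ppa_min: float = 0.8
    clpp_min: float = 0.01
    # phewas + permutation
    n_phewas_outcomes: int = 700
    n_background: int = 500
    p_permuted_max: float = 0.05
    # seeding
    seed: int = 0

    def __post_init__(self) -> None:
        props = (
            self.prop_shared + self.prop_distinct
            + self.prop_exposure_only + self.prop_null
        )
        if abs(props - 1.0) > 1e-9:
            raise ValueError(f"scenario proportions sum to {props}, not 1")
        for name in ("maf_min", "r2_max", "alpha", "ppa_min", "clpp_min",
                     "p_permuted_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scenario_mix(self) -> dict[str, float]:
        return {
            "shared": self.prop_shared,
            "distinct": self.prop_distinct,
            "exposure_only": self.prop_exposure_only,
            "null": self.prop_null,
        }


@dataclass
class RunManifest:
    """Config snapshot plus stage-by-stage record counts."""

    config: dict
    version: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)

    def validate_monotonic(self) -> None:
        chain = [
            self.counts.get("instruments", 0),
            self.counts.get("bonferroni_passes", 0),
            self.counts.get("colocalized_loci", 0),
        ]
        if not all(a >= b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"filter-chain counts not monotone: {chain}")

    def write(self, path: str | Path) -> None:
        self.validate_monotonic()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )


def _coloc_w(cfg: PipelineConfig, trait_type: str) -> float:
    return (
        cfg.coloc_w_case_control
        if trait_type == "case_control"
        else cfg.coloc_w_quantitative
    )


def _null_outcome_record(
    template: SummaryStatRecord, z: float, n: int, outcome_id: str
) -> SummaryStatRecord:
    se = 1.0 / math.sqrt(2.0 * n * template.eaf * (1.0 - template.eaf))
    return SummaryStatRecord(
        variant_id=template.variant_id,
        chrom=template.chrom,
        pos=template.pos,
        effect_allele=template.effect_allele,
        other_allele=template.other_allele,
        eaf=template.eaf,
        beta=z * se,
        se=se,
        pvalue=max(float(pvalue_from_z(z)), _P_FLOOR),
        n=n,
    )


def report_tables(estimates, positions: dict[str, int] | None = None) -> pd.DataFrame:
    """Manhattan-style table: -log10 p, position, direction per estimate."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "protein_id": e.protein_id,
                "outcome_id": e.outcome_id,
                "variant_id": e.variant_id,
                "pos": (positions or {}).get(e.variant_id, -1),
                "ratio": e.ratio,
                "se_ratio": e.se_ratio,
                "pvalue": e.pvalue,
                "neglog10_p": -math.log10(e.pvalue),
                "direction": int(np.sign(e.ratio)),
                "passes_bonferroni": e.passes_bonferroni,
            }
        )
    columns = [
        "protein_id", "outcome_id", "variant_id", "pos", "ratio", "se_ratio",
        "pvalue", "neglog10_p", "direction", "passes_bonferroni",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage and write TSV results plus the manifest (last)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.SeedSequence(cfg.seed).generate_state(4)
    counts: dict[str, int] = {}

    # stage 1: synthetic proteome
    base = SyntheticScenario(
        m=cfg.m_variants,
        n_exposure=cfg.n_exposure,
        n_outcome=cfg.n_outcome,
        theta=cfg.theta,
        target_f=cfg.target_f,
        ld_structure=AR1Structure(cfg.ar1_rho),
        maf_range=(cfg.maf_min_sim, cfg.maf_max_sim),
        outcome_trait_type=cfg.outcome_trait_type,
        case_fraction=(
            cfg.case_fraction if cfg.outcome_trait_type == "case_control" else None
        ),
    )
    study = simulate_proteome_study(
        cfg.n_proteins, cfg.scenario_mix(), base, seed=int(stage_seeds[0] % 2**31)
    )
    counts["proteins"] = len(study)
    logger.info("simulated %d protein loci", len(study))

    exposure_all = [r for lp in study for r in lp.exposure]
    outcome_all = [r for lp in study for r in lp.outcome]
    write_sumstats(exposure_all, outdir / "exposure_sumstats.tsv")
    write_sumstats(outcome_all, outdir / "outcome_sumstats.tsv")
    pd.DataFrame([dataclasses.asdict(lp.truth) for lp in study]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # stage 2: instrument selection
    by_protein = {lp.protein_id: lp.exposure for lp in study}
    windows = {
        lp.protein_id: GeneWindow(
            gene_id=lp.protein_id,
            chrom=lp.exposure[0].chrom,
            start=min(r.pos for r in lp.exposure),
            end=max(r.pos for r in lp.exposure),
            flank=cfg.cis_flank,
        )
        for lp in study
    }
    ld_by_protein = {lp.protein_id: lp.ld for lp in study}
    instruments = select_instruments(
        by_protein, windows, ld_by_protein,
        maf_min=cfg.maf_min, r2_max=cfg.r2_max, f_min=cfg.f_min,
    )
    counts["instruments"] = len(instruments)
    pd.DataFrame(
        [
            {
                "protein_id": ins.protein_id,
                "variant_id": ins.variant.variant_id,
                "gamma": ins.gamma,
                "sigma_x": ins.sigma_x,
                "f_stat": ins.f_stat,
            }
            for ins in instruments
        ],
        columns=["protein_id", "variant_id", "gamma", "sigma_x", "f_stat"],
    ).to_csv(outdir / "instruments.tsv", sep="\t", index=False, float_format="%.10g")

    # stage 3: proteome-wide MR against the main outcome
    outcome_by_variant = {r.variant_id: r for lp in study for r in lp.outcome}
    estimates = proteome_scan(
        instruments, {"outcome": outcome_by_variant},
        n_proteins_tested=max(cfg.n_proteins, 1), alpha=cfg.alpha,
    )
    passes = [e for e in estimates if e.passes_bonferroni]
    counts["bonferroni_passes"] = len(passes)
    positions = {r.variant_id: r.pos for lp in study for r in lp.exposure}
    report_tables(estimates, positions).to_csv(
        outdir / "mr_results.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # stage 4: dual colocalization of Bonferroni passes
    priors = ColocPriors(cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12)
    loci = {lp.protein_id: lp for lp in study}
    coloc_rows = []
    colocalized_ids = []
    for est in passes:
        lp = loci[est.protein_id]
        cres = coloc_pp(
            [(r.beta, r.se) for r in lp.exposure],
            [(r.beta, r.se) for r in lp.outcome],
            priors=priors,
            prior_sd1=cfg.coloc_w_quantitative,
            prior_sd2=_coloc_w(cfg, lp.outcome[0].trait_type),
        )
        eres = ecaviar_clpp(
            [r.z for r in lp.exposure], [r.z for r in lp.outcome], lp.ld,
            prior_gamma=cfg.ecaviar_prior_gamma,
            ncp_sd=cfg.ecaviar_ncp_sd,
            max_causal=cfg.ecaviar_max_causal,
        )
        decision, reason = colocalizes(cres, eres, cfg.ppa_min, cfg.clpp_min)
        if decision:
            colocalized_ids.append(est.protein_id)
        coloc_rows.append(
            {
                "locus_id": est.protein_id,
                "n_variants": cres.n_variants,
                **cres.as_dict(),
                "locus_clpp": eres.locus_clpp,
                "decision": decision,
                "reason": reason,
            }
        )
    counts["colocalized_loci"] = len(colocalized_ids)
    pd.DataFrame(
        coloc_rows,
        columns=[
            "locus_id", "n_variants", "pp_h0", "pp_h1", "pp_h2", "pp_h3",
            "pp_h4", "locus_clpp", "decision", "reason",
        ],
    ).to_csv(outdir / "coloc_results.tsv", sep="\t", index=False, float_format="%.10g")

    # stage 5: phewas + permutation for colocalized proteins
    phewas_frames, perm_frames, followup_rows = [], [], []
    rng_phewas = np.random.default_rng(int(stage_seeds[1] % 2**31))
    rng_bg = np.random.default_rng(int(stage_seeds[2] % 2**31))
    instrument_by_id = {ins.protein_id: ins for ins in instruments}
    n_flagged = 0
    for pid in colocalized_ids:
        lp = loci[pid]
        instr = instrument_by_id[pid]
        chol = np.linalg.cholesky(lp.ld.r + 1e-10 * np.eye(lp.ld.m))
        # synthetic null phenome: one MVN(0, LD) z-draw per outcome
        outcome_ids = [f"phenome{j:04d}" for j in range(cfg.n_phewas_outcomes)]
        phenome: dict[str, dict[str, SummaryStatRecord]] = {}
        for oid in outcome_ids:
            zvec = chol @ rng_phewas.standard_normal(lp.ld.m)
            phenome[oid] = {
                rec.variant_id: _null_outcome_record(rec, float(z), cfg.n_outcome, oid)
                for rec, z in zip(lp.exposure, zvec)
            }
        rows = phewas_scan(
            instr, phenome, n_outcomes=cfg.n_phewas_outcomes, alpha=cfg.alpha
        )
        phewas_frames.append(pd.DataFrame([dataclasses.asdict(r) for r in rows]))

        # background pQTL: other instruments, null outcome effects
        pool = [i for i in instruments if i.protein_id != pid]
        n_bg = min(cfg.n_background, len(pool))
        bg_idx = rng_bg.choice(len(pool), size=n_bg, replace=False) if n_bg else []
        background = {}
        for k in sorted(bg_idx):
            bg = pool[k]
            z_bg = rng_bg.standard_normal(cfg.n_phewas_outcomes)
            ests = {}
            for oid, z in zip(outcome_ids, z_bg):
                rec = _null_outcome_record(bg.variant, float(z), cfg.n_outcome, oid)
                ests[oid] = wald_ratio(bg, rec.beta, rec.se, oid)
            background[bg.protein_id] = ests
        target_ests = {}
        for oid in outcome_ids:
            rec = phenome[oid][instr.variant.variant_id]
            target_ests[oid] = wald_ratio(instr, rec.beta, rec.se, oid)
        perm_rows = permutation_rank_p(target_ests, background)
        perm_frames.append(pd.DataFrame([dataclasses.asdict(r) for r in perm_rows]))

        flagged = [r for r in perm_rows if r.p_permuted < cfg.p_permuted_max]
        n_flagged += len(flagged)
        if flagged:
            locus_results = {}
            for row in flagged:
                recs = [phenome[row.outcome_id][r.variant_id] for r in lp.exposure]
                cres = coloc_pp(
                    [(r.beta, r.se) for r in lp.exposure],
                    [(r.beta, r.se) for r in recs],
                    priors=priors,
                    prior_sd1=cfg.coloc_w_quantitative,
                    prior_sd2=cfg.coloc_w_quantitative,
                )
                eres = ecaviar_clpp(
                    [r.z for r in lp.exposure], [r.z for r in recs], lp.ld,
                    prior_gamma=cfg.ecaviar_prior_gamma,
                    ncp_sd=cfg.ecaviar_ncp_sd,
                    max_causal=cfg.ecaviar_max_causal,
                )
                locus_results[row.outcome_id] = (cres, eres)
            followup_rows.extend(
                followup_coloc(flagged, locus_results, cfg.ppa_min, cfg.clpp_min)
            )
    counts["phewas_flags"] = n_flagged

    phewas_cols = [
        "protein_id", "outcome_id", "outcome_category", "variant_id",
        "ratio", "se_ratio", "pvalue", "passes_bonferroni",
    ]
    perm_cols = [
        "protein_id", "outcome_id", "target_statistic", "rank",
        "n_background", "p_permuted", "q_fdr",
    ]
    (pd.concat(phewas_frames, ignore_index=True) if phewas_frames
     else pd.DataFrame(columns=phewas_cols)).to_csv(
        outdir / "phewas.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (pd.concat(perm_frames, ignore_index=True) if perm_frames
     else pd.DataFrame(columns=perm_cols)).to_csv(
        outdir / "permutation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    followup_cols = [
        "protein_id", "outcome_id", "p_permuted", "q_fdr", "pp_h4",
        "locus_clpp", "decision", "reason",
    ]
    pd.DataFrame(followup_rows, columns=followup_cols).to_csv(
        outdir / "followup_coloc.tsv", sep="\t", index=False, float_format="%.10g"
    )

    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        version=__version__,
        seed=cfg.seed,
        counts=counts,
    )
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %s", counts)
    return manifest
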