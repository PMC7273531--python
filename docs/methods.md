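# Methods

This note records the statistical model behind each stage of `pqtlmr`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Summary-level simulation

All synthetic data are generated at the summary level. For a locus of m
variants with LD matrix R (signed genotype correlations) and per-allele
joint causal effects b, the marginal z-score vector of one study is

    z ~ MVN( R · (b / se), R ),

the standard large-sample model for GWAS marginal statistics and exactly
the likelihood the ABF and fine-mapping machinery downstream assumes.
Betas and SEs are back-computed from z with the asymptotic standard error
of a per-allele effect on a standardized phenotype under Hardy–Weinberg
genotype variance 2·eaf·(1−eaf):

    se_j = 1 / sqrt(2 · n · eaf_j · (1 − eaf_j)),

multiplied by 1/sqrt(φ(1−φ)) for case-control traits with case fraction φ
(logistic large-sample approximation, betas on the log-odds scale).
Exposure and outcome studies draw independent noise — the two-sample MR
setting with non-overlapping samples.

Scenarios encode the causal structures colocalization must separate:

* **shared** — one variant drives the protein (effect β_x) and, through
  it, the outcome (effect θ·β_x). The true Wald ratio is θ.
* **distinct** — the protein and outcome causal variants differ (linkage).
  The outcome causal effect magnitude is set to θ·β_x as well, so
  discrimination tests compare signals of equal strength.
* **exposure_only** — pQTL present, outcome globally null. This is the
  meaningful "null proteome" for type-I-error checks: under the fully null
  scenario no instrument passes F > 15 and the outcome scan would be
  vacuously quiet.
* **null** — no signal in either trait.

Defaults are chosen to mirror the setting the pipeline targets: exposure
n = 144 (a small post-mortem brain proteome study), outcome n = 50,000 (a
moderate GWAS), m = 100 variants per cis locus (within the realistic
50–500 range; the null-proteome simulations use m = 50, the lower end, to
keep 40,000-locus Monte-Carlo runs desk-scale), AR(1) LD with ρ = 0.5,
MAF uniform on [0.05, 0.5] (eligibility requires MAF over 5 %), θ = 0.3,
and a target instrument F of 150 via `target_f` (which back-solves β_x
from the realized causal-variant frequency; F ≈ 100–200 is typical of the
single strong cis-pQTL per protein that motivates the Wald-ratio design).
Allele pairs are non-palindromic by default; a `palindromic_fraction` flag
injects A/T and C/G variants for harmonization testing. One causal variant
per trait per locus is the default, matching the single-pQTL regime.

What the simulator does **not** emulate: realistic human LD maps (AR(1)
and block structures only), cross-panel LD mismatch between the exposure
study and an external reference (one shared R is used for both traits and
for analysis), imputation error, sample overlap between studies, and
uncertainty in the LD estimate itself. Passing tests therefore demonstrate
correctness of the statistical machinery under its own assumptions, not
robustness to the misspecifications real data add.

## Instrument selection

MAF is min(eaf, 1−eaf); both the MAF cutoff ("over 5 %") and the
instrument-strength cutoff F > 15 are strict inequalities. The cis window
is the gene body ± 100 kb, inclusive at both boundaries, positions
1-based. Clumping is greedy: repeatedly take the smallest-p remaining
variant as an index and drop everything with r² ≥ 0.01 against it;
p-value ties break by (position, variant id), making the output invariant
to input order. Clumping is restricted to the supplied locus — all
instruments here are cis by construction, so no genome-wide window is
needed. F is computed after clumping; with a single true pQTL per locus
the order is immaterial.

## Wald-ratio MR

θ̂ = β_Y/γ with first-order delta-method SE σ_Y/|γ|. The neglected
second-order term is of relative size 1/F, which the F > 15 screen keeps
small; the confidence-coverage test makes the regime explicit (nominal
coverage requires the outcome z to be well below √F). Harmonization
orients the outcome to the exposure's effect allele, flips β when the
allele pair is swapped, and drops palindromic variants whose MAF exceeds
0.42 in either study (strand unresolvable from frequency; 0.42 is the
conventional ambiguity threshold). The Bonferroni denominator is the
number of proteins analyzed — not proteins × outcomes — so a scan of 692
proteins uses p < 0.05/692 ≈ 7.23×10⁻⁵ regardless of how many outcomes
are tested; independent evidence (colocalization) is the intended guard
for the untested outcome dimension.

P-values are floored at 1e−300 so extreme z-statistics stay inside (0,1];
`pvalue_from_z` uses erfc directly.

## Colocalization

**ABF route.** Per-variant Wakefield log-ABF: with z = β/se, V = se²,
r = W²/(W²+V), log ABF = ½log(1−r) + ½rz². Prior effect-size SD W = 0.15
for quantitative traits, 0.2 for case-control (the conventional
defaults). Under one causal variant per trait, hypothesis likelihoods are
L0 = 1, L1 = p1·ΣBF₁, L2 = p2·ΣBF₂, L3 = p1·p2·(ΣBF₁·ΣBF₂ − Σ(BF₁BF₂)),
L4 = p12·Σ(BF₁BF₂), with per-variant priors p1 = p2 = 1e−4, p12 = 1e−5.
All sums use log-sum-exp; L3's difference uses log1mexp and cancels
exactly at m = 1. "PPA" in the decision rule is read as PP.H4, the
posterior of a shared causal variant (the standard reading; a
PP.H4/(PP.H3+PP.H4) conditioning variant exists but is not offered).

**CLPP route.** For each trait the z-vector is modelled as
MVN(0, Σ + s²·Σ_C Σ_Cᵀ) under causal configuration C (Σ = R, s = ncp_sd),
with configuration prior γ^|C|(1−γ)^(m−|C|); enumeration covers |C| ≤ 1
by default (≤ 2 optional, O(m²) densities). The configuration Bayes
factor against the empty configuration reduces by a Woodbury identity to

    log BF(C) = ½·( s²·z_Cᵀ(I + s²Σ_CC)⁻¹z_C − log det(I + s²Σ_CC) ),

a function of z_C and Σ_CC only — no inversion of the full (possibly
singular) LD matrix, so perfectly correlated variants are handled exactly
and symmetrically. Per-variant inclusion probabilities sum configuration
posteriors; CLPP is the product of the two traits' inclusions, and the
locus CLPP aggregates per-variant CLPPs by max (matching the per-variant
threshold semantics of the decision rule; sum aggregation is available).
Defaults γ = 0.01, s = 5.2, matching the single-causal prior rate and
non-centrality scale conventional for this method. At |C| = 1 the BF
reduces to the Wakefield ABF with shrinkage s²/(1+s²) — the two routes
differ in priors, LD use and aggregation, not in the per-variant evidence
model.

The dual decision rule — PP.H4 > 0.8 **or** locus CLPP > 0.01, both
strict — deliberately ORs two methods with different prior assumptions;
the result records which route fired.

LD matrices validate symmetry, unit diagonal, |r| ≤ 1 and positive
semi-definiteness within 1e−8; a mildly indefinite matrix gets one ridge
repair (ε = 1e−6, renormalized to unit diagonal, recorded on the object)
and is rejected if still indefinite.

## Phenome-wide scan and permutation screen

The phenome scan is the same Wald machinery with Bonferroni at
0.05/n_outcomes. The permutation screen ranks the target's evidence per
outcome against N background pQTL: the ranking statistic is |z| =
|θ̂/se(θ̂)| because raw ratio estimates are not comparable across proteins
with different instrument strengths and outcome units (ranking on |θ̂| is
available behind a flag). With the target included in its own null,
p_perm = rank/(N+1), descending, ties counted against the target; the
smallest attainable p is 1/(N+1) — with N = 499 the granularity is 0.002,
so a second-place target reports p = 0.004. Outcomes covered by fewer
than half the background pQTL are excluded. BH-FDR is the vectorized
step-up q_(i) = min_{j≥i} p_(j)·m/j, capped at 1, order-restored
(implemented directly so out-of-range p-values error loudly; tests
cross-check against statsmodels).

## Pipeline

`run_pipeline` chains the stages with one master seed split into
per-stage child seeds (SeedSequence), so runs are byte-identical given
the config and individual stages reproducible in isolation. In the
phewas stage the synthetic phenome is one MVN(0, R) z-draw per outcome at
the target locus; background-pQTL outcome effects are marginal N(0,1)
z-draws at the background instrument — statistically identical to full
locus draws under the null and far cheaper. The background pool is capped
at the available instruments when the configured N = 500 exceeds it (a
desk-scale proteome has ~100). The manifest enforces filter-chain
monotonicity (instruments ≥ Bonferroni passes ≥ colocalized loci) and is
written last, after every result table.

## Known limitations

* Single-instrument MR only: no IVW/Egger/median estimators, no Steiger
  filtering, no winner's-curse correction.
* Colocalization assumes at most one causal variant per trait (ABF route)
  or at most `max_causal` ∈ {1,2} (CLPP route); no sampling-based
  fine-mapping for higher causal counts.
* The simulator's LD is also the analysis LD; sensitivity to LD-panel
  mismatch is untested by design.
* The permutation screen's resolution is bounded by the background count;
  with few background pQTL, BH-FDR q-values cannot be small even for
  rank-1 hits.
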