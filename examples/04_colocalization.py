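"""Dual colocalization of a shared-causal locus and a linkage locus.

Runs both evidence routes — ABF hypothesis posteriors (PP.H0-PP.H4) and
eCAVIAR-style per-variant CLPP — on a locus where protein and outcome share
one causal variant, and on a locus where two different variants drive them.
"""

from pqtlmr import (
    SyntheticScenario,
    coloc_pp,
    colocalizes,
    ecaviar_clpp,
    simulate_locus_pair,
)

for scenario in ("shared", "distinct"):
    lp = simulate_locus_pair(
        SyntheticScenario(scenario=scenario, m=100, target_f=150.0, theta=0.3, seed=19)
    )
    cres = coloc_pp(
        [(r.beta, r.se) for r in lp.exposure],
        [(r.beta, r.se) for r in lp.outcome],
    )
    eres = ecaviar_clpp(
        [r.z for r in lp.exposure], [r.z for r in lp.outcome], lp.ld
    )
    decision, reason = colocalizes(cres, eres, ppa_min=0.8, clpp_min=0.01)
    print(f"--- {scenario} scenario ---")
    print("  PP.H0..H4 :", "  ".join(f"{p:.3f}" for p in (
        cres.pp_h0, cres.pp_h1, cres.pp_h2, cres.pp_h3, cres.pp_h4)))
    print(f"  locus CLPP: {eres.locus_clpp:.4g}")
    print(f"  decision  : {decision} ({reason})")
print()
print("A shared causal variant concentrates posterior mass on H4 and gives a")
print("large CLPP; two distinct causal variants in low LD load H3 instead —")
print("association at the locus driven by linkage, not a shared variant.")
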