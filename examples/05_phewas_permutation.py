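"""Phenome-wide MR of one protein with the rank-permutation screen.

Scans a target instrument across 300 synthetic null outcomes, then ranks
its evidence per outcome against 99 background pQTL. One outcome is given a
real (injected) effect to show how the screen surfaces it; BH-FDR q-values
quantify the multiplicity burden.
"""

import numpy as np

from pqtlmr import (
    Instrument,
    SyntheticScenario,
    bh_fdr,
    permutation_rank_p,
    simulate_locus_pair,
    wald_ratio,
)

rng = np.random.default_rng(23)
lp = simulate_locus_pair(SyntheticScenario(scenario="shared", m=50, target_f=150.0, seed=23))
instr = Instrument.from_record("TARGET", lp.exposure[lp.truth.causal_exposure_index])

n_outcomes, n_bg = 300, 99
outcome_ids = [f"o{k:03d}" for k in range(n_outcomes)]

def null_estimate(who, oid, z):
    return wald_ratio(who, float(z) * 0.02, 0.02, oid)

target = {
    oid: null_estimate(instr, oid, z)
    for oid, z in zip(outcome_ids, rng.standard_normal(n_outcomes))
}
target["o000"] = null_estimate(instr, "o000", 5.5)  # injected pleiotropic effect

background = {
    f"B{b}": {
        oid: null_estimate(instr, oid, z)
        for oid, z in zip(outcome_ids, rng.standard_normal(n_outcomes))
    }
    for b in range(n_bg)
}

rows = permutation_rank_p(target, background)
flagged = sorted(
    (r for r in rows if r.p_permuted < 0.05), key=lambda r: r.p_permuted
)
print(f"outcomes scanned         : {len(rows)}")
print(f"flagged (p_permuted<0.05): {len(flagged)}")
for r in flagged[:5]:
    print(f"  {r.outcome_id}: |z| {r.target_statistic:.2f}  rank {r.rank}/"
          f"{r.n_background + 1}  p_permuted {r.p_permuted:.4f}  q {r.q_fdr:.3f}")
print()
print(f"power floor: min attainable p = 1/(N+1) = {1 / (n_bg + 1):.3f}")
print("The injected effect ranks first among the background pQTL. Because the")
print("rank p cannot go below 1/(N+1), BH-FDR q-values stay modest even for")
print("the top hit — flagged outcomes are candidates that the follow-up")
print("colocalization step must then adjudicate.")
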