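"""Tests of the summary-level locus simulator against its stated model."""

import numpy as np
import pytest

from pqtlmr.datatypes import pvalue_from_z
from pqtlmr.simulate import (
    AR1Structure,
    BlockStructure,
    SyntheticScenario,
    simulate_ld_matrix,
    simulate_locus_pair,
    simulate_proteome_study,
)


class TestLDStructures:
    def test_zero_correlation_gives_identity(self):
        ld = simulate_ld_matrix(3, AR1Structure(0.0))
        assert np.array_equal(ld.r, np.eye(3))

    def test_ar1_closed_form(self):
        ld = simulate_ld_matrix(3, AR1Structure(0.8))
        expected = np.array([[1, 0.8, 0.64], [0.8, 1, 0.8], [0.64, 0.8, 1]])
        np.testing.assert_allclose(ld.r, expected, atol=1e-12)

    def test_blocks_have_zero_cross_entries(self):
        ld = simulate_ld_matrix(50, BlockStructure((25, 25), 0.9))
        assert np.all(ld.r[:25, 25:] == 0)
        assert np.all(ld.r[:25, :25][~np.eye(25, dtype=bool)] == 0.9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_ld_matrix(0, AR1Structure(0.5))
        with pytest.raises(ValueError):
            AR1Structure(1.0)
        with pytest.raises(ValueError):
            simulate_ld_matrix(5, BlockStructure((2, 2), 0.5))


class TestLocusPair:
    def test_deterministic_given_seed(self):
        scn = SyntheticScenario(m=30, seed=42)
        a = simulate_locus_pair(scn)
        b = simulate_locus_pair(SyntheticScenario(m=30, seed=42))
        assert [r.beta for r in a.exposure] == [r.beta for r in b.exposure]
        assert [r.pvalue for r in a.outcome] == [r.pvalue for r in b.outcome]

    def test_scenario_index_consistency_enforced(self):
        with pytest.raises(ValueError):
            SyntheticScenario(
                scenario="shared", m=10,
                causal_exposure_index=2, causal_outcome_index=3,
            )
        with pytest.raises(ValueError):
            SyntheticScenario(
                scenario="distinct", m=10,
                causal_exposure_index=2, causal_outcome_index=2,
            )
        with pytest.raises(ValueError):
            SyntheticScenario(m=10, maf_range=(0.01, 0.5))

    def test_stored_pvalues_match_beta_over_se(self):
        lp = simulate_locus_pair(SyntheticScenario(m=40, seed=5))
        for rec in lp.exposure + lp.outcome:
            expected = float(pvalue_from_z(rec.beta / rec.se))
            if expected > 1e-290:
                assert rec.pvalue == pytest.approx(expected, rel=1e-6)

    def test_null_scenario_pvalues_uniform(self):
        # Monte-Carlo check: fraction of p < 0.05 near 0.05 under the null.
        hits = total = 0
        for seed in range(500):
            lp = simulate_locus_pair(
                SyntheticScenario(scenario="null", m=20, seed=seed)
            )
            ps = [r.pvalue for r in lp.outcome]
            hits += sum(p < 0.05 for p in ps)
            total += len(ps)
        assert 0.03 <= hits / total <= 0.07

    def test_exposure_only_outcome_z_standard_normal(self):
        zs = []
        for seed in range(300):
            lp = simulate_locus_pair(
                SyntheticScenario(scenario="exposure_only", m=15, seed=seed)
            )
            zs.append(lp.outcome[lp.truth.causal_exposure_index].z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 3.0 / np.sqrt(len(zs))
        assert 0.85 <= zs.std() <= 1.15

    def test_null_outcome_z_covariance_converges_to_ld(self):
        m, reps = 6, 1000
        zmat = np.empty((reps, m))
        for seed in range(reps):
            lp = simulate_locus_pair(
                SyntheticScenario(scenario="null", m=m, seed=seed,
                                  ld_structure=AR1Structure(0.6))
            )
            zmat[seed] = [r.z for r in lp.outcome]
        emp = np.cov(zmat, rowvar=False)
        expected = simulate_ld_matrix(m, AR1Structure(0.6)).r
        assert np.max(np.abs(emp - expected)) < 0.1

    def test_shared_scenario_wald_recovery(self):
        # Parameter recovery: Wald ratio at the causal variant ~ theta.
        ratios = []
        for seed in range(200):
            scn = SyntheticScenario(
                scenario="shared", m=25, target_f=100.0, theta=0.3, seed=seed
            )
            lp = simulate_locus_pair(scn)
            ci = lp.truth.causal_exposure_index
            ratios.append(lp.outcome[ci].beta / lp.exposure[ci].beta)
        assert np.mean(ratios) == pytest.approx(0.3, rel=0.10)

    def test_wald_bias_shrinks_with_exposure_sample_size(self):
        # Consistency: weak-instrument bias decreases as n_exposure grows.
        biases = {}
        for n_exp in (144, 2000):
            ratios = []
            for seed in range(300):
                scn = SyntheticScenario(
                    scenario="shared", m=10, beta_exposure=0.8, theta=0.3,
                    n_exposure=n_exp, seed=seed,
                )
                lp = simulate_locus_pair(scn)
                ci = lp.truth.causal_exposure_index
                ratios.append(lp.outcome[ci].beta / lp.exposure[ci].beta)
            biases[n_exp] = abs(np.mean(ratios) - 0.3)
        assert biases[2000] < 0.015
        assert biases[2000] <= biases[144] + 0.01

    def test_case_control_se_scaling(self):
        scn_cc = SyntheticScenario(
            scenario="null", m=5, seed=1,
            outcome_trait_type="case_control", case_fraction=0.2,
        )
        scn_q = SyntheticScenario(scenario="null", m=5, seed=1)
        cc = simulate_locus_pair(scn_cc).outcome
        q = simulate_locus_pair(scn_q).outcome
        scale = 1.0 / np.sqrt(0.2 * 0.8)
        for rcc, rq in zip(cc, q):
            assert rcc.se == pytest.approx(rq.se * scale, rel=1e-12)


class TestProteomeStudy:
    def test_empty(self):
        study = simulate_proteome_study(0, {"null": 1.0})
        assert len(study) == 0

    def test_allocation_exact(self):
        base = SyntheticScenario(m=10)
        study = simulate_proteome_study(
            100, {"shared": 0.1, "null": 0.9}, base, seed=1
        )
        labels = [lp.truth.scenario for lp in study]
        assert labels.count("shared") == 10
        assert labels.count("null") == 90

    def test_determinism(self):
        base = SyntheticScenario(m=10)
        a = simulate_proteome_study(20, {"shared": 0.5, "null": 0.5}, base, seed=7)
        b = simulate_proteome_study(20, {"shared": 0.5, "null": 0.5}, base, seed=7)
        for la, lb in zip(a, b):
            assert [r.beta for r in la.exposure] == [r.beta for r in lb.exposure]

    def test_truth_retrievable_and_consistent(self):
        base = SyntheticScenario(m=10, theta=0.4, beta_exposure=1.2)
        study = simulate_proteome_study(10, {"shared": 1.0}, base, seed=3)
        t = study.truth_for("P0003")
        assert t.scenario == "shared"
        assert t.beta_outcome_causal == pytest.approx(0.4 * t.beta_exposure_causal)
        with pytest.raises(KeyError):
            study.truth_for("nope")

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome_study(10, {"shared": 0.5, "null": 0.4})
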