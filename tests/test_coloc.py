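"""Colocalization: Wakefield ABFs, hypothesis posteriors, CLPP — each checked
against an independent brute-force enumeration oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from pqtlmr.coloc import (
    CLPPResult,
    ColocPriors,
    ColocResult,
    W_QUANTITATIVE,
    coloc_pp,
    colocalizes,
    ecaviar_clpp,
    log_abf,
)

from conftest import ld_from, random_correlation_matrix


# ---------------------------------------------------------------------------
# independent oracles (plain-float loops, no log-space tricks)

def oracle_log_abf(beta, se, w):
    """Wakefield ABF as the ratio of marginal to null densities of beta."""
    num = stats.norm.logpdf(beta, loc=0, scale=math.sqrt(se**2 + w**2))
    den = stats.norm.logpdf(beta, loc=0, scale=se)
    return num - den


def oracle_coloc(locus1, locus2, priors, w1, w2):
    """Enumerate all (m+1)^2 single-causal configurations directly."""
    bf1 = [math.exp(log_abf(b, s, w1)) for b, s in locus1]
    bf2 = [math.exp(log_abf(b, s, w2)) for b, s in locus2]
    m = len(bf1)
    w = {"h0": 1.0, "h1": 0.0, "h2": 0.0, "h3": 0.0, "h4": 0.0}
    for i in range(m):
        w["h1"] += priors.p1 * bf1[i]
        w["h2"] += priors.p2 * bf2[i]
        w["h4"] += priors.p12 * bf1[i] * bf2[i]
    for i in range(m):
        for j in range(m):
            if i != j:
                w["h3"] += priors.p1 * priors.p2 * bf1[i] * bf2[j]
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def oracle_inclusion(z, sigma, gamma, ncp_sd, max_causal):
    """Posterior inclusion probabilities by full MVN density enumeration."""
    import itertools

    m = len(z)
    configs = [()] + [(i,) for i in range(m)]
    if max_causal >= 2:
        configs += list(itertools.combinations(range(m), 2))
    ridge = sigma + 1e-12 * np.eye(m)
    log_weights = []
    for c in configs:
        cov = ridge.copy()
        if c:
            u = sigma[:, list(c)]
            cov = cov + ncp_sd**2 * u @ u.T
        logpdf = stats.multivariate_normal.logpdf(z, mean=np.zeros(m), cov=cov)
        logprior = len(c) * math.log(gamma) + (m - len(c)) * math.log(1 - gamma)
        log_weights.append(logprior + logpdf)
    log_weights = np.array(log_weights)
    weights = np.exp(log_weights - log_weights.max())
    weights /= weights.sum()
    incl = np.zeros(m)
    for wgt, c in zip(weights, configs):
        for i in c:
            incl[i] += wgt
    return incl


# ---------------------------------------------------------------------------

class TestLogABF:
    def test_zero_signal_is_negative(self):
        w, se = 0.15, 0.1
        r = w**2 / (w**2 + se**2)
        assert log_abf(0.0, se, w) == pytest.approx(0.5 * math.log(1 - r))
        assert log_abf(0.0, se, w) < 0

    def test_degenerate_prior_limit(self):
        assert log_abf(0.5, 0.1, 0.0) == 0.0
        assert abs(log_abf(0.5, 0.1, 1e-9)) < 1e-12

    def test_matches_density_ratio_oracle(self):
        for beta, se, w in [(0.5, 0.1, 0.15), (-0.2, 0.05, 0.2), (0.0, 1.0, 0.15),
                            (1.3, 0.4, 0.15)]:
            assert log_abf(beta, se, w) == pytest.approx(
                oracle_log_abf(beta, se, w), abs=1e-10
            )

    def test_monotone_in_abs_z(self):
        vals = [log_abf(b, 0.1, 0.15) for b in np.linspace(0, 1, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0, 0.15)


class TestColocPP:
    def test_single_variant_h3_exactly_zero(self):
        res = coloc_pp([(0.5, 0.1)], [(0.4, 0.1)])
        assert res.pp_h3 == 0.0
        assert res.n_variants == 1

    def test_all_null_gives_h0(self):
        res = coloc_pp([(0.0, 1.0)] * 5, [(0.0, 1.0)] * 5)
        assert res.pp_h0 > 0.99

    def test_enumeration_oracle_m3(self):
        z1, z2 = (6.0, 1.0, 0.0), (6.0, 0.0, 1.0)
        locus1 = [(z, 1.0) for z in z1]
        locus2 = [(z, 1.0) for z in z2]
        priors = ColocPriors()
        res = coloc_pp(locus1, locus2, priors, 0.15, 0.15)
        exp = oracle_coloc(locus1, locus2, priors, 0.15, 0.15)
        for k in ("h0", "h1", "h2", "h3", "h4"):
            assert getattr(res, f"pp_{k}") == pytest.approx(exp[k], abs=1e-12)

    def test_enumeration_oracle_random(self, rng):
        priors = ColocPriors()
        for _ in range(25):
            # moderate z so the plain-float oracle cannot overflow
            m = int(rng.integers(1, 11))
            locus1 = [(float(rng.normal(0, 2)), float(rng.uniform(0.3, 1))) for _ in range(m)]
            locus2 = [(float(rng.normal(0, 2)), float(rng.uniform(0.3, 1))) for _ in range(m)]
            res = coloc_pp(locus1, locus2, priors)
            exp = oracle_coloc(locus1, locus2, priors, W_QUANTITATIVE, W_QUANTITATIVE)
            for k in ("h0", "h1", "h2", "h3", "h4"):
                assert getattr(res, f"pp_{k}") == pytest.approx(exp[k], abs=1e-10)

    def test_probabilities_sum_to_one_and_order_invariant(self, rng):
        m = 7
        locus1 = [(float(rng.normal(0, 2)), 0.3) for _ in range(m)]
        locus2 = [(float(rng.normal(0, 2)), 0.3) for _ in range(m)]
        res = coloc_pp(locus1, locus2)
        total = res.pp_h0 + res.pp_h1 + res.pp_h2 + res.pp_h3 + res.pp_h4
        assert total == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(m)
        res_p = coloc_pp([locus1[i] for i in perm], [locus2[i] for i in perm])
        assert res_p.pp_h4 == pytest.approx(res.pp_h4, abs=1e-12)
        assert res_p.pp_h3 == pytest.approx(res.pp_h3, abs=1e-12)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            coloc_pp([(0.1, 0.1)], [(0.1, 0.1), (0.2, 0.1)])

    def test_invalid_priors(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)


class TestEcaviarCLPP:
    def test_single_variant_strong_signal(self):
        ld = ld_from(np.eye(1))
        res = ecaviar_clpp([8.0], [8.0], ld)
        assert res.inclusion_trait1[0] > 0.99
        assert res.inclusion_trait2[0] > 0.99
        assert res.locus_clpp > 0.98

    def test_perfect_ld_symmetry(self):
        ld = ld_from(np.array([[1.0, 1.0], [1.0, 1.0]]))
        res = ecaviar_clpp([5.0, 5.0], [4.0, 4.0], ld)
        assert res.inclusion_trait1[0] == pytest.approx(res.inclusion_trait1[1], abs=1e-12)
        assert res.clpp[0] == pytest.approx(res.clpp[1], abs=1e-12)

    @pytest.mark.parametrize("max_causal", [1, 2])
    def test_enumeration_oracle_random(self, rng, max_causal):
        for _ in range(20):
            m = int(rng.integers(2, 11))
            sigma = random_correlation_matrix(m, rng)
            ld = ld_from(sigma)
            z1 = rng.normal(0, 3, m)
            z2 = rng.normal(0, 3, m)
            res = ecaviar_clpp(z1, z2, ld, max_causal=max_causal)
            e1 = oracle_inclusion(z1, ld.r, 0.01, 5.2, max_causal)
            e2 = oracle_inclusion(z2, ld.r, 0.01, 5.2, max_causal)
            np.testing.assert_allclose(res.inclusion_trait1, e1, atol=1e-10)
            np.testing.assert_allclose(res.inclusion_trait2, e2, atol=1e-10)
            np.testing.assert_allclose(res.clpp, e1 * e2, atol=1e-10)

    def test_clpp_monotone_in_shared_signal(self, rng):
        m = 12
        sigma = random_correlation_matrix(m, rng)
        ld = ld_from(sigma)
        z1 = rng.normal(0, 1, m)
        z2 = rng.normal(0, 1, m)
        prev = -1.0
        for boost in (2.0, 4.0, 6.0, 9.0):
            a, b = z1.copy(), z2.copy()
            a[3], b[3] = boost, boost
            res = ecaviar_clpp(a, b, ld)
            assert res.clpp[3] >= prev
            prev = res.clpp[3]

    def test_per_variant_clpp_below_inclusions(self, rng):
        m = 8
        ld = ld_from(random_correlation_matrix(m, rng))
        res = ecaviar_clpp(rng.normal(0, 2, m), rng.normal(0, 2, m), ld)
        assert np.all(res.clpp <= np.minimum(res.inclusion_trait1, res.inclusion_trait2) + 1e-12)
        assert 0.0 <= res.locus_clpp <= 1.0

    def test_unsupported_settings(self):
        ld = ld_from(np.eye(2))
        with pytest.raises(ValueError):
            ecaviar_clpp([1.0, 1.0], [1.0, 1.0], ld, max_causal=3)
        with pytest.raises(ValueError):
            ecaviar_clpp([1.0], [1.0], ld)


class TestDecisionRule:
    def _clpp(self, locus_clpp):
        return CLPPResult(["v0"], np.array([1.0]), np.array([1.0]),
                          np.array([locus_clpp]), locus_clpp)

    def test_coloc_only(self):
        c = ColocResult(0.05, 0.05, 0.02, 0.03, 0.85, 10)
        assert colocalizes(c, self._clpp(0.001)) == (True, "coloc_only")

    def test_ecaviar_only(self):
        c = ColocResult(0.1, 0.1, 0.1, 0.2, 0.5, 10)
        assert colocalizes(c, self._clpp(0.02)) == (True, "ecaviar_only")

    def test_boundaries_strict(self):
        c = ColocResult(0.05, 0.05, 0.05, 0.05, 0.8, 10)
        decision, reason = colocalizes(c, self._clpp(0.01))
        assert decision is False and reason == "none"

    def test_weak_evidence_rejected(self):
        # The pattern of a permutation-flagged locus failing follow-up
        # colocalization (PPA ~ 0.127, CLPP ~ 2.9e-4).
        c = ColocResult(0.4, 0.2, 0.173, 0.1, 0.127, 50)
        decision, reason = colocalizes(c, self._clpp(2.92e-4))
        assert decision is False and reason == "none"
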