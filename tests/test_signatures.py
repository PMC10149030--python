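"""Moderated t, threshold test, BH adjustment and signature derivation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epipanel.signatures import (GeneSignature, PriorEstimationError,
                                 VariancePrior, bh_adjust, derive_signatures,
                                 estimate_prior, moderated_t_de, treat_pvalue)
from epipanel.simulate import CohortSimConfig, simulate_cohort


def _random_expr(rng, n_genes=200, na=6, nb=8):
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    return (pd.DataFrame(rng.normal(size=(n_genes, na + nb)), columns=cols),
            cols[:na], cols[na:])


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self, rng):
        """With no prior weight the moderated statistic IS the pooled
        two-sample t-test, gene by gene."""
        expr, ga, gb = _random_expr(rng)
        de = moderated_t_de(expr, ga, gb, prior=VariancePrior(0.0, 1.0))
        ref = stats.ttest_ind(expr[ga], expr[gb], axis=1, equal_var=True)
        assert np.allclose(de["t"], ref.statistic, atol=1e-10)
        assert np.allclose(de["p"], ref.pvalue, atol=1e-10)

    def test_equal_means_give_null_result(self):
        expr = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"],
                            columns=["a1", "a2", "b1", "b2"])
        for d0 in (0.0, 5.0, math.inf):
            de = moderated_t_de(expr, ["a1", "a2"], ["b1", "b2"],
                                prior=VariancePrior(d0, 0.5))
            assert de.loc["g", "logfc"] == 0
            assert de.loc["g", "t"] == 0
            assert de.loc["g", "p"] == pytest.approx(1.0)

    def test_limits_ordinary_t_and_fixed_variance_z(self, rng):
        """d0 -> 0 recovers the ordinary t; d0 -> inf the fixed-variance
        z-test with variance s0^2."""
        expr, ga, gb = _random_expr(rng, n_genes=50)
        tiny = moderated_t_de(expr, ga, gb, prior=VariancePrior(1e-9, 0.7))
        plain = moderated_t_de(expr, ga, gb, prior=VariancePrior(0.0, 0.7))
        assert np.allclose(tiny["t"], plain["t"], rtol=1e-6)

        huge = moderated_t_de(expr, ga, gb, prior=VariancePrior(1e9, 0.7))
        scale = math.sqrt(0.7) * math.sqrt(1 / len(ga) + 1 / len(gb))
        z = tiny["logfc"] / scale
        assert np.allclose(huge["t"], z, rtol=1e-6)
        pz = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(huge["p"], pz, rtol=1e-5)

    def test_zero_variance_flagged_without_prior(self):
        expr = pd.DataFrame([[1.0, 1.0, 2.0, 2.0]], index=["g"],
                            columns=["a1", "a2", "b1", "b2"])
        de = moderated_t_de(expr, ["a1", "a2"], ["b1", "b2"],
                            prior=VariancePrior(0.0, 1.0))
        assert np.isnan(de.loc["g", "t"])
        assert np.isnan(de.loc["g", "p"])

    def test_small_groups_rejected(self, rng):
        expr, ga, gb = _random_expr(rng, n_genes=10)
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t_de(expr, ga[:1], gb)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_d0(self):
        s2 = np.full(200, 0.3)
        prior = estimate_prior(s2, np.full(200, 1000.0))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.3, rel=0.01)

    def test_scale_equivariance(self, rng):
        d = np.full(500, 8.0)
        s2 = 0.1 * rng.chisquare(8, 500) / 8
        p1 = estimate_prior(s2, d)
        p2 = estimate_prior(2 * s2, d)
        assert p2.s0_sq == pytest.approx(2 * p1.s0_sq, rel=1e-8)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-6)

    def test_parameter_recovery(self, rng):
        """Two-level simulation: gene variances from a scaled-inverse-chi2
        prior (d0=4, s0^2=0.05), then chi2 sampling noise at 10 df."""
        n, d = 5000, 10.0
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, np.full(n, d))
        assert prior.d0 == pytest.approx(4.0, rel=0.20)
        assert prior.s0_sq == pytest.approx(0.05, rel=0.10)

    def test_too_few_genes(self):
        with pytest.raises(PriorEstimationError, match="fixed prior"):
            estimate_prior(np.full(10, 1.0), np.full(10, 4.0))


class TestTreatPvalue:
    def test_tau_zero_reduces_to_two_sided_t(self):
        for fc, se, df in [(1.2, 0.4, 10.0), (-0.3, 0.1, 25.0)]:
            p = treat_pvalue(fc, se, df, tau=0.0)
            ref = 2 * stats.t.sf(abs(fc) / se, df)
            assert p == pytest.approx(ref, rel=1e-12)

    def test_boundary_limit_half(self):
        # |logFC| = tau: first term is exactly 0.5, so p -> 0.5 from above
        # as the second tail (|logFC|+tau)/se grows
        p = treat_pvalue(1.0, 1.0 / 3.0, math.inf, tau=1.0)
        assert 0.5 < p < 0.5 + 1e-8
        p_far = treat_pvalue(1.0, 1e-3, math.inf, tau=1.0)
        assert p_far == pytest.approx(0.5, abs=1e-12) and p_far >= 0.5

    def test_closed_form_normal_example(self):
        p = treat_pvalue(2.0, 0.5, math.inf, tau=1.0)
        expected = stats.norm.sf(2.0) + stats.norm.sf(6.0)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_effect_and_threshold(self):
        ps = [treat_pvalue(fc, 0.5, 20.0, tau=1.0)
              for fc in np.linspace(0, 4, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        ps = [treat_pvalue(2.0, 0.5, 20.0, tau=t)
              for t in np.linspace(0, 3, 15)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_invalid_se(self):
        with pytest.raises(ValueError, match="se"):
            treat_pvalue(1.0, 0.0, 10.0, tau=0.5)


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_monotone_in_sorted_order(self, rng):
        # note BH is NOT idempotent in general ([0.2, 0.9] -> [0.4, 0.9]
        # -> [0.8, 0.9]); the guaranteed property is step-up monotonicity
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 60))
            assert np.allclose(bh_adjust(p),
                               multipletests(p, method="fdr_bh")[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=25),
       st.randoms(use_true_random=False))
def test_bh_permutation_equivariance_and_bounds(p, rand):
    """BH adjustment commutes with reordering and stays within [p, 1]."""
    p = np.asarray(p)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
    perm = list(range(len(p)))
    rand.shuffle(perm)
    assert np.allclose(bh_adjust(p[perm]), adj[perm])


class TestDeriveSignatures:
    def test_recovers_planted_up_genes(self):
        """>=90% of planted subtype genes land in the correct up set with
        <=1% contamination, at a threshold below the planted effect."""
        for seed in (0, 1):
            bundle, truth = simulate_cohort(CohortSimConfig(
                n_tumors_per_subtype=100, n_normals=10, n_genes=2000,
                n_signature_genes=200, signature_effect=1.0, seed=seed))
            labels = bundle.labeled_tumors()
            sigs = derive_signatures(bundle.expression[labels.index], labels,
                                     logfc_threshold=0.25)
            for s in "123":
                planted = set(truth.signature_genes[s])
                assert len(sigs[s].up & planted) >= 0.90 * len(planted)
                assert len(sigs[s].up - planted) <= 0.01 * len(planted)

    def test_permuted_labels_give_empty_signatures(self, small_cohort, rng):
        bundle, _ = small_cohort
        labels = bundle.labeled_tumors()
        sizes = []
        for _ in range(10):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            sigs = derive_signatures(bundle.expression[labels.index], perm,
                                     logfc_threshold=0.25)
            sizes.append(sum(len(s.up) + len(s.down) for s in sigs.values()))
        assert np.mean(sizes) <= 0.01 * bundle.expression.shape[0]

    def test_deterministic(self, small_cohort):
        bundle, _ = small_cohort
        labels = bundle.labeled_tumors()
        s1 = derive_signatures(bundle.expression[labels.index], labels,
                               logfc_threshold=0.5)
        s2 = derive_signatures(bundle.expression[labels.index], labels,
                               logfc_threshold=0.5)
        for k in s1:
            assert s1[k].up == s2[k].up and s1[k].down == s2[k].down

    def test_signature_usability(self):
        assert not GeneSignature("1").usable
        assert GeneSignature("1", up={"a"}).usable
        assert not GeneSignature("1", up={"a"}, down={"a"}).usable
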