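"""HMP statistic, decisions, multilevel subsets, posteriors, comparators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from harmonicp import (
    Subset,
    WeightedPValues,
    bh_rejections,
    bonferroni_combined,
    comparator_tests,
    direct_test,
    exact_test,
    fisher_combined,
    harmonic_mean_p,
    hmp_null,
    mean_max_lr,
    model_posteriors,
    multilevel_test,
    simes_combined,
    threshold,
)
from oracles import hmp_exact_fraction

pvec = st.lists(
    st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=30
).map(np.asarray)


def _pv(p, w=None):
    return WeightedPValues(np.asarray(p, dtype=float), w=w)


class TestHarmonicMean:
    def test_identical_values(self):
        assert harmonic_mean_p(_pv([0.1] * 4)) == pytest.approx(0.1, rel=1e-15)

    def test_two_term_closed_form(self):
        assert harmonic_mean_p(_pv([0.01, 1.0])) == pytest.approx(2 / 101, rel=1e-15)

    def test_matches_rational_arithmetic_oracle(self):
        p = [i / 20 for i in range(1, 11)]
        expect = float(hmp_exact_fraction(p))
        assert harmonic_mean_p(_pv(p)) == pytest.approx(expect, rel=1e-14)

    def test_weighted_matches_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(1, 12)
            p = rng.uniform(1e-6, 1.0, n)
            w = rng.uniform(0.1, 2.0, n)
            with pytest.warns(UserWarning):
                pv = _pv(p, w=w)
            expect = float(hmp_exact_fraction(p.tolist(), (w / w.sum()).tolist()))
            assert harmonic_mean_p(pv) == pytest.approx(expect, rel=1e-12)

    def test_subset_selection(self):
        pv = _pv([0.5, 0.01, 1.0, 0.2])
        sub = Subset(indices=(1, 2))
        assert harmonic_mean_p(pv, sub) == pytest.approx(
            0.5 / (0.25 / 0.01 + 0.25 / 1.0), rel=1e-15
        )

    def test_no_overflow_at_smallest_normal(self):
        tiny = np.finfo(float).tiny
        v = harmonic_mean_p(_pv([tiny, 0.5]))
        assert 0.0 < v < 1.0 and np.isfinite(v)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2, 0.5], [-0.1], [np.nan]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            _pv(bad)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            Subset(indices=())

    def test_out_of_bounds_subset_rejected(self):
        with pytest.raises(IndexError):
            harmonic_mean_p(_pv([0.5, 0.5]), Subset(indices=(5,)))

    @given(pvec)
    def test_mean_inequality_bounds(self, p):
        """min p <= HMP <= arithmetic mean (classical mean inequality)."""
        h = harmonic_mean_p(_pv(p))
        assert p.min() <= h * (1 + 1e-12)
        assert h <= p.mean() * (1 + 1e-12)

    @given(pvec, st.integers(0, 29), st.floats(0.05, 0.9))
    def test_monotone_in_each_pvalue(self, p, i, shrink):
        """Decreasing any single p-value strictly decreases the HMP."""
        i = i % p.size
        q = p.copy()
        q[i] = p[i] * shrink
        assert harmonic_mean_p(_pv(q)) < harmonic_mean_p(_pv(p))

    @given(pvec, st.randoms(use_true_random=False))
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(p.size))
        rnd.shuffle(perm)
        assert harmonic_mean_p(_pv(p[perm])) == pytest.approx(
            harmonic_mean_p(_pv(p)), rel=1e-12
        )


class TestMeanMaxLR:
    def test_inverse_pvalue_case(self):
        """With R_i = 1/p_i (two-df tests), R-bar = 1/HMP exactly."""
        p = np.array([0.05, 0.5])
        assert mean_max_lr(1.0 / p) == pytest.approx(11.0, rel=1e-15)
        assert 1.0 / harmonic_mean_p(_pv(p)) == pytest.approx(11.0, rel=1e-15)

    def test_unit_ratios(self, rng):
        w = rng.uniform(0, 1, 7)
        assert mean_max_lr(np.ones(7), w) == pytest.approx(1.0, rel=1e-15)

    def test_matches_dot_product(self, rng):
        R = rng.uniform(0.1, 50, 9)
        w = rng.dirichlet(np.ones(9))
        assert mean_max_lr(R, w) == pytest.approx(float(np.dot(w, R)), rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mean_max_lr(np.array([1.0, 0.0]))

    @given(pvec)
    def test_identity_with_inverse_hmp(self, p):
        """1/HMP equals the equal-weight mean of the inverse p-values."""
        assert 1.0 / harmonic_mean_p(_pv(p)) == pytest.approx(
            mean_max_lr(1.0 / p), rel=1e-12
        )


class TestModelPosteriors:
    def test_two_tests(self):
        q = model_posteriors(_pv([0.01, 0.02]))
        np.testing.assert_allclose(q, [2 / 3, 1 / 3], rtol=1e-14)

    def test_symmetry(self):
        q = model_posteriors(_pv([0.3] * 5))
        np.testing.assert_allclose(q, np.full(5, 0.2), rtol=1e-14)

    def test_matches_brute_force(self, rng):
        p = rng.uniform(1e-4, 1, 8)
        w = rng.dirichlet(np.ones(8))
        pv = _pv(p, w=w)
        expect = (w / p) / (w / p).sum()
        np.testing.assert_allclose(model_posteriors(pv), expect, rtol=1e-12)
        assert model_posteriors(pv).sum() == pytest.approx(1.0, rel=1e-12)


class TestDecisions:
    def test_direct_examples(self):
        assert direct_test(0.04, wR=1.0, alpha=0.05)
        assert not direct_test(0.04, wR=0.5, alpha=0.05)

    def test_direct_boundary_rejects(self):
        assert direct_test(0.05 * 0.5, wR=0.5, alpha=0.05)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            direct_test(0.01, alpha=0.0)
        with pytest.raises(ValueError):
            direct_test(0.01, alpha=1.5)
        with pytest.warns(UserWarning, match="exceeds 0.05"):
            direct_test(0.01, alpha=0.2)

    def test_exact_at_printed_threshold_boundary(self):
        """hmp near 0.040 at L=10 sits at the alpha=0.05 rejection boundary."""
        t = threshold(10, 0.05)
        assert round(t, 3) == 0.040
        assert exact_test(t, 10, alpha=0.05).significant_exact
        assert not exact_test(t * 1.001, 10, alpha=0.05).significant_exact

    def test_exact_no_evidence(self):
        r = exact_test(1.0, 1000)
        assert r.exact_p > 0.9
        assert not r.significant_exact

    def test_exact_calibrated_when_small(self):
        """sf(1/p°) tracks p° itself for small HMPs (asymptotic calibration)."""
        r = exact_test(1e-4, 100)
        assert r.exact_p == pytest.approx(1e-4, rel=0.1)

    def test_formulations_agree(self, rng):
        """exact_p <= alpha*wR iff hmp <= the Landau threshold at level alpha*wR."""
        for _ in range(50):
            hmp = 10 ** rng.uniform(-5, 0)
            L = int(rng.choice([10, 100, 1000]))
            wR = rng.uniform(0.05, 1.0)
            r = exact_test(hmp, L, wR=wR, alpha=0.05)
            assert r.significant_exact == (hmp <= threshold(L, 0.05 * wR))

    def test_result_fields(self):
        r = exact_test(0.002, 50, wR=0.5, alpha=0.05, n=10, label="x")
        assert r.adjusted == pytest.approx(r.hmp / r.wR)
        assert r.adjusted >= r.hmp
        assert r.L_total == 50 and r.n == 10 and r.label == "x"


class TestMultilevel:
    def test_full_family_degenerate(self):
        pv = _pv(np.linspace(0.05, 0.9, 20))
        headline, results = multilevel_test(pv, [pv.full_subset()], alpha=0.05)
        assert results[0].hmp == pytest.approx(headline.hmp, rel=1e-14)
        assert results[0].exact_p == pytest.approx(headline.exact_p, rel=1e-12)

    def test_planted_signal_rejects_subset_and_headline(self, rng):
        p = rng.uniform(size=100)
        p[13] = 1e-6
        pv = _pv(p)
        sub = Subset(indices=tuple(range(10, 20)), label="hit")
        headline, results = multilevel_test(pv, [sub], alpha=0.05, method="exact")
        assert results[0].significant_exact
        assert headline.significant_exact
        # subset significance accompanied by headline significance (closure)
        headline_d, results_d = multilevel_test(pv, [sub], alpha=0.05, method="direct")
        assert results_d[0].significant_direct and headline_d.significant_direct

    def test_direct_closure_over_random_families(self, rng):
        """A rejected subset implies a rejected headline for the direct test."""
        for _ in range(200):
            L = int(rng.integers(5, 60))
            p = rng.uniform(size=L) ** rng.uniform(1, 6)
            k = int(rng.integers(1, L + 1))
            idx = tuple(rng.choice(L, size=k, replace=False))
            pv = _pv(p)
            headline, results = multilevel_test(
                pv, [Subset(indices=idx)], alpha=0.05, method="direct"
            )
            if results[0].significant_direct:
                assert headline.significant_direct

    def test_bad_method(self):
        with pytest.raises(ValueError):
            multilevel_test(_pv([0.5]), [], method="bayes")


class TestComparators:
    def test_singleton_identity(self):
        pv = _pv([0.01])
        res = comparator_tests(pv, alpha=0.05)
        assert res["bonferroni"]["statistic"] == pytest.approx(0.01)
        assert res["simes"]["statistic"] == pytest.approx(0.01)
        assert res["fisher"]["statistic"] == pytest.approx(0.01, rel=1e-10)
        assert res["bh"]["rejections"].tolist() == [0]

    def test_simes_hand_example(self):
        assert simes_combined([0.02, 0.03, 0.9]) == pytest.approx(0.045, rel=1e-14)

    def test_bonferroni_cap(self):
        assert bonferroni_combined([0.9, 0.8]) == 1.0

    def test_fisher_matches_scipy(self, rng):
        p = rng.uniform(size=12)
        _, expect = stats.combine_pvalues(p, method="fisher")
        assert fisher_combined(p) == pytest.approx(expect, rel=1e-12)

    def test_bh_stepup(self):
        # classic step-up: p_(k) <= alpha*k/L with the largest such k
        p = np.array([0.001, 0.012, 0.035, 0.04, 0.9])
        rej = bh_rejections(p, alpha=0.05)
        assert rej.tolist() == [0, 1, 2, 3]
        assert bh_rejections(np.array([0.5, 0.9]), 0.05).size == 0

    @given(pvec)
    def test_hmp_dominates_bonferroni_and_simes(self, p):
        """The HMP never exceeds the Bonferroni or Simes combined statistics."""
        h = harmonic_mean_p(_pv(p))
        assert h <= bonferroni_combined(p) * (1 + 1e-12)
        assert h <= simes_combined(p) * (1 + 1e-12)


class TestWeights:
    def test_default_equal(self):
        pv = _pv([0.1, 0.2, 0.3])
        np.testing.assert_allclose(pv.w, 1 / 3)

    def test_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            pv = _pv([0.1, 0.2], w=[2.0, 2.0])
        np.testing.assert_allclose(pv.w, 0.5)

    def test_negative_or_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            _pv([0.1, 0.2], w=[-1.0, 2.0])
        with pytest.raises(ValueError):
            _pv([0.1, 0.2], w=[0.0, 0.0])

    def test_subset_weight(self):
        with pytest.warns(UserWarning):
            pv = _pv([0.1, 0.2, 0.3], w=[1.0, 2.0, 3.0])
        assert pv.subset_weight(Subset(indices=(0, 2))) == pytest.approx(4 / 6)
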