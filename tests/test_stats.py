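"""Normality gating, paired tests, correction and correlation."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import megmapper as mm


def sample_from(diffs, base=1.0):
    diffs = np.asarray(diffs, dtype=float)
    return mm.PairedSample(
        subject_ids=[f"s{i}" for i in range(len(diffs))],
        score_a=base + diffs,
        score_b=np.full(len(diffs), base),
    )


def enumerate_sign_flip_p(diffs, alternative="two_sided"):
    """Oracle: explicit enumeration of all sign patterns."""
    diffs = np.asarray(diffs, dtype=float)
    mu = diffs.mean()
    means = [
        np.mean([s * d for s, d in zip(signs, diffs)])
        for signs in itertools.product((1, -1), repeat=len(diffs))
    ]
    p_g = np.mean([m >= mu - 1e-15 for m in means])
    p_l = np.mean([m <= mu + 1e-15 for m in means])
    if alternative == "two_sided":
        return min(1.0, 2 * min(p_l, p_g)), p_l, p_g
    return (p_g if alternative == "greater" else p_l), p_l, p_g


class TestPairedDifferences:
    def test_first_fixture_pair(self, table1):
        d = mm.paired_differences(table1)
        assert d[0] == pytest.approx(0.0557)

    def test_fixture_mean(self, table1):
        assert mm.paired_differences(table1).mean() == pytest.approx(0.0547, abs=5e-5)

    def test_equal_pairs_all_zero(self):
        assert np.all(mm.paired_differences(sample_from([0, 0, 0])) == 0)


class TestNormalityGate:
    def test_fixture_routes_to_permutation(self, table1):
        test_type, p = mm.normality_gate(mm.paired_differences(table1))
        assert test_type == "paired_permutation"
        assert round(p, 2) == 0.02

    def test_normal_draws_route_to_t_test(self):
        chosen = []
        for seed in range(100):
            d = np.random.default_rng(seed).normal(size=500)
            test_type, p = mm.normality_gate(d)
            # gate fidelity: branch must match the reference decision
            assert test_type == (
                "paired_permutation" if sps.shapiro(d).pvalue < 0.05 else "paired_t"
            )
            chosen.append(test_type)
        assert chosen.count("paired_t") >= 90

    def test_constant_vector_warns_and_permutes(self):
        test_type, p = mm.normality_gate(np.zeros(10))
        assert test_type == "paired_permutation"
        assert np.isnan(p)


class TestPairedTTest:
    def test_symmetric_jitter_p_near_one(self):
        s = sample_from([1e-6, -1e-6, 1e-6, -1e-6])
        assert mm.paired_t_test(s).p_raw > 0.5

    def test_known_statistic(self):
        # d = {1,2,3}: t = 2 / (1/sqrt(3)) = 3.4641, two-sided p ~ 0.0742
        res = mm.paired_t_test(sample_from([1, 2, 3]))
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-10)
        assert res.p_raw == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), df=2), rel=1e-10)
        assert res.p_raw == pytest.approx(0.0742, abs=5e-4)

    def test_swapping_conditions_negates_statistic(self):
        s = sample_from([0.5, 1.0, 1.5, 0.2])
        fwd = mm.paired_t_test(s)
        swapped = mm.PairedSample(
            subject_ids=s.subject_ids, score_a=s.score_b, score_b=s.score_a
        )
        rev = mm.paired_t_test(swapped)
        assert rev.statistic == pytest.approx(-fwd.statistic)
        assert rev.p_raw == pytest.approx(fwd.p_raw)

    def test_constant_differences_rejected(self):
        with pytest.raises(mm.UsageError):
            mm.paired_t_test(sample_from([1, 1, 1]))


class TestPairedPermutationTest:
    def test_exact_small_case(self):
        # 8 sign patterns; mu_obs = 2 is the unique maximum
        res = mm.paired_permutation_test(sample_from([1, 2, 3]), mode="exact")
        assert res.statistic == pytest.approx(2.0)
        assert res.p_g == pytest.approx(1 / 8)
        assert res.p_l == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(0.25)
        assert res.n_permutations == "exact"

    def test_all_zero_differences(self):
        res = mm.paired_permutation_test(sample_from([0, 0, 0]), mode="exact")
        assert res.p_l == res.p_g == 1.0
        assert res.p_raw == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=int(rng.integers(3, 9)))
        res = mm.paired_permutation_test(sample_from(d), mode="exact")
        expected, p_l, p_g = enumerate_sign_flip_p(d)
        assert res.p_raw == expected
        assert res.p_l == p_l and res.p_g == p_g

    def test_monte_carlo_within_three_se_of_exact(self):
        rng = np.random.default_rng(42)
        for _ in range(4):
            d = rng.normal(0.3, 1.0, size=int(rng.integers(5, 13)))
            exact = mm.paired_permutation_test(sample_from(d), mode="exact")
            mc = mm.paired_permutation_test(
                sample_from(d), mode="monte_carlo", n_perm=10_000, seed=int(rng.integers(2**31))
            )
            # two-sided p doubles the smaller tail, so its SE is 2x tail SE
            tail = min(exact.p_l, exact.p_g)
            se = 2 * np.sqrt(tail * (1 - tail) / 10_000)
            assert abs(mc.p_raw - exact.p_raw) <= 3 * max(se, 1e-4) + 2 / 10_001

    def test_two_sided_p_invariant_under_global_sign_flip(self):
        d = np.array([0.4, -0.1, 0.7, 0.2, -0.3])
        a = mm.paired_permutation_test(sample_from(d), mode="exact")
        b = mm.paired_permutation_test(sample_from(-d), mode="exact")
        assert a.p_raw == b.p_raw

    def test_fixture_swapped_permutation_statistic(self, table1):
        res = mm.paired_permutation_test(table1, seed=0)
        assert round(res.statistic, 4) == 0.0547
        # the printed permuted dataset: swap the three bolded subjects
        flip = np.array(
            [1 - 2 * (s in table1.swapped_subjects) for s in table1.subject_ids]
        )
        permuted_stat = (flip * mm.paired_differences(table1)).mean()
        assert round(permuted_stat, 4) == 0.0490

    def test_bad_n_perm_rejected(self):
        with pytest.raises(mm.UsageError):
            mm.paired_permutation_test(sample_from([1, 2]), mode="monte_carlo", n_perm=0)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 1, 0.2)])
    def test_values(self, p, m, expected):
        assert mm.bonferroni(p, m) == pytest.approx(expected)

    def test_monotone_in_family_size_and_capped(self):
        ps = [mm.bonferroni(0.02, m) for m in range(1, 100)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert max(ps) <= 1.0


class TestCompareParadigms:
    def _samples(self, rng, n_triples=3, n_subj=10, shift=0.0):
        out = {}
        for t in range(n_triples):
            a = rng.normal(0.5 + shift, 0.05, n_subj)
            b = rng.normal(0.5, 0.05, n_subj)
            out[(t, 50, 5)] = mm.PairedSample(
                subject_ids=[f"s{i}" for i in range(n_subj)], score_a=a, score_b=b
            )
        return out

    def test_clear_shift_satisfied(self):
        rng = np.random.default_rng(0)
        res = mm.compare_paradigms(self._samples(rng, shift=0.2), hypothesis="a_greater")
        assert res.satisfied
        assert res.n_satisfied == res.n_triples == 3
        for info in res.per_triple.values():
            assert info["test"].p_corrected <= 1.0
            assert info["direction"] == "a_greater"

    def test_wrong_direction_not_satisfied(self):
        rng = np.random.default_rng(0)
        res = mm.compare_paradigms(self._samples(rng, shift=0.2), hypothesis="b_greater")
        assert not res.satisfied

    def test_no_triples_rejected(self):
        with pytest.raises(mm.InsufficientDataError):
            mm.compare_paradigms({})

    def test_single_pair_sample_rejected(self):
        with pytest.raises(mm.UsageError):
            mm.PairedSample(subject_ids=["only"], score_a=[1.0], score_b=[2.0])

    def test_type_one_error_rate_under_null(self):
        # both conditions identical: rejection rate at alpha=0.05 must sit
        # near the nominal level
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.5, 0.05, 10)
            b = rng.normal(0.5, 0.05, 10)
            s = mm.PairedSample(subject_ids=[f"s{i}" for i in range(10)], score_a=a, score_b=b)
            result, _ = mm.run_paired_test(s, seed=seed)
            rejections += result.p_raw < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = mm.correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_shuffle_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = rng.permutation(x)
        r, _ = mm.correlate(x, y)
        assert abs(r) < 0.1

    def test_known_pearson_value(self):
        # oracle: direct covariance / variance arithmetic
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        expected = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        r, _ = mm.correlate(x, y)
        assert r == pytest.approx(expected) == pytest.approx(0.6)

    def test_spearman_available(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = mm.correlate(x, x**3, method="spearman")
        assert r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(mm.UsageError):
            mm.correlate([1, 1, 1], [1, 2, 3])
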