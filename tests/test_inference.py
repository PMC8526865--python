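import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lwl import inference as inf


def brute_force_signed_rank_p(values):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(values, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    n = len(d)
    vs = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    lower = (vs <= v_obs).mean()
    upper = (vs >= v_obs).mean()
    return min(1.0, 2 * min(lower, upper))


def grid_bf10_ttest(t, n, r_scale=inf.DEFAULT_T_SCALE, grid=20001):
    """Trapezoid oracle via the angle substitution delta = r * tan(u)."""
    nu = n - 1
    u = np.linspace(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6, grid)
    delta = r_scale * np.tan(u)
    dens = np.nan_to_num(stats.nct.pdf(t, nu, delta * math.sqrt(n)))  # far tails ~ 0
    num = np.trapezoid(dens / np.pi, u)
    return num / stats.t.pdf(t, nu)


def grid_bf10_corr(r, n, kappa=inf.DEFAULT_CORR_KAPPA, grid=40001, lo=-1.0, hi=1.0):
    """Trapezoid oracle over the stretched-beta prior on rho."""
    a = 1.0 / kappa
    rho = np.linspace(lo + 1e-9, hi - 1e-9, grid)
    from scipy import special

    like = ((1 - rho**2) ** ((n - 1) / 2) / (1 - rho * r) ** (n - 1.5)
            * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))
    prior = (1 - rho**2) ** (a - 1)
    f0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return np.trapezoid(like * prior, rho) / np.trapezoid(prior, rho) / f0


class TestWilcoxon:
    def test_reference_example(self):
        w = inf.wilcoxon_signed_rank([1.5, 2.5, 4.0])
        assert w.V == 6 and w.p == pytest.approx(0.25)
        assert w.method == inf.EXACT

    def test_pseudomedian_walsh_averages(self):
        w = inf.wilcoxon_signed_rank([1, 2, 3])
        assert w.pseudomedian == pytest.approx(2.0)  # Walsh: 1,1.5,2,2,2.5,3
        assert w.ci_low <= w.pseudomedian <= w.ci_high

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for n in range(4, 13):
            x = rng.normal(0.2, 1.0, n)
            mine = inf.wilcoxon_signed_rank(x)
            assert mine.method == inf.EXACT
            assert mine.p == pytest.approx(brute_force_signed_rank_p(x), abs=1e-12)

    def test_null_distribution_sums_to_one(self):
        for n in (5, 12, 30, 49):
            assert inf.signed_rank_pmf(n).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_r_wilcox_test_frozen_values(self):
        # frozen from R 4.3.3: wilcox.test(x, conf.int=TRUE, exact=TRUE)
        x = [-0.068206, 0.055319, -0.253311, -0.222531, 0.285698, -0.13683,
             0.314721, 0.174984, 0.040855, -0.150824, -0.115687, -0.01967,
             -0.257659, -0.001113, -0.179989]
        w = inf.wilcoxon_signed_rank(x)
        assert w.V == 45
        assert w.p == pytest.approx(0.4212036, abs=1e-6)
        assert w.ci_low == pytest.approx(-0.1453685, abs=1e-6)
        assert w.ci_high == pytest.approx(0.067437, abs=1e-6)
        assert w.pseudomedian == pytest.approx(-0.04787, abs=1e-6)

    def test_ties_fall_back_to_normal_approximation(self):
        # frozen from R 4.3.3 (n=52 with midrank ties)
        z = [0.1, 0.1, -0.2, 0.3, 0.3, 0.05, -0.05, 0.2, 0.15, -0.1, 0.25,
             0.1, -0.3, 0.4, 0.2, 0.1, -0.15, 0.05, 0.3, -0.2, 0.1, 0.2,
             -0.1, 0.05, 0.15, 0.25, -0.05, 0.3, 0.1, -0.2, 0.2, 0.1, 0.05,
             -0.1, 0.3, 0.15, 0.2, -0.25, 0.1, 0.05, 0.2, -0.1, 0.15, 0.3,
             0.1, -0.05, 0.25, 0.2, 0.1, 0.3, -0.15, 0.2]
        w = inf.wilcoxon_signed_rank(z)
        assert w.method == inf.NORMAL_APPROX
        assert w.V == 1060.5
        assert w.p == pytest.approx(0.0006879771, rel=1e-5)

    def test_scipy_agreement_on_random_exact_samples(self):
        rng = np.random.default_rng(12)
        for n in (10, 25, 42):
            x = rng.normal(0.1, 1.0, n)
            mine = inf.wilcoxon_signed_rank(x)
            ref = stats.wilcoxon(x, method="exact")
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetric_sample_centre(self):
        # |d| = {1, 1.5, 3, 3.5}: positives 1.5 and 3.5 carry ranks 2 and 4
        w = inf.wilcoxon_signed_rank([-3.0, -1.0, 1.5, 3.5])
        assert w.V == 6.0  # close to n(n+1)/4 = 5: near-symmetric
        assert w.p > 0.6

    def test_all_zero_deviations_error(self):
        with pytest.raises(inf.DegenerateDataError):
            inf.wilcoxon_signed_rank([0.3, 0.3], mu=0.3)


class TestEffectSizesAndRankTests:
    def test_cohens_d(self):
        assert inf.cohens_d_one_sample([-1.0, 1.0]) == 0.0
        x = np.array([0.1, 0.4, 0.3, 0.9, -0.2])
        d = inf.cohens_d_one_sample(x, mu=0.1)
        assert d == pytest.approx((x.mean() - 0.1) / x.std(ddof=1), abs=1e-12)
        with pytest.raises(inf.DegenerateDataError):
            inf.cohens_d_one_sample([1.0, 1.0])

    def test_kruskal_wallis_hand_value(self):
        res = inf.kruskal_wallis([[1, 2], [3, 4]])
        assert res.H == pytest.approx(2.4)
        assert res.df == 1
        same = inf.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert same.H == pytest.approx(0.0)
        relabeled = inf.kruskal_wallis([[3, 4], [1, 2]])
        assert relabeled.H == pytest.approx(res.H)
        with pytest.raises(ValueError):
            inf.kruskal_wallis([[1, 2], []])

    def test_pearson_r_reference(self):
        x = np.arange(10.0)
        res = inf.pearson_r(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.df == 8
        y = np.array([0.2, -0.1, 0.5, 0.3, -0.4, 0.1, 0.0, 0.25, -0.3, 0.15])
        two = inf.pearson_r(x, y)
        r = np.corrcoef(x, y)[0, 1]
        t = r * math.sqrt(8 / (1 - r * r))
        assert two.r == pytest.approx(r, abs=1e-12)
        assert two.p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)
        one = inf.pearson_r(x, y, alternative=inf.POSITIVE)
        assert one.p == pytest.approx(stats.t.sf(t, 8), abs=1e-12)


class TestBayesFactors:
    def test_ttest_bf_matches_dense_grid_oracle(self):
        for t, n in [(0.0, 42), (0.5, 10), (2.0, 42), (-1.5, 20), (5.0, 42)]:
            mine = inf.bf01_ttest(t=t, n=n)
            oracle = 1.0 / grid_bf10_ttest(t, n)
            assert mine.bf01 == pytest.approx(oracle, rel=5e-3)

    def test_ttest_bf_null_data_favor_null(self):
        res = inf.bf01_ttest(t=0.0, n=42)
        assert res.bf01 > 1

    def test_ttest_bf_large_t_vanishes(self):
        assert inf.bf01_ttest(t=15.0, n=42).bf01 < 1e-6

    def test_ttest_directional_average_recovers_two_sided(self):
        for t, n in [(1.2, 30), (-0.8, 15)]:
            two = inf.bf01_ttest(t=t, n=n)
            pos = inf.bf01_ttest(t=t, n=n, direction=inf.POSITIVE)
            neg = inf.bf01_ttest(t=t, n=n, direction=inf.NEGATIVE)
            assert (1 / pos.bf01 + 1 / neg.bf01) / 2 == pytest.approx(
                1 / two.bf01, rel=1e-6)

    def test_ttest_bf_from_values_equals_summary_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.2, 1.0, 25)
        t = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
        assert inf.bf01_ttest(x).bf01 == pytest.approx(
            inf.bf01_ttest(t=t, n=len(x)).bf01, rel=1e-9)

    def test_correlation_bf_matches_dense_grid_oracle(self):
        for r, n in [(0.0, 42), (0.3, 10), (0.49, 14), (-0.6, 20), (0.083, 42)]:
            mine = inf.bf01_correlation(r, n)
            oracle = 1.0 / grid_bf10_corr(r, n)
            assert mine.bf01 == pytest.approx(oracle, rel=5e-3)
        one = inf.bf01_correlation(0.49, 14, direction=inf.POSITIVE)
        oracle_one = 1.0 / grid_bf10_corr(0.49, 14, lo=0.0)
        assert one.bf01 == pytest.approx(oracle_one, rel=5e-3)

    def test_correlation_bf_cross_checked_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        from pingouin.bayesian import bayesfactor_pearson

        for r, n, direction, alt in [
            (0.49, 14, inf.TWO_SIDED, "two-sided"),
            (0.49, 14, inf.POSITIVE, "greater"),
            (0.65, 14, inf.NEGATIVE, "less"),
            (-0.2, 30, inf.TWO_SIDED, "two-sided"),
        ]:
            mine = inf.bf01_correlation(r, n, direction=direction)
            ref = bayesfactor_pearson(r, n, alternative=alt, method="ly", kappa=1 / 3)
            assert mine.bf10 == pytest.approx(float(ref), rel=1e-4)

    def test_published_directional_convention_is_complement_row(self):
        """The published-convention helper equals the opposite-signed
        alternative's BF10."""
        val = inf.published_directional_bf01(0.49, 14, direction=inf.POSITIVE)
        neg = inf.bf01_correlation(0.49, 14, direction=inf.NEGATIVE)
        assert val == pytest.approx(neg.bf10, rel=1e-12)

    def test_correlation_bf_input_guards(self):
        with pytest.raises(ValueError):
            inf.bf01_correlation(1.0, 14)
        with pytest.raises(ValueError):
            inf.bf01_correlation(0.2, 3)


class TestEvidenceLadder:
    @pytest.mark.parametrize(
        "bf01, label",
        [
            (5.91, "moderate evidence for H0"),
            (2.83, "anecdotal evidence for H0"),
            (0.24, "moderate evidence for H1"),
            (15.0, "strong evidence for H0"),
            (0.009, "extreme evidence for H1"),
            (45.0, "very strong evidence for H0"),
            (1.0, "no evidence"),
        ],
    )
    def test_labels(self, bf01, label):
        assert inf.classify_evidence(bf01) == label

    def test_reciprocal_invariance_up_to_direction(self):
        for bf in (0.04, 0.5, 2.0, 7.0, 120.0):
            a = inf.classify_evidence(bf)
            b = inf.classify_evidence(1 / bf)
            assert a.split(" evidence")[0] == b.split(" evidence")[0]
        with pytest.raises(ValueError):
            inf.classify_evidence(0.0)


def test_wilcoxon_p_uniform_under_null_small_batch():
    """Exact two-sided p-values of null-normal samples look uniform."""
    rng = np.random.default_rng(99)
    ps = [inf.wilcoxon_signed_rank(rng.normal(0, 1, 25)).p for _ in range(300)]
    d = stats.kstest(ps, "uniform")
    assert d.pvalue > 0.01
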