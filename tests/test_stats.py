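"""From-formula statistics against closed forms, printed values and
independent scipy / brute-force / permutation oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from gdasim import (
    brown_forsythe,
    cumulative_proportions,
    jackpot_plates,
    kendall_tau,
    loglog_slope,
    poisson_tail,
    spearman_rho,
    summarize_counts,
    summarize_fluctuation,
    table1_fixture,
    variance_ratio,
)


class TestSummarizeCounts:
    def test_fluctuation_fixture_reproduces_printed_summaries(self):
        fx = table1_fixture()
        mean, var, med = summarize_counts(fx["parallel"])
        assert mean == pytest.approx(1.95, abs=0.005)
        assert var == pytest.approx(10.13, abs=0.005)
        assert med == 1
        expected = {
            "single_18": (0.67, 0.71, 0),
            "single_49a": (0.24, 0.31, 0),
            "single_49b": (0.22, 0.22, 0),
        }
        for arm, (m, v, md) in expected.items():
            mean, var, med = summarize_counts(fx[arm])
            assert mean == pytest.approx(m, abs=0.005)
            assert var == pytest.approx(v, abs=0.005)
            assert med == md

    def test_hand_arithmetic_and_degenerate_cases(self):
        assert summarize_counts([0, 2, 4]) == (2.0, 4.0, 2.0)
        assert summarize_counts([0] * 10) == (0.0, 0.0, 0.0)
        assert math.isnan(summarize_counts([5])[1])
        with pytest.raises(ValueError):
            summarize_counts([])

    def test_against_two_pass_oracle_on_random_lists(self, rng):
        for _ in range(200):
            x = rng.integers(0, 20, size=rng.integers(2, 40))
            mean, var, med = summarize_counts(x)
            assert mean == pytest.approx(sum(x) / len(x))
            assert var == pytest.approx(
                sum((v - mean) ** 2 for v in x) / (len(x) - 1)
            )
            assert med == float(np.median(x))


class TestCumulativeProportions:
    def test_enumerated_examples(self):
        assert cumulative_proportions([0, 1, 2]) == [(1, pytest.approx(2 / 3)), (2, pytest.approx(1 / 3))]
        arm = table1_fixture()["single_18"]
        assert cumulative_proportions(arm) == [
            (1, pytest.approx(8 / 18)),
            (2, pytest.approx(4 / 18)),
        ]
        assert cumulative_proportions([0, 0, 0]) == []

    def test_non_increasing_in_x(self, rng):
        x = rng.poisson(3, size=200)
        pts = cumulative_proportions(x)
        ps = [p for _, p in pts]
        assert all(b <= a for a, b in zip(ps, ps[1:]))


class TestLoglogSlope:
    def test_exact_power_law_and_constant(self):
        assert loglog_slope([(x, 1.0 / x) for x in (1, 2, 4, 8)]) == pytest.approx(-1.0)
        assert loglog_slope([(x, 0.5) for x in (1, 2, 4)]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            loglog_slope([(1, 0.5)])

    def test_poisson_drops_steeper_than_jackpot_distribution(self):
        from gdasim import gen_ld_plates, gen_poisson_plates

        ld = gen_ld_plates(2e-7, 24, 2e7, 300, seed=3)
        po = gen_poisson_plates(ld.mean(), 300, seed=4)
        s_ld = loglog_slope(cumulative_proportions(ld))
        s_po = loglog_slope(cumulative_proportions(po))
        assert s_po < s_ld


class TestPoissonTail:
    def test_closed_form_values(self):
        assert poisson_tail(3.7, 0) == 1.0
        assert poisson_tail(1.0, 1) == pytest.approx(1 - math.exp(-1))
        assert poisson_tail(0.67, 3) == pytest.approx(
            1 - math.exp(-0.67) * (1 + 0.67 + 0.67**2 / 2)
        )
        with pytest.raises(ValueError):
            poisson_tail(-0.1, 2)

    def test_against_scipy_and_cdf_identity(self):
        for lam in (0.22, 0.67, 1.95, 7.5):
            for x in range(0, 15):
                assert poisson_tail(lam, x) == pytest.approx(
                    float(sps.poisson.sf(x - 1, lam)), abs=1e-12
                )
                # P(>=0) - P(>=x) is the CDF up to x-1
                assert 1.0 - poisson_tail(lam, x) == pytest.approx(
                    float(sps.poisson.cdf(x - 1, lam)), abs=1e-12
                )


class TestBrownForsythe:
    def test_degenerate_cases(self):
        f, p = brown_forsythe([1, 2, 3], [1, 2, 3])
        assert f == 0.0 and p == 1.0
        # pure location shift leaves the median deviations identical
        f, p = brown_forsythe([1, 2, 3], [4, 5, 6])
        assert f == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            brown_forsythe([1.0], [1, 2])

    def test_matches_scipy_levene_median_centered(self, rng):
        for _ in range(25):
            a = rng.poisson(2.0, size=rng.integers(5, 40))
            b = rng.poisson(5.0, size=rng.integers(5, 40))
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                continue
            f, p = brown_forsythe(a, b)
            f_ref, p_ref = sps.levene(a, b, center="median")
            assert f == pytest.approx(float(f_ref), rel=1e-10)
            assert p == pytest.approx(float(p_ref), rel=1e-10)

    def test_f_distribution_p_agrees_with_permutation_oracle(self, rng):
        # on discrete count data the F reference is approximate; agreement
        # tightens with group size
        for i in range(8):
            a = rng.poisson(1.5, size=80)
            b = rng.poisson(2.5, size=80)
            f, p_f = brown_forsythe(a, b)
            _, p_perm = brown_forsythe(
                a, b, method="permutation", n_permutations=4000, seed=i
            )
            assert abs(p_f - p_perm) < 0.05

    def test_fixture_arms_differ_in_spread(self):
        fx = table1_fixture()
        f, p = brown_forsythe(fx["parallel"], fx["single_49b"])
        assert f > 0 and p < 0.05


def _brute_force_spearman(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _brute_force_kendall(x, y):
    n = len(x)
    c = d = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[i] - x[j])
        sy = np.sign(y[i] - y[j])
        if sx == 0 and sy == 0:
            continue
        if sx == 0:
            tx += 1
        elif sy == 0:
            ty += 1
        elif sx == sy:
            c += 1
        else:
            d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((c + d + tx) * (c + d + ty))


class TestRankCorrelations:
    def test_perfect_and_reversed_rankings(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1])[0] == pytest.approx(-1.0)
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_hand_computed_examples(self):
        # sum of squared rank differences is 2: rho = 1 - 6*2/(4*15)
        rho, _ = spearman_rho([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)
        # five concordant, one discordant pair
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(4 / 6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            kendall_tau([1, 2, 3], [1, 2])

    def test_exhaustive_small_instances_against_pair_enumeration(self):
        for perm in itertools.permutations(range(5)):
            x = list(range(5))
            y = list(perm)
            assert kendall_tau(x, y)[0] == pytest.approx(_brute_force_kendall(x, y))
            assert spearman_rho(x, y)[0] == pytest.approx(_brute_force_spearman(x, y))

    def test_ties_match_scipy(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p_rho = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(float(ref.statistic), abs=1e-10)
            assert p_rho == pytest.approx(float(ref.pvalue), rel=1e-6, abs=1e-10)
            tau, p_tau = kendall_tau(x, y)
            ref_t = sps.kendalltau(x, y, method="asymptotic")
            assert tau == pytest.approx(float(ref_t.statistic), abs=1e-10)
            assert p_tau == pytest.approx(float(ref_t.pvalue), rel=1e-6, abs=1e-10)


class TestJackpotsAndVarianceRatio:
    def test_fixture_jackpots_flagged_only_in_parallel_arm(self):
        fx = table1_fixture()
        flagged = jackpot_plates(fx["parallel"])
        values = fx["parallel"][flagged]
        assert 17 in values and 19 in values
        for arm in ("single_18", "single_49a", "single_49b"):
            assert jackpot_plates(fx[arm]) == []

    def test_uniform_counts_and_single_outlier(self):
        assert jackpot_plates([3] * 20) == []
        counts = [2] * 30 + [40]
        assert jackpot_plates(counts) == [30]

    def test_fixture_variance_ratio_at_least_tenfold(self):
        fx = table1_fixture()
        ratio = variance_ratio(fx["parallel"], fx["single_18"])
        assert ratio == pytest.approx(10.13 / 0.71, abs=0.1)
        assert ratio >= 10

    def test_shift_invariance_and_degenerate_input(self, rng):
        a = rng.poisson(4, 30)
        b = rng.poisson(2, 30)
        r1 = variance_ratio(a, b)
        r2 = variance_ratio(a + 7, b + 7)
        assert r1 == pytest.approx(r2)
        assert variance_ratio(a, a) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            variance_ratio(a, [3, 3, 3])


class TestSummarizeFluctuation:
    def test_summary_collects_all_components(self):
        fx = table1_fixture()
        s = summarize_fluctuation(fx["parallel"])
        assert s.mean == pytest.approx(1.95, abs=0.005)
        assert s.variance == pytest.approx(10.13, abs=0.005)
        assert s.median == 1
        assert len(s.jackpot_indices) >= 2
        assert s.loglog_slope is not None and s.loglog_slope < 0
        assert s.cumulative_points[0][0] == 1

    def test_all_zero_counts_have_no_slope(self):
        s = summarize_fluctuation([0, 0, 0, 0])
        assert s.loglog_slope is None
        assert s.cumulative_points == []
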