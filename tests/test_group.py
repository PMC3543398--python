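import itertools

import numpy as np
import pytest
from scipy import stats

from cogrecov import (
    AssessmentSeries,
    CohortConfig,
    ModelKind,
    OccasionMatrix,
    analyze_group,
    cohort_series,
    fit_group_curve,
    friedman_test,
    generate_cohort,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent oracles (naive, loop-based; no shared code with the package)


def _avg_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def friedman_oracle(grid):
    """Tie-corrected Friedman chi-square from first principles."""
    n, k = len(grid), len(grid[0])
    col_sums = [0.0] * k
    tie_sum = 0.0
    for row in grid:
        ranks = _avg_ranks(list(row))
        for j, r in enumerate(ranks):
            col_sums[j] += r
        for v in set(row):
            t = list(row).count(v)
            tie_sum += t**3 - t
    stat = 12.0 / (n * k * (k + 1)) * sum(s * s for s in col_sums) - 3 * n * (k + 1)
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        return 0.0, 1.0
    stat /= correction
    return stat, float(stats.chi2.sf(stat, df=k - 1))


def wilcoxon_oracle(x, y):
    """Exact signed-rank test by exhaustive enumeration of all sign flips."""
    d = [a - b for a, b in zip(x, y) if a != b]
    if not d:
        return 0.0, 1.0
    ranks = _avg_ranks([abs(v) for v in d])
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    w_minus = sum(r for r, v in zip(ranks, d) if v < 0)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((0, 1), repeat=len(d))
    ]
    cdf = sum(w <= w_plus for w in ws) / len(ws)
    sf = sum(w >= w_plus for w in ws) / len(ws)
    return min(w_plus, w_minus), min(1.0, 2.0 * min(cdf, sf))


# ---------------------------------------------------------------------------


class TestFriedman:
    def test_no_rank_variation_is_null(self):
        grid = [[22, 22, 22]] * 5
        res = friedman_test(np.array(grid))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_toy_grid_statistic(self):
        # hand formula: 12/(n k (k+1)) * sum(R_j^2) - 3 n (k+1) with n=k=3
        res = friedman_test(np.array([[1, 2, 3]] * 3))
        assert res.statistic == pytest.approx(6.0)
        assert res.pvalue == pytest.approx(float(stats.chi2.sf(6.0, 2)))

    def test_matches_oracle_on_random_small_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(120):
            n = rng.integers(2, 9)
            k = rng.integers(2, 6)
            grid = rng.integers(0, 31, size=(n, k)).astype(float)
            res = friedman_test(grid)
            stat, p = friedman_oracle(grid.tolist())
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            grid = rng.normal(20, 4, size=(rng.integers(3, 10), 3))
            res = friedman_test(grid)
            ref = stats.friedmanchisquare(*(grid[:, j] for j in range(3)))
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.pvalue == pytest.approx(ref.pvalue)

    def test_type_i_error_near_nominal_under_null(self):
        # 2000 null grids: rejection rate at alpha=0.05 should sit near the
        # nominal level (wide a-priori band; the chi-square reference is an
        # approximation on a discrete rank statistic)
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(2000):
            grid = rng.normal(size=(25, 3))
            if friedman_test(grid).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / 2000 <= 0.08

    def test_rejects_tiny_or_incomplete_grids(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, 2.0]]))  # single patient
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([3, 4, 5], [3, 4, 5])
        assert res.degenerate
        assert res.pvalue == 1.0
        assert res.n_used == 0

    def test_one_sided_extreme_statistic_zero(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 7])
        assert res.statistic == 0.0

    def test_exact_p_equals_enumeration_n6(self):
        x = [10, 14, 9, 21, 17, 8]
        y = [12, 11, 15, 20, 12, 16]
        res = wilcoxon_signed_rank(x, y)
        stat, p = wilcoxon_oracle(x, y)
        assert res.statistic == pytest.approx(stat)
        assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(14)
        for _ in range(120):
            n = rng.integers(2, 9)
            x = rng.integers(0, 31, size=n).tolist()
            y = rng.integers(0, 31, size=n).tolist()
            res = wilcoxon_signed_rank(x, y)
            stat, p = wilcoxon_oracle(x, y)
            assert res.statistic == pytest.approx(stat)
            assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            d = rng.permutation(np.arange(1, 11)) * rng.choice([-1, 1], 10)
            x = np.zeros(10) + d
            y = np.zeros(10)
            res = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, method="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.pvalue == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(16)
        x = rng.normal(22, 3, 60)
        y = x + rng.normal(0.6, 1.5, 60)
        res = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="approx", correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)


class TestGroupCurve:
    def _collinear_cohort(self):
        import math

        # three patients whose occasion means fall exactly on 18 + 2 ln(t)
        days = [5, 12, 19]
        series = []
        for pid, shift in [("a", -1), ("b", 0), ("c", 1)]:
            obs = [(d, round(18 + 2 * math.log(d)) + shift) for d in days]
            series.append(AssessmentSeries(pid, tuple(obs)))
        return series

    def test_collinear_summary_points_r2_high(self):
        fit = fit_group_curve(self._collinear_cohort(), ModelKind.LOGARITHMIC)
        assert fit.r_squared > 0.99  # integer rounding is the only slack

    def test_two_point_fit_saturated(self):
        cohort = [AssessmentSeries("a", ((5, 20), (12, 24)))]
        for kind in ModelKind:
            assert fit_group_curve(cohort, kind, mode="pooled").r_squared == pytest.approx(1.0)

    def test_pooled_fit_on_zero_noise_log_cohort(self):
        # shared true curve well inside the score range: the only scatter is
        # the +/-0.5 integer rounding, so the pooled fit is near-saturated
        cohort = cohort_series(
            generate_cohort(CohortConfig(n_patients=60, seed=17, noise_sd=0.0, a_fixed=12.0, b_fixed=3.5))
        )
        fit = fit_group_curve(cohort, ModelKind.LOGARITHMIC, mode="pooled")
        assert fit.r_squared >= 0.98
        assert fit.slope_b == pytest.approx(3.5, abs=0.1)

    def test_r2_invariant_to_affine_regressor_rescaling(self):
        cohort = cohort_series(generate_cohort(CohortConfig(n_patients=30, seed=18)))
        base = fit_group_curve(cohort, ModelKind.LINEAR, mode="pooled")
        rescaled = [
            AssessmentSeries(s.patient_id, tuple((3 * o.day + 10, o.score) for o in s.observations))
            for s in cohort
        ]
        assert fit_group_curve(rescaled, ModelKind.LINEAR, mode="pooled").r_squared == pytest.approx(
            base.r_squared
        )

    def test_zero_regressor_variance_rejected(self):
        cohort = [AssessmentSeries("a", ((5, 20),)), AssessmentSeries("b", ((5, 22),))]
        with pytest.raises(ValueError):
            fit_group_curve(cohort, ModelKind.LINEAR, mode="pooled")

    def test_log_fit_usually_beats_linear_on_log_truth(self):
        wins = 0
        for seed in range(30):
            cohort = cohort_series(
                generate_cohort(CohortConfig(n_patients=57, seed=seed, followup_offsets=(7, 14)))
            )
            report = analyze_group(cohort)
            wins += (
                report.fits["logarithmic"].r_squared >= report.fits["linear"].r_squared
            )
        assert wins >= 24  # >=80% of replicates


class TestAnalyzeGroup:
    def test_report_structure_and_bonferroni(self):
        cohort = cohort_series(
            generate_cohort(CohortConfig(n_patients=20, seed=19, followup_offsets=(7, 14)))
        )
        plain = analyze_group(cohort)
        adjusted = analyze_group(cohort, bonferroni=True)
        assert plain.friedman_p <= 1.0
        assert len(plain.pairwise) == 2  # each later occasion vs baseline
        for raw, adj in zip(plain.pairwise, adjusted.pairwise):
            assert adj["pvalue"] == pytest.approx(min(1.0, raw["pvalue"] * 2))
        d = plain.to_dict()
        assert set(d["fits"]) == {"logarithmic", "linear"}
        assert "friedman_p" in d

    def test_mismatched_series_lengths_rejected(self):
        cohort = [
            AssessmentSeries("a", ((5, 20), (12, 22), (19, 23))),
            AssessmentSeries("b", ((6, 18), (13, 19))),
        ]
        with pytest.raises(ValueError):
            OccasionMatrix.from_cohort(cohort)
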