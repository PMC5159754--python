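"""The lambda_meta statistic, its null distribution and the overlap
transform."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwamaqc import (
    CHI2_1_MEDIAN,
    CohortSummary,
    compute_lambda,
    gamma_from_lambda,
    lambda_af,
    lambda_gc,
    lambda_theoretical_se,
    pair_lambda,
    pairwise_scan,
    t_stats,
)
from gwamaqc.sumstats_io import harmonize_pair

from conftest import make_cohort


def synthetic_pair(m, gamma, seed, sigma1=0.03, sigma2=0.03, het_sd=0.0,
                   n1=1000, n2=1000):
    """Analytic generator of a harmonised effect-size pair: the two error
    vectors are bivariate normal with correlation gamma; optional
    cohort-specific true effects add heterogeneity."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        [0, 0], [[1, gamma], [gamma, 1]], size=m
    )
    b1 = sigma1 * z[:, 0]
    b2 = sigma2 * z[:, 1]
    if het_sd > 0:
        b1 = b1 + rng.normal(0, het_sd, m)
        b2 = b2 + rng.normal(0, het_sd, m)
    se1 = np.full(m, sigma1)
    se2 = np.full(m, sigma2)
    return b1, se1, b2, se2


class TestTStats:
    def test_equal_effects_give_zero(self):
        t = t_stats([0.2, -0.1], [0.1, 0.1], [0.2, -0.1], [0.1, 0.1])
        np.testing.assert_allclose(t, 0.0)

    def test_forced_arithmetic(self):
        t = t_stats([1.0], [np.sqrt(0.5)], [0.0], [np.sqrt(0.5)])
        assert t[0] == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            t_stats([0.1], [0.0], [0.1], [0.1])

    def test_null_distribution_is_chi2_1(self):
        """30 000 independent-null T values pass a KS test against
        chi-square(1) at alpha = 0.001."""
        b1, se1, b2, se2 = synthetic_pair(30_000, gamma=0.0, seed=8)
        t = t_stats(b1, se1, b2, se2)
        _, p = stats.kstest(t, stats.chi2(df=1).cdf)
        assert p > 0.001


class TestComputeLambda:
    def test_constant_at_chi2_median_gives_one(self):
        assert compute_lambda(np.full(100, CHI2_1_MEDIAN)) == pytest.approx(1.0)

    def test_all_zero_gives_zero(self):
        assert compute_lambda(np.zeros(10)) == 0.0

    def test_chi2_draws_within_three_theoretical_se(self):
        rng = np.random.default_rng(12)
        lam = compute_lambda(rng.chisquare(1, 30_000))
        assert abs(lam - 1.0) < 3 * 0.0135

    def test_theoretical_se_matches_monte_carlo(self):
        """The asymptotic median-variance formula agrees with the Monte-Carlo
        SD of lambda over independent null replicates."""
        rng = np.random.default_rng(13)
        m, reps = 5000, 800
        lams = np.median(
            rng.standard_normal((reps, m)) ** 2, axis=1
        ) / CHI2_1_MEDIAN
        assert lams.std(ddof=1) == pytest.approx(lambda_theoretical_se(m), rel=0.10)


class TestLambdaAf:
    def test_identical_frequencies_give_zero(self):
        p = np.linspace(0.1, 0.9, 50)
        lam, _ = lambda_af(p, 500, p, 500)
        assert lam == 0.0

    def test_independent_binomial_samples_near_one(self):
        rng = np.random.default_rng(14)
        m, n = 30_000, 500
        p = rng.uniform(0.1, 0.9, m)
        f1 = rng.binomial(2 * n, p) / (2 * n)
        f2 = rng.binomial(2 * n, p) / (2 * n)
        lam, _ = lambda_af(f1, n, f2, n)
        assert abs(lam - 1.0) < 3 * lambda_theoretical_se(m)

    def test_monomorphic_snps_excluded_and_counted(self):
        p = np.array([0.0, 0.5, 0.4])
        lam, n_excl = lambda_af(p, 100, p.copy(), 100)
        assert n_excl == 1
        assert lam == 0.0


class TestLambdaGc:
    def test_iid_chi2_near_one(self):
        rng = np.random.default_rng(15)
        assert lambda_gc(rng.chisquare(1, 30_000)) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(16)
        x = rng.chisquare(1, 5000)
        assert lambda_gc(2 * x) == pytest.approx(2 * lambda_gc(x))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc(np.array([-0.1, 1.0]))


class TestGammaFromLambda:
    def test_lambda_one_gives_zero_overlap(self):
        gamma, n_o = gamma_from_lambda(1.0, 1000, 1000)
        assert gamma == 0.0
        assert n_o == 0.0

    def test_equal_n_arithmetic(self):
        gamma, n_o = gamma_from_lambda(0.9, 1000, 1000)
        assert gamma == pytest.approx(0.1)
        assert n_o == pytest.approx(100.0)

    def test_heterogeneity_reports_no_overlap_count(self):
        gamma, n_o = gamma_from_lambda(1.2, 1000, 1000)
        assert gamma < 0
        assert np.isnan(n_o)

    def test_true_correlation_for_unequal_sizes(self):
        # 100 shared of 1000 and 2000: gamma = 100/sqrt(2e6) = 0.0707
        lam = 1 - 0.0707 * 2 * np.sqrt(1000 * 2000) / 3000
        gamma, n_o = gamma_from_lambda(lam, 1000, 2000)
        assert gamma == pytest.approx(0.0707, abs=1e-10)
        assert n_o == pytest.approx(100.0, rel=1e-3)


class TestOverlapHeterogeneityDirections:
    def test_overlap_deflates_heterogeneity_inflates(self):
        lam_overlap, lam_het = [], []
        for rep in range(20):
            b1, s1, b2, s2 = synthetic_pair(5000, gamma=0.15, seed=200 + rep)
            lam_overlap.append(compute_lambda(t_stats(b1, s1, b2, s2)))
            b1, s1, b2, s2 = synthetic_pair(
                5000, gamma=0.0, het_sd=0.012, seed=400 + rep
            )
            lam_het.append(compute_lambda(t_stats(b1, s1, b2, s2)))
        assert np.mean(lam_overlap) < 1.0 - 2 * lambda_theoretical_se(5000) / np.sqrt(20)
        assert np.mean(lam_het) > 1.0 + 2 * lambda_theoretical_se(5000) / np.sqrt(20)

    def test_deflation_maximal_at_equal_sample_sizes(self):
        """For a given summary-statistic correlation, |E[lambda] - 1| (hence
        detection power) peaks when the two cohorts have equal size: the
        deflation is gamma * 2 sqrt(n1 n2) / (n1 + n2)."""
        gamma = 0.1

        def mean_lambda(n1, n2, seed0):
            s1, s2 = 1 / np.sqrt(n1), 1 / np.sqrt(n2)
            lams = [
                compute_lambda(
                    t_stats(*synthetic_pair(
                        5000, gamma=gamma, sigma1=s1, sigma2=s2, seed=seed0 + r
                    ))
                )
                for r in range(20)
            ]
            return np.mean(lams)

        balanced = mean_lambda(1000, 1000, 600)
        skewed = mean_lambda(200, 1800, 700)
        assert 1 - balanced > 1 - skewed

    def test_relatives_across_cohorts_deflate_lambda(self):
        """First-degree pairs split across cohorts correlate the summary
        statistics and pull lambda below 1."""
        from gwamaqc import CohortSpec, PopulationSpec, SimConfig, run_simulation

        lams = []
        for rep in range(5):
            cfg = SimConfig(
                m_snps=10_000,
                populations=[PopulationSpec("POP")],
                cohorts=[
                    CohortSpec("cohort1", "POP", 500, h2=0.8),
                    CohortSpec("cohort2", "POP", 500, h2=0.8,
                               relatives_with=("cohort1", 250)),
                ],
                n_qtl=500,
                seed=900 + rep,
            )
            res = run_simulation(cfg, keep_genotypes=False)
            t1 = res.cohorts["cohort1"].summary.table
            t2 = res.cohorts["cohort2"].summary.table
            ok = t1["se"].notna() & t2["se"].notna()
            lams.append(
                compute_lambda(
                    t_stats(
                        t1.loc[ok, "beta"], t1.loc[ok, "se"],
                        t2.loc[ok, "beta"], t2.loc[ok, "se"],
                    )
                )
            )
        assert np.mean(lams) < 1.0 - 2 * lambda_theoretical_se(10_000) / np.sqrt(5)


def null_cohort(cohort_id, seed, m=3000, n=1000):
    """Summary statistics of a pure-noise GWAS drawn analytically."""
    rng = np.random.default_rng(seed)
    base = make_cohort(m=m, n=n, seed=0, cohort_id=cohort_id,
                       chrom_count=10, spacing=200_000)
    t = base.table.copy()
    se = 1 / np.sqrt(n * 2 * t["freq_a1"] * (1 - t["freq_a1"]))
    t["se"] = se
    t["beta"] = rng.standard_normal(m) * se
    return CohortSummary(cohort_id, t)


class TestPairwiseScan:
    def test_symmetry_and_matrix_layout(self):
        cohorts = [null_cohort(f"c{i}", 30 + i) for i in range(3)]
        scan = pairwise_scan(cohorts, target_m=3000, seed=5)
        m = scan.matrix
        for a in m.index:
            for b in m.columns:
                if a != b:
                    assert m.loc[a, b] == m.loc[b, a]

    def test_duplicated_cohort_flagged_with_zero_lambda(self):
        cohorts = [null_cohort(f"c{i}", 40 + i) for i in range(3)]
        dup = CohortSummary("c0_dup", cohorts[0].table.copy())
        scan = pairwise_scan(cohorts + [dup], target_m=3000, seed=5)
        row = scan.pairs.query("cohort1 == 'c0' and cohort2 == 'c0_dup'").iloc[0]
        assert row["lambda_meta"] == 0.0
        assert row["p_theoretical"] < 1e-10
        assert row["significant_bonferroni"]

    def test_null_calibration_of_theoretical_z(self):
        cohorts = [null_cohort(f"c{i}", 50 + i) for i in range(10)]
        scan = pairwise_scan(cohorts, target_m=3000, seed=5)
        frac = (scan.pairs["z_theoretical"].abs() > 1.96).mean()
        # 45 pairs, expect ~5%; allow a generous binomial band
        assert frac <= 0.20
        assert scan.pairs["lambda_meta"].mean() == pytest.approx(1.0, abs=0.02)

    def test_theoretical_se_at_30k(self):
        assert lambda_theoretical_se(30_000) == pytest.approx(0.0135, abs=0.001)

    def test_af_mode_runs(self):
        cohorts = [null_cohort(f"c{i}", 60 + i) for i in range(2)]
        scan = pairwise_scan(cohorts, mode="allele_frequency",
                             target_m=3000, seed=5)
        assert len(scan.pairs) == 1


class TestPairLambdaOnSimulation:
    def test_lambda_symmetric_in_cohort_order(self, small_pair_sim):
        c1 = small_pair_sim.cohorts["cohort1"].summary
        c2 = small_pair_sim.cohorts["cohort2"].summary
        l12 = pair_lambda(harmonize_pair(c1, c2)).lambda_meta
        l21 = pair_lambda(harmonize_pair(c2, c1)).lambda_meta
        assert l12 == l21

    def test_overlap_detected_in_simulated_pair(self, small_pair_sim):
        c1 = small_pair_sim.cohorts["cohort1"].summary
        c2 = small_pair_sim.cohorts["cohort2"].summary
        res = pair_lambda(harmonize_pair(c1, c2))
        # 40 shared of 400/400 -> gamma = 0.1
        assert res.lambda_meta < 1.0
        assert res.gamma_hat == pytest.approx(0.1, abs=3 * res.theoretical_se)
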