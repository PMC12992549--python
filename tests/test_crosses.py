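"""Tests for the cross-experiment estimators and tests.

The GLMM fixture values were computed with R lme4::glmer
(binomial family, nAGQ = 25) on the identical table, an independent
implementation of the same marginal-likelihood problem.
"""

import numpy as np
import pytest

from suppdrive.crosses import (
    RateEstimate,
    VialRecord,
    compare_rates_z,
    embryo_resistance_rate,
    fecundity_ttest,
    glmm_logit_rate,
    pooled_rate,
    viability_compare,
)
from suppdrive.synth import gen_cross_vials


class TestPooledRate:
    @pytest.mark.parametrize(
        "k, n, pct, se_pct",
        [
            (4, 9, 44.4, 16.56),   # sterile drive daughters, small cross set
            (19, 30, 63.3, 8.8),   # sterile drive daughters, larger cross set
        ],
    )
    def test_reported_rate_and_se(self, k, n, pct, se_pct):
        est = pooled_rate([(k, n)])
        assert round(100 * est.estimate, 1) == pct
        assert round(100 * est.se, len(str(se_pct).split(".")[1])) == se_pct

    def test_zero_successes(self):
        est = pooled_rate([(0, 25)])
        assert est.estimate == 0.0 and est.se == 0.0

    def test_pools_across_vials(self):
        est = pooled_rate([(5, 10), (15, 20)])
        assert est.estimate == pytest.approx(20 / 30)
        assert est.n == 30

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_rate([])

    def test_exact_ci_option(self):
        est = pooled_rate([(0, 10)], exact_ci=True)
        assert est.ci[0] == 0.0 and 0 < est.ci[1] < 0.4

    def test_wald_ci_clipped(self):
        est = pooled_rate([(1, 10)])
        assert est.ci[0] >= 0.0


class TestGlmmRate:
    def test_matches_lme4_oracle(self):
        # deterministic fixture; reference fit: mu=2.39937573 (SE 0.25889828),
        # sigma=0.63486644 from lme4 glmer nAGQ=25
        df = gen_cross_vials(12, 42, rate=0.9, sigma_vial=0.5, mean_offspring=40)
        est = glmm_logit_rate(list(zip(df.n_carriers, df.n_offspring)), nagq=25)
        assert est.extras["mu"] == pytest.approx(2.39937573, abs=2e-5)
        assert est.extras["se_mu"] == pytest.approx(0.25889828, rel=1e-3)
        assert est.extras["sigma"] == pytest.approx(0.63486644, abs=2e-4)

    def test_loglik_matches_exact_integration(self):
        from scipy import integrate, special, stats as ss
        from suppdrive.crosses import _aghq_loglik

        df = gen_cross_vials(8, 7, rate=0.8, sigma_vial=0.6, mean_offspring=25)
        ks = df.n_carriers.to_numpy()
        ns = df.n_offspring.to_numpy()
        mu, sigma = 1.2, 0.6
        exact = 0.0
        for k, n in zip(ks, ns):
            f = lambda b: ss.binom.pmf(k, n, special.expit(mu + b)) * ss.norm.pdf(b, 0, sigma)
            v, _ = integrate.quad(f, -8 * sigma, 8 * sigma, limit=200)
            exact += np.log(v)
        nodes, weights = np.polynomial.hermite.hermgauss(25)
        assert _aghq_loglik(mu, sigma, ks, ns, nodes, weights) == pytest.approx(
            exact, abs=1e-8
        )

    def test_degenerate_homogeneous_vials_match_pooled(self):
        vials = [(9, 10)] * 8
        g = glmm_logit_rate(vials, nagq=25)
        p = pooled_rate(vials)
        assert g.estimate == pytest.approx(p.estimate, abs=1e-4)
        assert g.extras["sigma"] < 0.05

    def test_recovers_generating_mean(self):
        """Median logit-scale bias under the generating GLMM is small."""
        from scipy import special

        mus = []
        for s in range(30):
            df = gen_cross_vials(20, 2000 + s, rate=0.9, sigma_vial=0.5, mean_offspring=50)
            est = glmm_logit_rate(list(zip(df.n_carriers, df.n_offspring)))
            mus.append(est.extras["mu"])
        assert abs(np.median(mus) - special.logit(0.9)) < 0.1

    def test_nagq1_close_to_converged_quadrature(self):
        # one node == Laplace approximation; for well-populated vials it
        # should land near the nAGQ=25 fit
        df = gen_cross_vials(12, 42, rate=0.9, sigma_vial=0.5, mean_offspring=40)
        vials = list(zip(df.n_carriers, df.n_offspring))
        lap = glmm_logit_rate(vials, nagq=1)
        full = glmm_logit_rate(vials, nagq=25)
        assert lap.extras["mu"] == pytest.approx(full.extras["mu"], abs=0.05)

    def test_requires_two_vials(self):
        with pytest.raises(ValueError):
            glmm_logit_rate([(5, 10)])


class TestCompareRatesZ:
    def test_identical_rates(self):
        z, p = compare_rates_z((50, 100), (50, 100))
        assert z == 0.0 and p == 1.0

    def test_two_sample_counts(self):
        z, p = compare_rates_z((50, 100), (70, 100))
        # direct formula with per-group binomial SEs
        se = np.sqrt(0.5 * 0.5 / 100 + 0.7 * 0.3 / 100)
        assert z == pytest.approx(-0.2 / se, abs=1e-10)
        assert p == pytest.approx(0.0032, abs=5e-4)

    def test_one_sample_against_null(self):
        est = RateEstimate(0.413, 0.026, (0.36, 0.46), 400, "glmm")
        z, p = compare_rates_z(est, 0.5)
        assert z == pytest.approx(-3.346, abs=0.01)
        assert p < 0.001

    def test_symmetry_under_swap(self):
        z1, p1 = compare_rates_z((30, 80), (50, 90))
        z2, p2 = compare_rates_z((50, 90), (30, 80))
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_zero_se_conflict_rejected(self):
        with pytest.raises(ValueError):
            compare_rates_z((0, 50), (50, 50))


class TestEmbryoResistance:
    def test_pooled_over_sterility_flags(self):
        records = [(f"f{i}", i < 4) for i in range(9)]  # 4 sterile of 9
        est = embryo_resistance_rate(records)
        assert round(100 * est.estimate, 1) == 44.4
        assert round(100 * est.se, 2) == 16.56

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            embryo_resistance_rate([])


class TestFecundityTtest:
    def test_identical_samples(self):
        x = [20.0, 25.0, 30.0, 22.0]
        t, df, p = fecundity_ttest(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_power_against_simulation_oracle(self, rng):
        """Welch rejection rate at a 1-SD shift matches a Monte-Carlo oracle."""
        n = 30
        shift = 1.0
        reps = 2000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(shift, 1, n)
            _, _, p = fecundity_ttest(a, b)
            rejections += p < 0.05
        power = rejections / reps
        # analytic power of the two-sample t-test at delta=1, n=30/30
        from scipy import stats as ss

        nc = shift / np.sqrt(2 / n)
        crit = ss.t.ppf(0.975, 2 * n - 2)
        analytic = 1 - ss.nct.cdf(crit, 2 * n - 2, nc) + ss.nct.cdf(-crit, 2 * n - 2, nc)
        assert abs(power - analytic) < 3 * np.sqrt(analytic * (1 - analytic) / reps)

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            fecundity_ttest([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fecundity_ttest([1.0], [2.0, 3.0])


class TestViability:
    def test_equal_survival(self):
        z, p = viability_compare(
            {"n_eggs": 500, "n_adults": 400}, {"n_eggs": 500, "n_adults": 400}
        )
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_proportion_formula(self):
        a = {"n_eggs": 500, "n_adults": 400}
        b = {"n_eggs": 500, "n_adults": 450}
        z, p = viability_compare(a, b)
        pool = (400 + 450) / 1000
        se = np.sqrt(pool * (1 - pool) * (1 / 500 + 1 / 500))
        assert z == pytest.approx((0.8 - 0.9) / se, abs=1e-10)
        assert p < 0.001

    def test_excess_adults_rejected(self):
        with pytest.raises(ValueError):
            viability_compare(
                {"n_eggs": 10, "n_adults": 12}, {"n_eggs": 10, "n_adults": 5}
            )


class TestVialRecord:
    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            VialRecord("v1", "cross", n_offspring=10, n_drive_carriers=11)

    def test_viability_bounds_checked(self):
        with pytest.raises(ValueError):
            VialRecord("v1", "cross", 10, 5, n_eggs=20, n_adults=30)
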