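"""Normal engine: information, canonical joint law, quadrature accuracy."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import multivariate_normal as mvn

import gspoisson as gp
from gspoisson import exact, normal, skellam


class TestInformation:
    def test_values(self):
        rates = gp.PoissonRates(15.0, 15.0)
        np.testing.assert_allclose(normal.information_levels(1, 30, rates), [1.0])
        np.testing.assert_allclose(
            normal.information_levels(3, 10, gp.PoissonRates(2.0, 3.0)), [2.0, 4.0, 6.0]
        )

    def test_strictly_increasing(self):
        info = normal.information_levels(8, 7, gp.PoissonRates(1.3, 0.4))
        assert np.all(np.diff(info) > 0)

    def test_canonical_covariance(self):
        _, cov = normal.canonical_mean_cov(4, 5, gp.PoissonRates(2, 1))
        assert np.allclose(np.diag(cov), 1.0)
        assert cov[0, 1] == pytest.approx(np.sqrt(1 / 2))
        assert cov[1, 3] == pytest.approx(np.sqrt(2 / 4))
        # positive definite well beyond the stage counts used in practice
        _, cov25 = normal.canonical_mean_cov(25, 5, gp.PoissonRates(2, 1))
        assert np.linalg.eigvalsh(cov25).min() > 0


class TestStageProbs:
    def test_single_stage_closed_form(self):
        design = gp.GroupSequentialDesign(1, 50, (1.6449,), (1.6449,), "normal")
        A, R = normal.normal_stage_probs(design, gp.PoissonRates(15, 15))
        assert R[0] == pytest.approx(float(stats.norm.sf(1.6449)), abs=1e-10)
        assert A[0] + R[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_stage_power_at_reference_design(self):
        # n = 71 with r = Phi^{-1}(0.95) gives power 0.802 at the least
        # informative alternative (lambda1 = 30, lambda2 = 27.75)
        design = gp.GroupSequentialDesign(1, 71, (1.6448536269514722,), (1.6448536269514722,), "normal")
        A, _ = normal.normal_stage_probs(design, gp.PoissonRates(30.0, 27.75))
        assert round(1 - A[0], 3) == 0.802

    @pytest.mark.parametrize(
        "design,rates",
        [
            (gp.GroupSequentialDesign(2, 38, (0.42, 1.67), (2.17, 1.67), "normal"), gp.PoissonRates(15, 12.75)),
            (gp.GroupSequentialDesign(2, 20, (0.0, 1.9), (2.1, 1.9), "normal"), gp.PoissonRates(4, 4)),
            (gp.GroupSequentialDesign(3, 29, (0.42, 0.80, 1.60), (2.33, 2.21, 1.60), "normal"), gp.PoissonRates(15, 15)),
        ],
    )
    def test_rectangle_probabilities_match_mvn_oracle(self, design, rates):
        """Stage probabilities equal multivariate normal rectangle probabilities."""
        A, R = normal.normal_stage_probs(design, rates)
        mean, cov = normal.canonical_mean_cov(design.K, design.n, rates)
        for k in range(1, design.K + 1):
            m, c = mean[:k], cov[:k, :k]
            lower = list(design.a[: k - 1]) + [-np.inf]
            upper = list(design.r[: k - 1]) + [design.a[k - 1]]
            a_or = mvn.cdf(np.array(upper), mean=m, cov=c, lower_limit=np.array(lower)) if k > 1 else float(
                stats.norm.cdf(design.a[0], loc=mean[0])
            )
            assert A[k - 1] == pytest.approx(float(a_or), abs=1e-5)
            lower = list(design.a[: k - 1]) + [design.r[k - 1]]
            upper = list(design.r[: k - 1]) + [np.inf]
            r_or = mvn.cdf(np.array(upper), mean=m, cov=c, lower_limit=np.array(lower)) if k > 1 else float(
                stats.norm.sf(design.r[0], loc=mean[0])
            )
            assert R[k - 1] == pytest.approx(float(r_or), abs=1e-5)

    def test_completeness(self):
        design = gp.GroupSequentialDesign(3, 29, (0.42, 0.80, 1.60), (2.33, 2.21, 1.60), "normal")
        A, R = normal.normal_stage_probs(design, gp.PoissonRates(8, 6))
        assert A.sum() + R.sum() == pytest.approx(1.0, abs=1e-5)

    def test_exact_engine_unsupported(self):
        design = gp.GroupSequentialDesign(1, 73, (110,), (110,), "exact")
        with pytest.raises(ValueError):
            normal.normal_stage_probs(design, gp.PoissonRates(15, 15))


class TestMaxError:
    def test_type_one_invariant_to_null_rate(self):
        design = gp.GroupSequentialDesign(2, 38, (0.42, 1.67), (2.17, 1.67), "normal")
        totals = []
        for lam in (15.0, 20.0, 30.0):
            _, R = normal.normal_stage_probs(design, gp.PoissonRates(lam, lam))
            totals.append(R.sum())
        assert max(totals) - min(totals) < 1e-6

    def test_single_stage_quantile_inversion(self, osah_problem):
        r1 = float(stats.norm.ppf(0.95))
        design = gp.GroupSequentialDesign(1, 40, (r1,), (r1,), "normal")
        assert normal.normal_max_error(design, osah_problem, "typeI") == pytest.approx(0.05, abs=1e-10)

    def test_type_two_maximized_at_interval_supremum(self, osah_problem):
        design = gp.GroupSequentialDesign(1, 71, (1.6449,), (1.6449,), "normal")
        worst = normal.normal_max_error(design, osah_problem, "typeII")
        for lam in np.linspace(15.5, 30, 20):
            A, _ = normal.normal_stage_probs(design, osah_problem.alt_rates(lam))
            assert A.sum() <= worst + 1e-12


class TestEss:
    def test_single_stage(self):
        design = gp.GroupSequentialDesign(1, 71, (1.6449,), (1.6449,), "normal")
        assert normal.normal_ess(design, gp.PoissonRates(15, 15)) == pytest.approx(142.0)

    def test_bounds_on_random_designs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            K = int(rng.integers(2, 4))
            a = np.sort(rng.uniform(-1, 1.2, K))
            r = a + rng.uniform(0.5, 2.5, K)
            a = list(a)
            r = list(r)
            a[-1] = r[-1]
            n = int(rng.integers(5, 60))
            design = gp.GroupSequentialDesign(K, n, tuple(a), tuple(r), "normal")
            rates = gp.PoissonRates(float(rng.uniform(1, 20)), float(rng.uniform(1, 20)))
            ess = normal.normal_ess(design, rates)
            assert 2 * n - 1e-9 <= ess <= 2 * K * n + 1e-9


def test_exact_and_normal_engines_agree_for_large_groups():
    """At n = 200 a single-stage exact boundary mapped to the standardized
    scale gives a rejection probability within 0.01 of the normal engine's."""
    n = 200
    for lam in (15.0, 22.0, 30.0):
        rates = gp.PoissonRates(lam, lam)
        sigma = np.sqrt(2 * n * lam)
        c = int(1.6 * sigma)
        exact_p = float(skellam.sf(c - 1, n * lam, n * lam))
        z = (c - 0.5) / sigma
        design = gp.GroupSequentialDesign(1, n, (z,), (z,), "normal")
        _, R = normal.normal_stage_probs(design, rates)
        assert abs(exact_p - R[0]) < 0.01
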