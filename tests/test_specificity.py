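import numpy as np
import pytest
from scipy.optimize import root
from scipy.stats import norm

from scabc import (
    DesignInfo,
    PeakGlmFit,
    PriorEstimate,
    call_specific_peaks,
    estimate_prior_sd,
    fit_map,
    fit_mle_no_intercept,
    iut_test,
    simulate,
    SimulationSpec,
)

from conftest import make_matrix


def random_design(rng, K=None, n=None):
    K = K or int(rng.integers(2, 5))
    n = n or int(rng.integers(3 * K, 40))
    labels = np.concatenate([np.arange(K), rng.integers(0, K, n - K)])
    h = rng.lognormal(2, 0.8, n)
    return DesignInfo.from_labels(labels, h)


class TestDesign:
    def test_partition_required(self):
        with pytest.raises(ValueError):
            DesignInfo(x=np.array([[1.0, 1.0], [1.0, 0.0]]), h=np.array([1.0, 1.0]))

    def test_positive_exposure_required(self):
        with pytest.raises(ValueError):
            DesignInfo.from_labels([0, 1], np.array([1.0, 0.0]))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            DesignInfo(x=np.array([[1.0, 0.0], [1.0, 0.0]]), h=np.array([1.0, 1.0]))


class TestMle:
    def test_closed_form_value(self):
        # one cluster with total counts 10 and total exposure 5: beta = ln 2
        d = DesignInfo.from_labels([0, 0, 1], np.array([2.0, 3.0, 1.0]))
        y = np.array([4, 6, 3])
        b = fit_mle_no_intercept(y, d, pseudocount=0.0)
        assert b[0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert b[1] == pytest.approx(np.log(3.0), abs=1e-12)

    def test_pseudocount_only_on_zero_total(self):
        d = DesignInfo.from_labels([0, 1], np.array([1.0, 2.0]))
        b = fit_mle_no_intercept(np.array([0, 4]), d, pseudocount=0.5)
        assert b[0] == pytest.approx(np.log(0.5), abs=1e-12)
        assert b[1] == pytest.approx(np.log(2.0), abs=1e-12)  # 4/2, no pseudocount

    def test_symmetry_identical_clusters(self):
        d = DesignInfo.from_labels([0, 1], np.array([3.0, 3.0]))
        b = fit_mle_no_intercept(np.array([7, 7]), d)
        assert b[0] == b[1]

    def test_matches_numeric_score_root(self):
        # independent oracle: solve the Poisson score equations numerically
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 30:
            d = random_design(rng)
            y = rng.poisson(d.h * rng.uniform(0.2, 3.0), len(d.h))
            S, H = d.x.T @ y, d.cluster_exposure
            if np.any(S == 0):
                continue
            sol = root(lambda b: (S - np.exp(b) * H) / S,
                       np.full(d.K, np.log(y.sum() / d.h.sum())), tol=1e-13)
            assert np.abs((S - np.exp(sol.x) * H) / S).max() < 1e-9
            np.testing.assert_allclose(
                fit_mle_no_intercept(y, d, pseudocount=0.0), sol.x, atol=1e-8)
            checked += 1


class TestPrior:
    def test_constructed_quantile(self):
        # build a column whose centered 0.95-quantile of |.| is z_{0.025}
        rng = np.random.default_rng(0)
        z = norm.ppf(0.975)
        vals = np.linspace(-z, z, 200) / 0.95 * 0.95
        beta = np.stack([vals, -vals], axis=1)  # row means are 0
        pe = estimate_prior_sd(beta, q=0.05)
        expect = np.quantile(np.abs(vals), 0.95) / z
        assert pe.sigma[0] == pytest.approx(expect, rel=1e-12)

    def test_degenerate_floored(self):
        beta = np.ones((50, 3))
        pe = estimate_prior_sd(beta, q=0.05)
        np.testing.assert_allclose(pe.sigma, 1e-3)

    def test_monte_carlo_consistency(self):
        # iid N(0, sigma^2) columns: centered effects are N(0, sigma^2 (1-1/K)),
        # so quantile matching recovers sigma * sqrt(1 - 1/K)
        rng = np.random.default_rng(1)
        sigma, K, R = 1.7, 4, 100_000
        beta = rng.normal(0, sigma, size=(R, K))
        pe = estimate_prior_sd(beta, q=0.05)
        target = sigma * np.sqrt(1 - 1 / K)
        np.testing.assert_allclose(pe.sigma, target, rtol=0.05)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            estimate_prior_sd(np.full((1, 2), 1.0))


class TestMap:
    def test_diffuse_prior_matches_mle_rates(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = random_design(rng)
            y = rng.poisson(d.h * 0.8, len(d.h))
            prior = PriorEstimate(sigma=np.full(d.K, 1e6), q=0.05, beta_bar=np.zeros(1))
            fit = fit_map(y, d, prior)
            assert fit.converged
            rates_map = np.exp(fit.beta0 + fit.beta)
            rates_mle = np.exp(fit_mle_no_intercept(y, d, pseudocount=0.5))
            np.testing.assert_allclose(rates_map, rates_mle, rtol=1e-4)

    def test_tight_prior_collapses_effects(self):
        rng = np.random.default_rng(3)
        d = random_design(rng, K=3, n=24)
        y = rng.poisson(d.h * 1.2, 24)
        prior = PriorEstimate(sigma=np.full(3, 1e-6), q=0.05, beta_bar=np.zeros(1))
        fit = fit_map(y, d, prior)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-4)
        assert fit.beta0 == pytest.approx(np.log(y.sum() / d.h.sum()), abs=1e-4)

    def test_identical_clusters_equal_effects(self):
        d = DesignInfo.from_labels([0, 1], np.array([4.0, 4.0]))
        prior = PriorEstimate(sigma=np.full(2, 0.7), q=0.05, beta_bar=np.zeros(1))
        fit = fit_map(np.array([6, 6]), d, prior)
        assert fit.beta[0] == pytest.approx(fit.beta[1], abs=1e-10)

    def test_shrinkage_monotone_in_sigma(self):
        rng = np.random.default_rng(4)
        d = DesignInfo.from_labels([0] * 10 + [1] * 10, rng.lognormal(2, 0.5, 20))
        y = rng.poisson(d.h * np.where(np.arange(20) < 10, 2.0, 0.5))
        mags = []
        for s in [10.0, 1.0, 0.3, 0.1, 0.03, 0.01]:
            prior = PriorEstimate(sigma=np.full(2, s), q=0.05, beta_bar=np.zeros(1))
            fit = fit_map(y, d, prior)
            mags.append(np.abs(fit.beta).max())
        assert all(a >= b - 1e-10 for a, b in zip(mags, mags[1:]))

    def test_cov_is_inverse_neg_hessian(self):
        rng = np.random.default_rng(5)
        d = random_design(rng, K=3, n=30)
        y = rng.poisson(d.h, 30)
        prior = PriorEstimate(sigma=np.array([0.5, 1.0, 2.0]), q=0.05, beta_bar=np.zeros(1))
        fit = fit_map(y, d, prior)
        lam = d.cluster_exposure * np.exp(fit.beta0 + fit.beta)
        A = np.zeros((4, 4))
        A[0, 0] = lam.sum()
        A[0, 1:] = A[1:, 0] = lam
        A[1:, 1:] = np.diag(lam + 1.0 / prior.sigma**2)
        np.testing.assert_allclose(fit.cov, np.linalg.inv(A), rtol=1e-8, atol=1e-12)


class TestIut:
    def fit_with(self, beta, var=1.0):
        K = len(beta)
        return PeakGlmFit(
            beta0=0.0, beta=np.asarray(beta, dtype=float), beta_mle=None,
            cov=np.eye(K + 1), converged=True, iterations=1,
            _d_inv=np.full(K, var / 2.0), _u=np.zeros(K), _cov00=0.0,
        )

    def test_equal_effects_give_half(self):
        _, p = iut_test(self.fit_with([1.0, 1.0]), 0)
        assert p == 0.5

    def test_max_rule_k3(self):
        # components z = 3 and z = 1 against unit-variance contrasts
        z, p = iut_test(self.fit_with([3.0, 0.0, 2.0]), 0)
        np.testing.assert_allclose(z, [3.0, 1.0])
        assert p == pytest.approx(1.0 - norm.cdf(1.0), abs=1e-12)

    def test_p_is_max_of_components(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            K = int(rng.integers(2, 6))
            fit = self.fit_with(rng.normal(size=K), var=float(rng.uniform(0.5, 2.0)))
            k = int(rng.integers(K))
            z, p = iut_test(fit, k)
            assert p == np.max(norm.sf(z))

    def test_zero_se_sign_rule(self):
        fit = self.fit_with([2.0, 0.0], var=0.0)
        _, p = iut_test(fit, 0)
        assert p == 0.0
        _, p = iut_test(fit, 1)
        assert p == 1.0


class TestCallSpecificPeaks:
    def small_data(self, seed=0, fold=4.0):
        spec = SimulationSpec(n_cells_per_cluster=(40, 40), n_common_peaks=150,
                              n_specific_peaks_per_cluster=25, fold_change=fold,
                              seed=seed)
        return simulate(spec)

    def test_no_signal_peaks_excluded(self):
        cm, truth = self.small_data()
        cm.counts[:, 0] = 0
        d = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        res = call_specific_peaks(cm, d)
        row = res.table.iloc[0]
        assert not row["tested"] and row["reason"] == "no_signal"
        assert np.isnan(row["p_0"])

    def test_cutoff_one_flags_everything_converged(self):
        cm, truth = self.small_data()
        d = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        res = call_specific_peaks(cm, d, cutoff=1.0)
        df = res.table[res.table["tested"] & res.table["converged"]]
        assert (df["specific_cluster"] == df["best_cluster"]).all()
        assert (df["p_best"] < 1.0).all()

    def test_exposure_rescaling_invariance(self):
        cm, truth = self.small_data()
        d1 = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        d2 = DesignInfo.from_labels(truth.labels, cm.sample_depth * 37.0)
        r1 = call_specific_peaks(cm, d1)
        r2 = call_specific_peaks(cm, d2)
        for k in range(2):
            np.testing.assert_allclose(r1.table[f"p_{k}"], r2.table[f"p_{k}"],
                                       rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(r1.table[f"beta_{k}"], r2.table[f"beta_{k}"],
                                       atol=1e-8)
        np.testing.assert_allclose(r2.table["beta0"], r1.table["beta0"] - np.log(37.0),
                                   atol=1e-8)

    def test_within_cluster_cell_permutation_invariance(self):
        cm, truth = self.small_data()
        d = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        r1 = call_specific_peaks(cm, d)
        rng = np.random.default_rng(8)
        perm = np.concatenate([rng.permutation(40), 40 + rng.permutation(40)])
        cm2 = cm.subset_cells(perm)
        d2 = DesignInfo.from_labels(truth.labels[perm], cm2.sample_depth)
        r2 = call_specific_peaks(cm2, d2)
        for k in range(2):
            np.testing.assert_allclose(r1.table[f"p_{k}"], r2.table[f"p_{k}"],
                                       rtol=1e-10, atol=1e-14)

    def test_null_regime_rarely_calls_peaks(self):
        cm, truth = self.small_data(seed=5, fold=1.0)
        d = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        res = call_specific_peaks(cm, d)
        assert (res.table["specific_cluster"] >= 0).sum() == 0

    def test_bed_export(self, tmp_path):
        cm, truth = self.small_data(seed=2, fold=8.0)
        d = DesignInfo.from_labels(truth.labels, cm.sample_depth)
        res = call_specific_peaks(cm, d, cutoff=1e-2)
        bed = tmp_path / "c1.bed"
        res.to_bed(0, cm.peaks, bed)
        lines = bed.read_text().strip().splitlines()
        assert len(lines) == len(res.specific_peaks(0))
        if lines:
            fields = lines[0].split("\t")
            assert len(fields) == 5 and float(fields[4]) >= 0
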