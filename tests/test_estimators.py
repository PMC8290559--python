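"""MR estimators against closed-form oracles and exact worked examples."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrexposome.estimators import (
    cochran_q,
    egger,
    ivw,
    mvmr,
    wald_ratios,
    weighted_median,
)
from mrexposome.exceptions import (
    CollinearityError,
    DomainError,
    InsufficientInstrumentsError,
)
from tests.conftest import make_harmonized, random_harmonized


class TestWaldRatios:
    def test_basic_ratio(self):
        h = make_harmonized([0.2], [0.1], [0.01])
        r = wald_ratios(h).iloc[0]
        assert r["theta"] == pytest.approx(0.5, abs=1e-15)
        assert r["se"] == pytest.approx(0.05, abs=1e-15)
        assert r["w"] == pytest.approx(400.0, rel=1e-12)

    def test_sign_cancellation(self):
        h1 = make_harmonized([0.2], [0.1], [0.01])
        h2 = make_harmonized([-0.2], [-0.1], [0.01])
        assert wald_ratios(h1)["theta"].iloc[0] == wald_ratios(h2)["theta"].iloc[0]

    def test_weight_is_inverse_variance(self):
        rng = np.random.default_rng(0)
        h = random_harmonized(rng, 10)
        r = wald_ratios(h)
        assert np.allclose(r["w"], 1.0 / r["se"] ** 2)

    def test_zero_beta_x_names_snp(self):
        h = make_harmonized([0.2, 0.0], [0.1, 0.1], [0.01, 0.01])
        with pytest.raises(DomainError, match="rs0001"):
            wald_ratios(h)


class TestIVW:
    def test_proportional_toy(self, proportional_toy):
        est, het = ivw(proportional_toy)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(1400), abs=1e-9)
        assert het.q_stat == pytest.approx(0.0, abs=1e-18)
        assert est.or_point == pytest.approx(np.exp(0.5))

    def test_matches_weighted_least_squares_oracle(self):
        """theta_hat equals the one-parameter weighted normal-equation solve."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            h = random_harmonized(rng, int(rng.integers(3, 51)))
            est, _ = ivw(h)
            bx = h.records["beta_x"].to_numpy()
            by = h.records["beta_y"].to_numpy()
            w = 1.0 / h.records["se_y"].to_numpy() ** 2
            oracle = np.linalg.solve(
                np.array([[np.sum(w * bx * bx)]]), np.array([np.sum(w * bx * by)])
            )[0]
            assert est.beta_hat == pytest.approx(oracle, abs=1e-10)

    def test_sign_equivariance(self, proportional_toy):
        est1, _ = ivw(proportional_toy)
        neg = proportional_toy.records.copy()
        neg["beta_x"] = -neg["beta_x"]
        flipped = make_harmonized(
            neg["beta_x"], neg["beta_y"], neg["se_y"], sx=neg["se_x"]
        )
        est2, _ = ivw(flipped)
        assert est2.beta_hat == pytest.approx(-est1.beta_hat, abs=1e-15)
        assert est2.se == pytest.approx(est1.se, abs=1e-15)

    def test_pval_consistent_with_normal_reference(self):
        rng = np.random.default_rng(2)
        h = random_harmonized(rng, 12)
        est, _ = ivw(h)
        expected = 2 * sps.norm.sf(abs(est.beta_hat) / est.se)
        assert est.pval == pytest.approx(expected, abs=1e-9)

    def test_requires_two_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], [0.05], [0.01]))


class TestCochranQ:
    def test_identical_ratios(self, proportional_toy):
        r = wald_ratios(proportional_toy)
        het = cochran_q(r, 0.5)
        assert het.q_stat == pytest.approx(0.0, abs=1e-18)
        assert het.pval == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """theta = (0.4, 0.6), w = (100, 100), theta_hat = 0.5:
        Q = 100*0.01*2 = 2, p = P(chi2_1 >= 2)."""
        ratios = pd.DataFrame(
            {"snp_id": ["a", "b"], "theta": [0.4, 0.6],
             "se": [0.1, 0.1], "w": [100.0, 100.0]}
        )
        het = cochran_q(ratios, 0.5)
        assert het.q_stat == pytest.approx(2.0, abs=1e-12)
        assert het.df == 1
        assert het.pval == pytest.approx(sps.chi2.sf(2.0, 1), abs=1e-9)
        assert het.pval == pytest.approx(0.1573, abs=1e-4)

    def test_scaling_by_common_se_factor(self):
        rng = np.random.default_rng(3)
        h = random_harmonized(rng, 8)
        r1 = wald_ratios(h)
        est, _ = ivw(h)
        q1 = cochran_q(r1, est.beta_hat).q_stat
        c = 2.0
        scaled = make_harmonized(
            h.records["beta_x"], h.records["beta_y"],
            h.records["se_y"] * c, sx=h.records["se_x"],
        )
        r2 = wald_ratios(scaled)
        est2, _ = ivw(scaled)
        q2 = cochran_q(r2, est2.beta_hat).q_stat
        assert q2 == pytest.approx(q1 / c**2, rel=1e-12)


class TestEgger:
    def test_proportional_toy_perfect_fit(self, proportional_toy):
        slope, intercept = egger(proportional_toy)
        assert slope.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta_hat == pytest.approx(0.0, abs=1e-12)

    def test_affine_toy(self, affine_toy):
        slope, intercept = egger(affine_toy)
        assert slope.beta_hat == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta_hat == pytest.approx(0.02, abs=1e-12)

    def test_matches_weighted_regression_oracle(self):
        """Slope and intercept equal the two-parameter weighted
        normal-equation solve with beta_x oriented positive."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            h = random_harmonized(rng, int(rng.integers(3, 51)))
            slope, intercept = egger(h)
            bx = h.records["beta_x"].to_numpy().copy()
            by = h.records["beta_y"].to_numpy().copy()
            flip = np.where(bx < 0, -1.0, 1.0)
            bx, by = bx * flip, by * flip
            w = 1.0 / h.records["se_y"].to_numpy() ** 2
            X = np.column_stack([np.ones_like(bx), bx])
            coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
            assert intercept.beta_hat == pytest.approx(coef[0], abs=1e-10)
            assert slope.beta_hat == pytest.approx(coef[1], abs=1e-10)

    def test_pval_consistent_with_t_reference(self):
        rng = np.random.default_rng(5)
        h = random_harmonized(rng, 15)
        slope, _ = egger(h)
        expected = 2 * sps.t.sf(abs(slope.beta_hat) / slope.se, 15 - 2)
        assert slope.pval == pytest.approx(expected, abs=1e-9)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_collinear_betas_rejected(self):
        h = make_harmonized([0.1, 0.1, -0.1], [0.05, 0.06, -0.04],
                            [0.01, 0.01, 0.01])
        with pytest.raises(CollinearityError):
            egger(h)


class TestWeightedMedian:
    def test_constant_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.03, 0.06, 0.12],
                            [0.01, 0.02, 0.05])
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta_hat == pytest.approx(0.3, abs=1e-12)

    def test_interpolation_oracle(self):
        """theta (0.1, 0.5, 0.9) with normalized weights (0.2, 0.6, 0.2):
        cumulative midpoints are (0.1, 0.5, 0.9), so the estimate is 0.5."""
        # choose bx, by, sy realizing those ratios and weights
        bx = np.array([1.0, np.sqrt(3.0), 1.0])
        sy = np.ones(3)
        by = np.array([0.1, 0.5, 0.9]) * bx
        h = make_harmonized(bx, by, sy)
        w = bx**2  # (1, 3, 1) -> normalized (0.2, 0.6, 0.2)
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-12)
        # brute-force cumulative-weight interpolation oracle
        order = np.argsort(by / bx)
        t, ww = (by / bx)[order], (w / w.sum())[order]
        p = np.cumsum(ww) - ww / 2
        assert np.interp(0.5, p, t) == pytest.approx(0.5, abs=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        h = random_harmonized(rng, 10)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se and a.beta_hat == b.beta_hat

    def test_seed_required(self):
        rng = np.random.default_rng(6)
        h = random_harmonized(rng, 10)
        with pytest.raises(DomainError):
            weighted_median(h, n_boot=100, seed=None)


class TestMVMR:
    def test_exact_construction(self):
        rng = np.random.default_rng(7)
        j = 20
        x1 = rng.normal(0.1, 0.05, j)
        x2 = rng.normal(0.1, 0.05, j)
        by = 0.5 * x1
        ests = mvmr(np.column_stack([x1, x2]), by, np.full(j, 0.01),
                    ["x1", "x2"])
        assert ests[0].beta_hat == pytest.approx(0.5, abs=1e-10)
        assert ests[1].beta_hat == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            j, k = int(rng.integers(6, 51)), int(rng.integers(2, 5))
            X = rng.normal(0.1, 0.05, (j, k))
            sy = rng.uniform(0.005, 0.05, j)
            y = X @ rng.normal(0.3, 0.2, k) + rng.normal(0, sy)
            ests = mvmr(X, y, sy)
            w = 1.0 / sy**2
            coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            for i in range(k):
                assert ests[i].beta_hat == pytest.approx(coef[i], abs=1e-10)

    def test_k1_nests_ivw(self, proportional_toy):
        est_ivw, _ = ivw(proportional_toy)
        bx = proportional_toy.records["beta_x"].to_numpy()[:, None]
        by = proportional_toy.records["beta_y"].to_numpy()
        sy = proportional_toy.records["se_y"].to_numpy()
        est_mv = mvmr(bx, by, sy)[0]
        assert est_mv.beta_hat == pytest.approx(est_ivw.beta_hat, abs=1e-12)

    def test_rank_deficiency_rejected(self):
        x1 = np.linspace(0.1, 0.5, 10)
        X = np.column_stack([x1, 2 * x1])
        with pytest.raises(CollinearityError):
            mvmr(X, 0.5 * x1, np.full(10, 0.01))

    def test_j_must_exceed_k(self):
        with pytest.raises(InsufficientInstrumentsError):
            mvmr(np.ones((2, 2)), np.ones(2), np.ones(2))


class TestStatisticalProperties:
    def test_estimators_consistent_without_pleiotropy(self):
        """At J=30 and se_y=0.01, the mean estimate over 500 replicates is
        within 0.02 of the true effect for IVW, Egger, and the WM."""
        rng = np.random.default_rng(9)
        theta = 0.3
        biases = {"ivw": [], "egger": [], "wm": []}
        for _ in range(500):
            j = 30
            bx = rng.normal(0.05, 0.02, j)
            bx[np.abs(bx) < 0.01] = 0.01
            sy = np.full(j, 0.01)
            by = rng.normal(theta * bx, sy)
            h = make_harmonized(bx, by, sy, sx=1e-4)
            biases["ivw"].append(ivw(h)[0].beta_hat - theta)
            biases["egger"].append(egger(h)[0].beta_hat - theta)
            biases["wm"].append(
                weighted_median(h, n_boot=50, seed=int(rng.integers(2**31)))
                .beta_hat - theta
            )
        for name, b in biases.items():
            assert abs(np.mean(b)) < 0.02, name

    def test_ivw_null_pvalues_uniform(self):
        """Kolmogorov-Smirnov distance of null IVW p-values from uniform."""
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(1000):
            j = 50
            bx = rng.normal(0.05, 0.02, j)
            bx[np.abs(bx) < 0.01] = 0.01
            sy = np.full(j, 0.01)
            by = rng.normal(0.0, sy, j)
            h = make_harmonized(bx, by, sy, sx=1e-4)
            pvals.append(ivw(h)[0].pval)
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.05
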