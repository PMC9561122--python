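"""Univariable estimators: closed-form oracles, robustness, degeneracies."""

import numpy as np
import pytest
from scipy import stats

from mrtri import (SimConfig, contamination_mixture, egger, harmonize, ivw,
                   mr_presso, mr_raps, simulate_sumstats, wald_ratios,
                   weighted_median, weighted_mode)
from mrtri.univariable import UNIVARIABLE_METHODS, _weighted_median_stat

from conftest import make_hset


def ivw_normal_equations_oracle(g, G, Gse):
    """Independent weighted least squares through the origin via the
    normal equations, coded separately from the estimator."""
    W = np.diag(1.0 / np.asarray(Gse, float) ** 2)
    X = np.asarray(g, float)[:, None]
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ np.asarray(G, float))[0]
    fixed_se = np.sqrt(np.linalg.inv(xtwx)[0, 0])
    resid = np.asarray(G) - beta * np.asarray(g)
    rss = float(resid @ W @ resid)
    phi = np.sqrt(rss / (len(g) - 1))
    return beta, fixed_se * max(phi, 1.0)


class TestIVW:
    def test_k1_wald_ratio(self):
        h = make_hset([0.5], 0.01, [0.25], [0.1])
        est = ivw(h)
        assert est.method == "wald_ratio"
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_exact_collinear_input_closed_form(self):
        h = make_hset([0.2, 0.4, 0.6], 0.0, [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        est = ivw(h)
        assert est.estimate == pytest.approx(0.5, abs=1e-12)
        # phi = 0 floored to 1 -> fixed-effect SE sqrt(1/56)
        assert est.se == pytest.approx(np.sqrt(1 / 56), abs=1e-12)
        assert est.diagnostics["cochran_q"] == pytest.approx(0.0, abs=1e-20)

    def test_joint_negation_invariance(self, clean_hset):
        est0 = ivw(clean_hset)
        h = make_hset(-clean_hset.exposure_beta[:, 0],
                      clean_hset.exposure_se[:, 0],
                      -clean_hset.outcome_beta, clean_hset.outcome_se)
        est1 = ivw(h)
        assert est1.estimate == pytest.approx(est0.estimate, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 6)
        g = rng.normal(0.1, 0.05, k)
        G = rng.normal(0.05, 0.03, k)
        Gse = rng.uniform(0.01, 0.05, k)
        est = ivw(make_hset(g, 0.0, G, Gse))
        beta, se = ivw_normal_equations_oracle(g, G, Gse)
        assert est.estimate == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_scale_equivariance(self, clean_hset):
        c = 3.7
        est0 = ivw(clean_hset)
        h = make_hset(clean_hset.exposure_beta[:, 0],
                      clean_hset.exposure_se[:, 0],
                      c * clean_hset.outcome_beta, c * clean_hset.outcome_se)
        est1 = ivw(h)
        assert est1.estimate == pytest.approx(c * est0.estimate, rel=1e-12)
        assert est1.se == pytest.approx(c * est0.se, rel=1e-12)


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        g = np.array([0.2, 0.4, 0.6])
        G = 0.05 + 0.5 * g
        est = egger(make_hset(g, 0.0, G, [0.1, 0.1, 0.1]))
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
        assert est.diagnostics["egger_intercept"] == pytest.approx(0.05,
                                                                   abs=1e-10)

    def test_constant_outcome_shift_moves_only_intercept(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.1, 0.5, 6)
        G = 0.4 * g + rng.normal(0, 0.01, 6)
        h0 = make_hset(g, 0.0, G, np.full(6, 0.05))
        h1 = make_hset(g, 0.0, G + 0.3, np.full(6, 0.05))
        e0, e1 = egger(h0), egger(h1)
        assert e1.estimate == pytest.approx(e0.estimate, abs=1e-10)
        assert e1.diagnostics["egger_intercept"] == pytest.approx(
            e0.diagnostics["egger_intercept"] + 0.3, abs=1e-10)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError, match="k >= 3"):
            egger(make_hset([0.1, 0.2], 0.0, [0.05, 0.1], [0.1, 0.1]))

    def test_intercept_estimates_mean_directional_pleiotropy(self):
        """With InSIDE-respecting directional pleiotropy and strong
        instruments (the intercept is unbiased only under negligible
        exposure-side noise) the intercept averages to the mean direct
        effect across replicates."""
        icepts = []
        for rep in range(60):
            cfg = SimConfig(n_snps=40, causal_effects=(0.3,),
                            exposure_names=("x",), exposure_h2=(0.05,),
                            n_exposure_samples=20_000_000,
                            pleiotropy_prob=1.0, pleiotropy_mean=0.02,
                            pleiotropy_sd=0.005, seed=40_000 + rep)
            tables, _ = simulate_sumstats(cfg)
            h = harmonize([tables["x"]], tables["outcome"])
            icepts.append(egger(h).diagnostics["egger_intercept"])
        mean = np.mean(icepts)
        mc_se = np.std(icepts, ddof=1) / np.sqrt(len(icepts))
        assert abs(mean - 0.02) < 4 * mc_se


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        h = make_hset([0.2, 0.4, 0.6], 0.0, [0.14, 0.28, 0.42],
                      [0.05, 0.05, 0.05])
        assert weighted_median(h, n_boot=50, seed=0).estimate == \
            pytest.approx(0.7, abs=1e-10)

    def test_equal_weight_midpoint_interpolation(self):
        # ratios (0.4, 0.5, 0.9), equal weights -> cumulative midpoints
        # (1/6, 1/2, 5/6); 0.5 lands exactly on the middle ratio
        assert _weighted_median_stat(np.array([0.4, 0.5, 0.9]),
                                     np.ones(3)) == pytest.approx(0.5)

    def test_breakdown_resistance_vs_ivw(self):
        """40% of SNPs with large pleiotropic offsets: the median stays near
        truth while IVW is dragged away."""
        rng = np.random.default_rng(5)
        k = 30
        g = rng.uniform(0.05, 0.15, k)
        Gse = np.full(k, 0.004)
        G = 0.5 * g + rng.normal(0, Gse)
        G[:12] += 0.08  # invalid minority
        h = make_hset(g, 0.0, G, Gse)
        med = weighted_median(h, n_boot=300, seed=1)
        naive = ivw(h)
        assert abs(med.estimate - 0.5) < 3 * med.se
        assert abs(naive.estimate - 0.5) > 3 * naive.se


class TestWeightedMode:
    def test_all_ratios_equal(self):
        h = make_hset([0.2, 0.4, 0.6], 0.0, [0.14, 0.28, 0.42],
                      [0.05, 0.05, 0.05])
        assert weighted_mode(h, n_boot=50, seed=0).estimate == \
            pytest.approx(0.7, abs=1e-3)

    def test_majority_cluster_wins_with_small_bandwidth(self):
        g = np.array([0.2, 0.25, 0.3, 0.1])
        G = np.array([0.1, 0.125, 0.15, 0.5])  # ratios 0.5,0.5,0.5,5.0
        h = make_hset(g, 0.0, G, np.full(4, 0.01))
        est = weighted_mode(h, bandwidth_factor=0.5, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(0.5, abs=0.05)

    def test_invariant_to_duplicating_modal_cluster(self):
        g = np.array([0.2, 0.25, 0.3, 0.1])
        G = np.array([0.1, 0.125, 0.15, 0.5])
        h1 = make_hset(g, 0.0, G, np.full(4, 0.01))
        g2 = np.concatenate([g, g[:3]])
        G2 = np.concatenate([G, G[:3]])
        h2 = make_hset(g2, 0.0, G2, np.full(7, 0.01))
        e1 = weighted_mode(h1, bandwidth_factor=0.5, n_boot=50, seed=0)
        e2 = weighted_mode(h2, bandwidth_factor=0.5, n_boot=50, seed=0)
        assert e2.estimate == pytest.approx(e1.estimate, abs=0.05)


class TestRAPS:
    def test_limiting_equivalence_to_fixed_effect_ivw(self):
        rng = np.random.default_rng(7)
        k = 10
        g = rng.uniform(0.1, 0.3, k)
        Gse = rng.uniform(0.01, 0.03, k)
        G = 0.4 * g + rng.normal(0, Gse)
        h = make_hset(g, 1e-12, G, Gse)  # negligible exposure noise
        est = mr_raps(h, robust_loss="none", overdispersion=False)
        w = 1 / Gse**2
        fixed = np.sum(w * g * G) / np.sum(w * g * g)
        assert est.estimate == pytest.approx(fixed, abs=1e-6)

    def test_k1_wald_ratio(self):
        h = make_hset([0.5], 0.01, [0.25], [0.1])
        assert mr_raps(h).method == "wald_ratio"

    def test_weak_instrument_bias_smaller_than_ivw(self):
        """With weak instruments, IVW's ratio-attenuation bias exceeds the
        profile-score estimator's over replicates."""
        ivw_err, raps_err = [], []
        for rep in range(40):
            cfg = SimConfig(n_snps=100, n_exposure_samples=8_000,
                            n_outcome_samples=80_000, exposure_h2=(0.02,),
                            causal_effects=(0.4,), exposure_names=("x",),
                            seed=60_000 + rep)
            tables, _ = simulate_sumstats(cfg)
            h = harmonize([tables["x"]], tables["outcome"])
            ivw_err.append(ivw(h).estimate - 0.4)
            raps_err.append(mr_raps(h, robust_loss="none").estimate - 0.4)
        assert abs(np.mean(raps_err)) < abs(np.mean(ivw_err))


class TestContaminationMixture:
    def test_consistent_snps_all_valid(self):
        rng = np.random.default_rng(9)
        k = 20
        g = rng.uniform(0.1, 0.3, k)
        Gse = np.full(k, 0.01)
        G = 0.5 * g + rng.normal(0, Gse)
        est = contamination_mixture(make_hset(g, 0.0, G, Gse))
        assert est.estimate == pytest.approx(0.5, abs=0.05)
        assert est.diagnostics["n_valid"] == k

    def test_matches_coarse_grid_oracle(self):
        """Grid argmax of the two-component profile log-likelihood, coded
        independently on a fixed ratio set."""
        g = np.array([0.2, 0.25, 0.4, 0.5])
        G = np.array([0.11, 0.12, 0.19, 0.24])
        Gse = np.array([0.01, 0.012, 0.015, 0.011])
        psi = 0.4
        est = contamination_mixture(make_hset(g, 0.0, G, Gse), psi=psi)
        r, v = G / g, Gse**2 / g**2
        grid = np.linspace(-2, 2, 40001)
        ll = np.array([
            np.sum(np.maximum(stats.norm.logpdf(r, b, np.sqrt(v)),
                              stats.norm.logpdf(r, 0, np.sqrt(v + psi**2))))
            for b in grid])
        assert est.estimate == pytest.approx(grid[np.argmax(ll)], abs=2e-3)

    def test_majority_cluster_wins(self):
        g = np.concatenate([np.full(6, 0.2), np.full(4, 0.2)])
        G = np.concatenate([np.full(6, 0.1), np.full(4, 0.4)])
        G += np.linspace(-1e-4, 1e-4, 10)
        est = contamination_mixture(make_hset(g, 0.0, G, np.full(10, 0.002)),
                                    psi=1.0)
        assert est.estimate == pytest.approx(0.5, abs=0.05)

    def test_k1_ratio_with_chi2_ci(self):
        h = make_hset([0.5], 0.0, [0.25], [0.1])
        est = contamination_mixture(h)
        assert est.estimate == pytest.approx(0.5, abs=1e-3)
        assert est.ci_low < 0.5 < est.ci_high


class TestPRESSO:
    def test_fixed_seed_identical_report(self, clean_hset):
        a = mr_presso(clean_hset, n_sim=100, seed=3)
        b = mr_presso(clean_hset, n_sim=100, seed=3)
        assert a.estimate == b.estimate
        assert a.diagnostics["global_p"] == b.diagnostics["global_p"]
        assert a.diagnostics["outlier_ids"] == b.diagnostics["outlier_ids"]

    def test_spiked_outlier_flagged_and_corrected(self):
        rng = np.random.default_rng(11)
        k = 20
        g = rng.uniform(0.1, 0.3, k)
        Gse = np.full(k, 0.01)
        G = 0.5 * g + rng.normal(0, Gse)
        G[7] += 30 * Gse[7]
        h = make_hset(g, 0.0, G, Gse)
        est = mr_presso(h, n_sim=500, seed=0)
        assert "rs7" in est.diagnostics["outlier_ids"]
        raw = est.diagnostics["raw_estimate"]
        assert abs(est.estimate - 0.5) < abs(raw - 0.5)
        assert est.diagnostics["global_p"] < 0.05

    def test_requires_four_snps(self):
        with pytest.raises(ValueError, match="k >= 4"):
            mr_presso(make_hset([0.1, 0.2, 0.3], 0.0, [0.05, 0.1, 0.15],
                                [0.1, 0.1, 0.1]))


class TestTriangulation:
    def test_all_estimators_agree_on_clean_data(self, clean_hset, clean_sim):
        """On strong-instrument, no-pleiotropy data, all seven estimators
        land within 2 SE of each other and of the simulated truth."""
        _, _, truth = clean_sim
        beta_true = truth.causal_effects[1]  # wc exposure
        results = {}
        for name, fn in UNIVARIABLE_METHODS.items():
            if name in ("weighted_median", "weighted_mode"):
                est = fn(clean_hset, n_boot=300, seed=0)
            elif name == "mr_presso":
                est = fn(clean_hset, n_sim=300, seed=0)
            else:
                est = fn(clean_hset)
            results[name] = est
        for name, est in results.items():
            assert abs(est.estimate - beta_true) <= 2 * max(est.se, 1e-3), name
        for a in results.values():
            for b in results.values():
                tol = 2 * max(np.hypot(a.se, b.se), 1e-3)
                assert abs(a.estimate - b.estimate) <= tol


def test_wald_ratios_second_order_term():
    h = make_hset([0.5, 0.4], [0.05, 0.05], [0.25, 0.2], [0.1, 0.1])
    first = wald_ratios(h)
    second = wald_ratios(h, second_order=True)
    assert np.all(second.variances > first.variances)
    np.testing.assert_allclose(first.ratios, [0.5, 0.5])
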