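"""Estimator panel: exact small-sample oracles, invariants, degenerate inputs."""

import numpy as np
import pytest
from scipy import stats

from mrmed import (
    InsufficientInstrumentsError,
    MREstimate,
    cochran_q,
    egger,
    estimates_frame,
    ivw,
    leave_one_out,
    mode_estimate,
    mr_all,
    steiger,
    wald_ratio,
    weighted_median,
)
from mrmed.estimators import Z95, _mode_point, _weighted_median_point


class TestWaldRatio:
    def test_arithmetic(self):
        e = wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert e.beta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.05).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_first_order_se_close_to_full_delta_for_strong_instruments(self):
        # full second-order delta SE: sqrt(so^2/bx^2 + bo^2 sx^2 / bx^4)
        bx, sx, bo, so = 0.2, 0.01, 0.1, 0.05
        assert sx / bx < 0.1
        first = wald_ratio(bx, sx, bo, so).se
        full = np.sqrt(so**2 / bx**2 + bo**2 * sx**2 / bx**4)
        assert first == pytest.approx(full, rel=0.05)


class TestIVW:
    def test_exact_proportionality(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3], 0.01, [0.1, 0.2, 0.3], 0.1)
        e = ivw(h)
        assert e.beta == pytest.approx(1.0)
        q, df, qp = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert not e.random_effects  # Q = 0 < df: fixed-effect SE

    def test_constant_ratios(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.4], 0.01, [0.05, 0.1, 0.2], 0.1)
        e = ivw(h)
        assert e.beta == pytest.approx(0.5)
        w = np.array([0.1, 0.2, 0.4]) ** 2 / 0.1**2
        assert e.se == pytest.approx(1 / np.sqrt(w.sum()))

    def test_requires_two_instruments(self, make_harmonized):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], 0.01, [0.1], 0.1))

    def test_single_instrument_pipeline_reduces_to_wald(self, make_harmonized):
        h = make_harmonized([0.1], 0.01, [0.07], 0.05)
        (only,) = mr_all(h)
        wald = wald_ratio(0.1, 0.01, 0.07, 0.05)
        assert only.method == "wald_ratio"
        assert only.beta == pytest.approx(wald.beta)
        assert only.se == pytest.approx(wald.se)

    def test_invariant_to_joint_sign_flip(self, make_harmonized):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.2, 0.05, 10)
        by = rng.normal(0.1, 0.05, 10)
        h1 = make_harmonized(bx, 0.01, by, 0.1)
        bx2, by2 = bx.copy(), by.copy()
        bx2[::2] *= -1
        by2[::2] *= -1
        h2 = make_harmonized(bx2, 0.01, by2, 0.1)
        assert ivw(h2).beta == pytest.approx(ivw(h1).beta)
        assert ivw(h2).se == pytest.approx(ivw(h1).se)

    def test_random_effects_inflation_fires_on_heterogeneity(self, make_harmonized):
        h = make_harmonized([0.1, 0.1, 0.1, 0.1], 0.001,
                            [0.0, 0.05, 0.2, 0.5], 0.01)
        e = ivw(h)
        q, df, _ = cochran_q(h)
        assert q > df and e.random_effects
        w = np.full(4, 0.1**2 / 0.01**2)
        assert e.se == pytest.approx(np.sqrt(q / df) / np.sqrt(w.sum()))


class TestEgger:
    def test_exact_line_recovered_to_machine_precision(self, make_harmonized):
        # Gamma_j = a + b * gamma_j with no noise
        a, b = 0.03, 0.7
        bx = np.array([0.1, 0.15, 0.22, 0.3, 0.41])
        by = a + b * bx
        res = egger(make_harmonized(bx, 0.01, by, 0.05))
        assert res.intercept == pytest.approx(a, abs=1e-12)
        assert res.slope.beta == pytest.approx(b, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-18)

    def test_orients_negative_exposure_betas(self, make_harmonized):
        a, b = 0.02, 0.5
        bx = np.array([0.1, -0.15, 0.22, -0.3, 0.41])
        by = a * np.sign(bx) + b * bx  # pleiotropy rides the oriented allele
        res = egger(make_harmonized(bx, 0.01, by, 0.05))
        assert res.intercept == pytest.approx(a, abs=1e-12)
        assert res.slope.beta == pytest.approx(b, abs=1e-12)

    def test_requires_three_instruments(self, make_harmonized):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], 0.01, [0.1, 0.2], 0.1))

    def test_slope_pvalue_uses_t_distribution(self, make_harmonized):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.4, 6)
        by = 0.3 * bx + rng.normal(0, 0.05, 6)
        res = egger(make_harmonized(bx, 0.01, by, 0.05))
        expected = 2 * stats.t.sf(abs(res.slope.beta / res.slope.se), 4)
        assert res.slope.pval == pytest.approx(expected)


class TestWeightedMedian:
    def test_equal_ratios_collapse(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3], 0.0001, [0.05, 0.1, 0.15], 0.0001)
        e = weighted_median(h, n_boot=300, seed=0)
        assert e.beta == pytest.approx(0.5)
        assert e.se < 0.01  # bootstrap SE shrinks with the input SEs

    def test_hand_computed_interpolation(self):
        # ratios {1, 2, 10} with equal weights: cumulative (1/6, 1/2, 5/6)
        # hits 0.5 exactly at the middle order statistic
        beta = _weighted_median_point(np.array([1.0, 2.0, 10.0]), np.ones(3))
        assert beta == pytest.approx(2.0)

    def test_interpolates_between_order_statistics(self):
        # weights (1,3)/4: cumulative (1/8, 5/8): 0.5 lies 3/4 of the way
        beta = _weighted_median_point(np.array([0.0, 1.0]), np.array([1.0, 3.0]))
        assert beta == pytest.approx(0.75)

    def test_requires_three_instruments(self, make_harmonized):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_harmonized([0.1, 0.2], 0.01, [0.1, 0.2], 0.1))

    def test_skip_bootstrap_gives_nan_se(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3], 0.01, [0.05, 0.1, 0.15], 0.1)
        e = weighted_median(h, n_boot=0)
        assert np.isnan(e.se) and np.isnan(e.pval)


class TestModeEstimate:
    def test_equal_ratios_collapse(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3], 0.001, [0.05, 0.1, 0.15], 0.001)
        e = mode_estimate(h, n_boot=0)
        assert e.beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_cluster_wins(self, make_harmonized):
        h = make_harmonized([0.1] * 4, 0.01, [0.0, 0.0, 0.0, 0.5], 0.05)
        e = mode_estimate(h, weighted=False, n_boot=0)
        assert abs(e.beta) < 1.0  # mode near the {0,0,0} cluster, not near 5

    def test_grid_argmax_matches_refined_grid(self, make_harmonized):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ratios = rng.normal(0.3, 0.2, 25)
            w = np.ones(25)
            coarse = _mode_point(ratios, w, 1.0)
            # 100x finer grid over the same span
            sd = np.std(ratios, ddof=1)
            mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
            h_ = 0.9 * min(sd, mad) * 25 ** (-0.2)
            grid = np.linspace(ratios.min() - 3 * h_, ratios.max() + 3 * h_, 51200)
            dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h_) ** 2).sum(axis=1)
            fine = grid[np.argmax(dens)]
            step = (grid[-1] - grid[0]) / 511
            assert abs(coarse - fine) <= step

    def test_weighted_variant_label(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3, 0.15], 0.01, [0.05, 0.1, 0.15, 0.07], 0.1)
        assert mode_estimate(h, weighted=True, n_boot=0).method == "weighted_mode"
        assert mode_estimate(h, weighted=False, n_boot=0).method == "simple_mode"


class TestEggerPleiotropy:
    """Intercept behaviour under simulated horizontal pleiotropy."""

    def _cfg(self, mode, mean, sd):
        from mrmed import SimulationConfig

        return SimulationConfig(
            m_snps=100, m_mediator_snps=0, n_exposure=1_000_000,
            theta_total=0.25, theta_em=0.0, theta_mo=0.0,
            pleiotropy_mode=mode, prop_invalid=1.0,
            pleiotropy_mean=mean, pleiotropy_sd=sd,
            prop_palindromic=0.0, ld_block_size=1,
        )

    def test_directional_intercept_recovers_mean_with_high_power(self):
        from mrmed import harmonize, simulate_triplet

        cfg = self._cfg("directional", mean=0.05, sd=0.025)  # mean = 2*sd
        icps, hits = [], 0
        for rep in range(60):
            e, _m, o, _t = simulate_triplet(cfg.with_(seed=8000 + rep))
            res = egger(harmonize(e, o))
            icps.append(res.intercept)
            hits += res.intercept_pval < 0.05
        icps = np.asarray(icps)
        mcse = icps.std(ddof=1) / np.sqrt(len(icps))
        assert abs(icps.mean() - 0.05) < 2 * mcse + 0.002
        assert hits / 60 >= 0.80  # detection power

    def test_balanced_pleiotropy_leaves_intercept_at_zero(self):
        from mrmed import harmonize, simulate_triplet

        cfg = self._cfg("balanced", mean=0.0, sd=0.025)
        icps = []
        for rep in range(60):
            e, _m, o, _t = simulate_triplet(cfg.with_(seed=8500 + rep))
            icps.append(egger(harmonize(e, o)).intercept)
        icps = np.asarray(icps)
        assert abs(icps.mean()) < 3 * icps.std(ddof=1) / np.sqrt(len(icps))


class TestCochranQ:
    def test_homogeneous_gives_zero(self, make_harmonized):
        h = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.1], 0.1)
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1 and p == pytest.approx(1.0)

    def test_outlier_strictly_increases_q(self, make_harmonized):
        base_x = [0.1, 0.2, 0.3]
        base_y = [0.05, 0.1, 0.15]
        q0, _, _ = cochran_q(make_harmonized(base_x, 0.01, base_y, 0.1))
        q1, _, _ = cochran_q(
            make_harmonized(base_x + [0.1], 0.01, base_y + [0.4], 0.1)
        )
        assert q1 > q0


class TestSteiger:
    def test_equal_variance_explained_gives_pval_one(self, make_harmonized):
        h = make_harmonized([0.1, 0.2], 0.01, [0.1, 0.2], 0.01,
                            n_exp=5000, n_out=5000)
        res = steiger(h)
        assert res.pval == pytest.approx(1.0)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)

    def test_swapping_roles_flips_direction(self, make_harmonized):
        h = make_harmonized([0.5, 0.6], 0.01, [0.05, 0.06], 0.01,
                            n_exp=5000, n_out=5000)
        fwd = steiger(h)
        swapped = make_harmonized([0.05, 0.06], 0.01, [0.5, 0.6], 0.01,
                                  n_exp=5000, n_out=5000)
        rev = steiger(swapped)
        assert fwd.direction and not rev.direction
        assert fwd.pval == pytest.approx(rev.pval)


class TestLeaveOneOut:
    def test_homogeneous_loo_equals_full(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.4], 0.01, [0.05, 0.1, 0.2], 0.1)
        loo = leave_one_out(h)
        assert len(loo) == 3
        assert np.allclose(loo.beta, 0.5)
        assert not loo.outlier.any()

    def test_matches_naive_refit(self, make_harmonized):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.4, 12)
        by = 0.3 * bx + rng.normal(0, 0.05, 12)
        h = make_harmonized(bx, 0.01, by, 0.05)
        loo = leave_one_out(h)
        for i in range(12):
            rest = make_harmonized(np.delete(bx, i), 0.01, np.delete(by, i), 0.05)
            ref = ivw(rest)
            assert loo.beta.iloc[i] == pytest.approx(ref.beta)
            assert loo.se.iloc[i] == pytest.approx(ref.se)

    def test_gross_outlier_moves_estimate_most_when_dropped(self, make_harmonized):
        bx = np.array([0.2, 0.2, 0.2, 0.2])  # equal weights
        by = np.array([0.1, 0.11, 0.09, 0.5])  # last SNP wildly off
        h = make_harmonized(bx, 0.01, by, 0.05)
        loo = leave_one_out(h)
        full = ivw(h).beta
        shifts = np.abs(loo.beta - full)
        assert loo.snp_id.iloc[int(np.argmax(shifts))] == h.table.snp_id.iloc[3]


class TestEstimateContracts:
    def test_or_columns_are_exp_of_beta(self, make_harmonized):
        rng = np.random.default_rng(3)
        h = make_harmonized(rng.uniform(0.1, 0.4, 8), 0.01,
                            rng.normal(0.1, 0.1, 8), 0.05)
        for e in mr_all(h, n_boot=50, seed=1):
            assert e.or_ == pytest.approx(np.exp(e.beta), rel=1e-9)
            assert e.or_lci95 == pytest.approx(np.exp(e.beta - Z95 * e.se), rel=1e-9)
            assert e.or_uci95 == pytest.approx(np.exp(e.beta + Z95 * e.se), rel=1e-9)
            assert e.or_lci95 < e.or_ < e.or_uci95

    def test_normal_pvalue_definition(self):
        e = MREstimate.from_normal("ivw", 5, 0.2, 0.1)
        assert e.pval == pytest.approx(2 * (1 - stats.norm.cdf(2.0)))

    def test_estimates_frame_layout(self, make_harmonized):
        h = make_harmonized([0.1, 0.2, 0.3, 0.25], 0.01,
                            [0.05, 0.1, 0.15, 0.12], 0.1)
        frame = estimates_frame(mr_all(h, n_boot=20, seed=0))
        assert list(frame.columns) == [
            "method", "nsnp", "pval", "Beta", "or", "or_lci95", "or_uci95"
        ]
        assert "Inverse variance weighted" in set(frame.method)
        assert "MR Egger" in set(frame.method)
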