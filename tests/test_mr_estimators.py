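"""Estimator correctness against independent oracles and invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_hset

from mrmediation.errors import InsufficientInstrumentsError
from mrmediation.instruments import harmonize
from mrmediation.mr_estimators import (
    all_methods,
    cochran_q,
    egger,
    format_or_ci,
    ivw,
    mode_estimate,
    to_or,
    wald_ratios,
    weighted_median,
)
from mrmediation.synthetic_gwas import SimConfig, simulate_with_truth


class TestWaldRatios:
    def test_arithmetic(self):
        h = make_hset([0.25], [0.01], [0.05], [0.01])
        ratios, ses, _ = wald_ratios(h)
        assert ratios[0] == pytest.approx(0.2)
        assert ses[0] == pytest.approx(0.04)

    def test_zero_outcome_effect(self):
        h = make_hset([0.25], [0.01], [0.0], [0.01])
        ratios, _, _ = wald_ratios(h)
        assert ratios[0] == 0.0

    def test_zero_exposure_effect_excluded_with_warning(self):
        h = make_hset([0.25, 0.0], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
        with pytest.warns(UserWarning, match="beta_exp == 0"):
            ratios, _, rsids = wald_ratios(h)
        assert len(ratios) == 1 and rsids == ["rs000"]

    def test_mean_ratio_recovers_true_effect(self):
        rng = np.random.default_rng(0)
        n, true = 20, 0.3
        bx = rng.normal(0.2, 0.03, n)
        seo = np.full(n, 0.01)
        by = true * bx + rng.normal(0, seo)
        h = make_hset(bx, np.full(n, 0.005), by, seo)
        ratios, ses, _ = wald_ratios(h)
        assert abs(ratios.mean() - true) < 2 * ses.mean() / np.sqrt(n)


class TestIVW:
    def test_single_instrument_collapse_exact(self):
        h = make_hset([0.25], [0.01], [0.05], [0.013])
        e = ivw(h)
        assert e.beta == 0.05 / 0.25
        assert e.se == 0.013 / 0.25
        assert e.n_snps == 1

    def test_matches_wls_oracle(self, hset_five):
        """Beta equals an independent weighted-least-squares solve."""
        t = hset_five.table
        x = t["beta_exp"].to_numpy()
        y = t["beta_out"].to_numpy()
        w = t["se_out"].to_numpy() ** -2.0
        # regression through the origin, solved via lstsq on scaled data
        sw = np.sqrt(w)
        beta_oracle = np.linalg.lstsq(
            (sw * x)[:, None], sw * y, rcond=None
        )[0][0]
        e = ivw(hset_five, model="fixed")
        assert e.beta == pytest.approx(beta_oracle, rel=1e-10)
        assert e.se == pytest.approx(np.sum(w * x**2) ** -0.5, rel=1e-10)

    def test_random_effects_never_deflates_se(self, hset_five):
        assert ivw(hset_five).se >= ivw(hset_five, model="fixed").se

    def test_homogeneous_fixture_equal_models(self):
        h = make_hset([0.2, 0.4], [0.01, 0.01], [0.06, 0.12], [0.01, 0.01])
        assert ivw(h).beta == pytest.approx(0.3)
        # Q < df here, so the multiplicative factor clamps at 1
        assert ivw(h).se == ivw(h, model="fixed").se


class TestEgger:
    def test_matches_normal_equations_oracle(self):
        h = make_hset(
            [0.20, 0.15, 0.30, 0.25], [0.02] * 4,
            [0.07, 0.05, 0.11, 0.08], [0.010, 0.015, 0.020, 0.012],
        )
        t = h.table
        x = t["beta_exp"].to_numpy()
        y = t["beta_out"].to_numpy()
        w = t["se_out"].to_numpy() ** -2.0
        X = np.column_stack([np.ones_like(x), x])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * y))
        e = egger(h)
        assert e.egger_intercept == pytest.approx(coef[0], rel=1e-10)
        assert e.beta == pytest.approx(coef[1], rel=1e-10)

    def test_orientation_invariance(self):
        """Flipping an instrument's allele coding leaves Egger unchanged."""
        h1 = make_hset([0.2, 0.3, 0.25], [0.02] * 3,
                       [0.07, 0.10, 0.08], [0.01] * 3)
        h2 = make_hset([-0.2, 0.3, 0.25], [0.02] * 3,
                       [-0.07, 0.10, 0.08], [0.01] * 3)
        e1, e2 = egger(h1), egger(h2)
        assert e1.beta == pytest.approx(e2.beta)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept)

    def test_minimum_three_instruments(self):
        h = make_hset([0.2, 0.3], [0.02] * 2, [0.06, 0.09], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError, match="3"):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_is_ordinary_median(self):
        h = make_hset([1.0, 1.0, 1.0], [0.1] * 3, [1.0, 2.0, 9.0], [1.0] * 3)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(2.0)

    def test_dominant_weight_returns_that_ratio(self):
        # middle ratio carries 90% of the inverse-variance weight
        se = np.array([3.0, 1.0, 3.0]) / np.sqrt(18)  # weights 0.05, 0.9, 0.05
        h = make_hset([1.0] * 3, [0.1] * 3, [1.0, 2.5, 9.0], se)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(2.5)

    def test_robust_to_half_invalid_instruments(self):
        """With 50% pleiotropic instruments the median beats IVW (majority
        of weight valid)."""
        rng = np.random.default_rng(7)
        true, wins, reps = 0.3, 0, 100
        for rep in range(reps):
            n = 20
            bx = rng.normal(0.1, 0.02, n)
            seo = np.full(n, 0.01)
            offsets = np.zeros(n)
            offsets[: n // 2] = rng.normal(0.02, 0.005, n // 2)
            by = true * bx + offsets + rng.normal(0, seo)
            h = make_hset(bx, np.full(n, 0.005), by, seo)
            wm = weighted_median(h, n_boot=5, seed=rep).beta
            iv = ivw(h).beta
            wins += abs(wm - true) < abs(iv - true)
        # offsets bias IVW upward; the median should win well over half
        assert wins > reps / 2


class TestModes:
    def test_point_mass_returns_common_ratio(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3,
                      [0.05, 0.10, 0.20], [0.01, 0.02, 0.03])
        for weighted in (False, True):
            e = mode_estimate(h, weighted=weighted, n_boot=5, seed=0)
            assert e.beta == pytest.approx(0.5)

    def test_mode_ignores_outlier_grid_oracle(self):
        """KDE mode of {0.3, 0.3, 0.3, 5.0} sits at 0.3; verified against
        an independently computed density grid."""
        h = make_hset([1.0] * 4, [0.1] * 4, [0.3, 0.3, 0.3, 5.0], [0.5] * 4)
        e = mode_estimate(h, weighted=False, n_boot=5, seed=0)

        ratios = np.array([0.3, 0.3, 0.3, 5.0])
        sd = np.std(ratios, ddof=1)
        mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
        disp = min(d for d in (sd, mad) if d > 0)
        bw = 0.9 * disp * 4 ** (-1 / 5)
        grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 512)
        dens = sps.norm.pdf((grid[:, None] - ratios[None, :]) / bw).sum(axis=1)
        assert e.beta == pytest.approx(grid[np.argmax(dens)])
        assert abs(e.beta - 0.3) < 0.1

    def test_simple_and_weighted_recover_truth(self):
        rng = np.random.default_rng(1)
        true, n = 0.4, 30
        bx = rng.normal(0.15, 0.02, n)
        seo = np.full(n, 0.008)
        by = true * bx + rng.normal(0, seo)
        h = make_hset(bx, np.full(n, 0.004), by, seo)
        for weighted in (False, True):
            e = mode_estimate(h, weighted=weighted, n_boot=20, seed=2)
            assert abs(e.beta - true) < 3 * e.se


class TestCochranQ:
    def test_homogeneous_q_zero(self):
        h = make_hset([0.2, 0.4, 0.1], [0.01] * 3,
                      [0.06, 0.12, 0.03], [0.01] * 3)
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        # ratios 0.2 and 0.4, wald ses 0.1 and 0.2 -> weights 100, 25
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.2, 0.4], [0.1, 0.2])
        q, df, p = cochran_q(h)
        beta = (100 * 0.2 + 25 * 0.4) / 125
        expect = 100 * (0.2 - beta) ** 2 + 25 * (0.4 - beta) ** 2
        assert q == pytest.approx(expect, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(expect, 1), rel=1e-12)

    def test_null_q_mean_matches_chi2_df(self):
        """Under homogeneity, E[Q] = n-1."""
        rng = np.random.default_rng(5)
        n, reps = 10, 1000
        qs = []
        for _ in range(reps):
            bx = np.full(n, 0.2)
            seo = np.full(n, 0.01)
            by = 0.3 * bx + rng.normal(0, seo)
            h = make_hset(bx, np.full(n, 1e-6), by, seo)
            qs.append(cochran_q(h)[0])
        mc_se = np.std(qs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(qs) - (n - 1)) < 3 * mc_se


class TestOddsRatioReporting:
    @pytest.mark.parametrize(
        "ci_low, ci_high, printed_or",
        [
            (0.031, 0.614, 0.138),   # protective plasma-protein exposure
            (1.114, 2.117, 1.536),   # monocyte-surface mediator phenotype
        ],
    )
    def test_published_style_or_ci_reconstruction(self, ci_low, ci_high, printed_or):
        """Reconstructing (beta, se) from a printed 95% CI and re-applying
        the OR transform reproduces the printed point estimate."""
        beta = np.log(np.sqrt(ci_low * ci_high))
        se = (np.log(ci_high) - np.log(ci_low)) / (2 * 1.96)
        or_, lo, hi = to_or(beta, se)
        assert round(or_, 3) == printed_or
        assert round(lo, 3) == ci_low
        assert round(hi, 3) == ci_high

    def test_null_beta_symmetric_ci(self):
        or_, lo, hi = to_or(0.0, 0.3)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    @given(
        beta=st.floats(-3, 3, allow_nan=False),
        se=st.floats(1e-3, 2, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_or_ci_coherence(self, beta, se):
        """sqrt(ci_low * ci_high) == OR and ci_low < OR < ci_high, always."""
        or_, lo, hi = to_or(beta, se)
        assert np.sqrt(lo * hi) == pytest.approx(or_, rel=1e-9)
        assert lo < or_ < hi

    def test_format(self):
        assert format_or_ci(0.138, 0.031, 0.614) == "0.138(0.031-0.614)"


class TestEstimatorInvariants:
    @pytest.fixture
    def hset20(self):
        rng = np.random.default_rng(12)
        n = 20
        bx = rng.normal(0.15, 0.04, n)
        by = 0.25 * bx + rng.normal(0, 0.01, n)
        return make_hset(bx, np.full(n, 0.006), by, np.full(n, 0.01))

    def test_permutation_invariance(self, hset20):
        from mrmediation.instruments import HarmonizedSet

        shuffled = HarmonizedSet(
            hset20.exposure_id, hset20.outcome_id,
            hset20.table.sample(frac=1, random_state=3).reset_index(drop=True),
        )
        for a, b in zip(all_methods(hset20, n_boot=50, seed=9),
                        all_methods(shuffled, n_boot=50, seed=9)):
            assert a.beta == pytest.approx(b.beta, rel=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_scale_equivariance(self, hset20):
        """Multiplying all exposure effects by c divides every estimate by c."""
        from mrmediation.instruments import HarmonizedSet

        c = 2.5
        t = hset20.table.copy()
        t["beta_exp"] *= c
        t["se_exp"] *= c
        scaled = HarmonizedSet("e", "o", t)
        for a, b in zip(all_methods(hset20, n_boot=20, seed=4),
                        all_methods(scaled, n_boot=20, seed=4)):
            assert b.beta == pytest.approx(a.beta / c, rel=1e-9)

    def test_all_five_recover_true_effect_without_pleiotropy(self):
        """Parameter recovery: each estimator's mean over replicates lies
        within 2 Monte Carlo SEs of the simulated truth."""
        base = SimConfig(
            m_snps=30, h2_x=0.2, theta_xd=0.5,
            n_cases=5000, n_controls=100_000,
            m_snps_mediator=0, h2_m=0.0,
        )
        reps = 200
        betas = {m: [] for m in
                 ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")}
        for seed in range(reps):
            x, _, d, tr = simulate_with_truth(dataclasses.replace(base, seed=seed))
            h = harmonize(x, d, tr.exposure_block)
            for e in all_methods(h, n_boot=2, seed=seed):
                betas[e.method].append(e.beta)
        for method, vals in betas.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - base.theta_xd) < 2 * mc_se, method
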