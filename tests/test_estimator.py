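"""Design construction, dummy-observation priors, and the Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest

import bpvar as bv
from bpvar.estimator import lag_block


def stacked_truth(truth: bv.SimulationTruth) -> np.ndarray:
    """Stack (A_j, alpha_i, beta_i) into the K × M layout of the design."""
    m = truth.n_vars
    blocks = [a.T for a in truth.lag_coefficients]
    return np.vstack(blocks + [truth.fixed_effects, truth.trend_slopes])


class TestBuildDesign:
    def test_shapes_two_countries_three_years(self):
        frame = pd.DataFrame({
            "country": ["A"] * 3 + ["B"] * 3, "year": [0, 1, 2] * 2,
            "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        design = bv.build_design(bv.PanelDataset(frame, ["y"]), bv.VARSpec(("y",), 1))
        assert design.Y.shape == (4, 1)
        assert design.X.shape == (4, 5)  # 1 lag + 2 dummies + 2 trends
        assert design.K == 5 and design.ex == 4

    def test_zero_noise_panel_satisfies_exact_identity(self):
        rng = np.random.default_rng(3)
        coefs = bv.random_stable_var(2, 1, 0.7, seed=rng)
        truth = bv.SimulationTruth(
            3, 8, 2, 1, coefs, 1e-30 * np.eye(2),
            rng.normal(size=(3, 2)), rng.normal(scale=0.05, size=(3, 2)), seed=4,
        )
        panel = bv.simulate_panel(truth)
        design = bv.build_design(panel, bv.VARSpec(tuple(panel.variable_order), 1))
        resid = design.Y - design.X @ stacked_truth(truth)
        assert np.abs(resid).max() < 1e-8

    def test_lags_never_cross_country_boundaries(self):
        frame = pd.DataFrame({
            "country": ["A"] * 4 + ["B"] * 4, "year": list(range(4)) * 2,
            "y": [1e6, 2e6, 3e6, 4e6, 1.0, 2.0, 3.0, 4.0],
        })
        design = bv.build_design(bv.PanelDataset(frame, ["y"]), bv.VARSpec(("y",), 2))
        b_rows = design.X[design.X[:, design.column_map["fe:B"]] == 1.0]
        assert set(b_rows[:, 0]) <= {1.0, 2.0, 3.0}  # B's own lags only
        assert b_rows[:, :2].max() < 1e5

    def test_unbalanced_panel_rejected(self, toy_frame):
        panel = bv.PanelDataset(toy_frame.iloc[:-1], ["x", "z"])
        with pytest.raises(ValueError, match="balanced"):
            bv.build_design(panel, bv.VARSpec(("x", "z"), 1))

    def test_too_many_lags_rejected(self, toy_frame):
        panel = bv.PanelDataset(toy_frame, ["x", "z"])
        with pytest.raises(ValueError, match="T > P"):
            bv.build_design(panel, bv.VARSpec(("x", "z"), 3))


class TestScalesAndMeans:
    def test_white_noise_scale_near_unity(self):
        rng = np.random.default_rng(5)
        n, t = 20, 200
        frame = pd.DataFrame({
            "country": np.repeat([f"C{i}" for i in range(n)], t),
            "year": np.tile(np.arange(t), n),
            "w": rng.standard_normal(n * t),
        })
        panel = bv.PanelDataset(frame, ["w"])
        sigma = bv.estimate_scales(panel, bv.VARSpec(("w",), 1))
        assert sigma[0] == pytest.approx(1.0, rel=0.05)

    def test_scale_linearity(self, small_panel, small_spec):
        sigma = bv.estimate_scales(small_panel, small_spec)
        scaled = small_panel.copy_with(
            small_panel.frame.assign(**{small_panel.variable_order[0]:
                                        10 * small_panel.frame[small_panel.variable_order[0]]})
        )
        sigma10 = bv.estimate_scales(scaled, small_spec)
        assert sigma10[0] == pytest.approx(10 * sigma[0], rel=1e-8)
        np.testing.assert_allclose(sigma10[1:], sigma[1:], rtol=1e-8)

    def test_constant_variable_rejected(self):
        frame = pd.DataFrame({
            "country": ["A"] * 5 + ["B"] * 5, "year": list(range(5)) * 2,
            "k": [3.0] * 5 + [7.0] * 5,
        })
        panel = bv.PanelDataset(frame, ["k"])
        with pytest.raises(ValueError, match="zero lag variance"):
            bv.estimate_scales(panel, bv.VARSpec(("k",), 1))

    def test_presample_mean_two_country_average(self):
        frame = pd.DataFrame({
            "country": ["A"] * 3 + ["B"] * 3, "year": list(range(3)) * 2,
            "y": [2.0, 9.0, 9.0, 4.0, 9.0, 9.0],
        })
        panel = bv.PanelDataset(frame, ["y"])
        mu = bv.presample_means(panel, bv.VARSpec(("y",), 1))
        assert mu[0] == pytest.approx(3.0)

    def test_presample_mean_country_order_invariant(self, small_panel, small_spec):
        mu = bv.presample_means(small_panel, small_spec)
        relabelled = small_panel.frame.assign(
            country=small_panel.frame["country"].map(
                lambda c: f"Z{9 - int(c[1:]):03d}"  # reverses sort order
            )
        )
        mu2 = bv.presample_means(bv.PanelDataset(relabelled, small_panel.variable_order), small_spec)
        np.testing.assert_allclose(mu2, mu, rtol=1e-12)


class TestBuildDummies:
    @pytest.fixture()
    def hyper2(self):
        return bv.PriorHyperparams(
            gamma=1.0, tau=1.0, c=0.001, lam=10.0,
            sigma=np.array([2.0, 3.0]), mu=np.array([0.5, -1.0]),
        )

    def test_row_count_bivariate_var1(self, hyper2):
        spec = bv.VARSpec(("a", "b"), 1)
        dum = bv.build_dummies(spec, hyper2, n_countries=4)
        assert dum.TD == 7  # 2 coef + 2 cov + 1 exog + 2 sum-of-coefs
        assert dum.XD.shape == (7, 2 + 8)

    def test_block_contents(self, hyper2):
        spec = bv.VARSpec(("a", "b"), 1)
        dum = bv.build_dummies(spec, hyper2, n_countries=1)
        # coefficient prior: own first lag centred on gamma, scaled by sigma/tau
        np.testing.assert_allclose(dum.YD[0], [2.0, 0.0])
        np.testing.assert_allclose(dum.XD[0, :2], [2.0, 0.0])
        np.testing.assert_allclose(dum.YD[1], [0.0, 3.0])
        # covariance prior: YD = diag(sigma), XD = 0
        np.testing.assert_allclose(dum.YD[2:4], np.diag([2.0, 3.0]))
        assert np.all(dum.XD[2:4] == 0)
        # exogenous prior: single row, c on the two deterministic columns
        np.testing.assert_allclose(dum.XD[4], [0, 0, 0.001, 0.001])
        assert np.all(dum.YD[4] == 0)
        # sum-of-coefficients: diag(gamma*mu)/lam on YD and every lag block of XD
        np.testing.assert_allclose(dum.YD[5:], np.diag([0.05, -0.1]))
        np.testing.assert_allclose(dum.XD[5:, :2], np.diag([0.05, -0.1]))
        assert np.all(dum.XD[5:, 2:] == 0)
        assert dum.block_labels == ["coef_prior"] * 2 + ["cov_prior"] * 2 + ["exog_prior"] + ["sum_of_coefs"] * 2

    def test_lag_decay_is_linear_in_lag_index(self, hyper2):
        spec = bv.VARSpec(("a", "b"), 3)
        dum = bv.build_dummies(spec, hyper2, n_countries=2)
        assert dum.TD == 2 * 3 + 2 + 1 + 2
        # lag-2 row of variable a carries 2*sigma_a/tau in the lag-2 column
        assert dum.XD[2, 2] == pytest.approx(2 * 2.0)
        assert dum.XD[4, 4] == pytest.approx(3 * 2.0)
        # sum-of-coefficients rows replicate across all three lag blocks
        np.testing.assert_allclose(dum.XD[-2, [0, 2, 4]], 0.05)

    def test_doubling_lambda_halves_sum_rows(self, hyper2):
        spec = bv.VARSpec(("a", "b"), 1)
        loose = bv.PriorHyperparams(1.0, 1.0, 0.001, 20.0, hyper2.sigma, hyper2.mu)
        d1, d2 = (bv.build_dummies(spec, h, 3) for h in (hyper2, loose))
        np.testing.assert_allclose(d2.YD[5:], d1.YD[5:] / 2)
        np.testing.assert_allclose(d2.XD[5:], d1.XD[5:] / 2)

    def test_stacking(self, small_design, small_spec, hyper2):
        hyper = bv.PriorHyperparams(1.0, 1.0, 0.001, 10.0, np.ones(3), np.zeros(3))
        dum = bv.build_dummies(small_spec, hyper, small_design.n_countries)
        y_star, x_star = bv.stack_with_dummies(small_design, dum)
        assert y_star.shape[0] == small_design.n_obs + dum.TD
        assert x_star.shape == (small_design.n_obs + dum.TD, small_design.K)
        empty = bv.DummyObservations.empty(3, small_design.K)
        y0, x0 = bv.stack_with_dummies(small_design, empty)
        assert y0 is small_design.Y and x0 is small_design.X

    def test_stacking_mismatch_rejected(self, small_design):
        bad = bv.DummyObservations(np.zeros((2, 3)), np.zeros((2, 4)), ["coef_prior"] * 2)
        with pytest.raises(ValueError, match="columns"):
            bv.stack_with_dummies(small_design, bad)


class TestPosteriorLocation:
    def test_scalar_normal_equations(self):
        b = bv.posterior_location(np.array([[1.0], [3.0]]), np.array([[1.0], [1.0]]))
        assert b[0, 0] == pytest.approx(2.0)

    def test_flat_prior_equals_equationwise_ols(self, small_design):
        b_star = bv.posterior_location(small_design.Y, small_design.X)
        for eq in range(small_design.Y.shape[1]):
            ols, *_ = np.linalg.lstsq(small_design.X, small_design.Y[:, eq], rcond=None)
            np.testing.assert_allclose(b_star[:, eq], ols, atol=1e-10)

    def test_noiseless_interpolation(self, small_design):
        rng = np.random.default_rng(0)
        b_true = rng.normal(size=(small_design.K, 3))
        y = small_design.X @ b_true
        np.testing.assert_allclose(bv.posterior_location(y, small_design.X), b_true, atol=1e-8)

    def test_rank_deficiency_diagnosed(self):
        x = np.ones((6, 2))  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            bv.posterior_location(np.arange(6.0)[:, None], x)

    def test_country_relabelling_leaves_lag_block_unchanged(self, small_panel, small_spec, small_design):
        b_ref = bv.posterior_location(small_design.Y, small_design.X)
        relabelled = small_panel.frame.assign(
            country=small_panel.frame["country"].map(lambda c: f"Z{9 - int(c[1:]):03d}")
        )
        design2 = bv.build_design(bv.PanelDataset(relabelled, small_panel.variable_order), small_spec)
        b_perm = bv.posterior_location(design2.Y, design2.X)
        np.testing.assert_allclose(b_perm[:3], b_ref[:3], atol=1e-9)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(17)
    x = np.column_stack([np.ones(40), rng.normal(size=40)])
    b_true = np.array([[1.0, -0.5], [0.3, 0.8]])
    y = x @ b_true + rng.normal(scale=0.5, size=(40, 2))
    return y, x


class TestConditionalDraws:
    def test_zero_covariance_limit_returns_location(self, toy):
        y, x = toy
        b_star = bv.posterior_location(y, x)
        draw = bv.draw_coefficients(1e-30 * np.eye(2), y, x, np.random.default_rng(0))
        np.testing.assert_allclose(draw, b_star, atol=1e-10)

    def test_coefficient_draw_moments(self, toy):
        y, x = toy
        omega = np.array([[0.5, 0.2], [0.2, 0.4]])
        b_star = bv.posterior_location(y, x)
        rng = np.random.default_rng(1)
        draws = np.array([bv.draw_coefficients(omega, y, x, rng) for _ in range(8000)])
        gram_inv = np.linalg.inv(x.T @ x)
        target_cov = np.kron(omega, gram_inv)
        sd = np.sqrt(np.diag(target_cov)).reshape(2, 2, order="F")
        assert np.all(np.abs(draws.mean(axis=0) - b_star) < 4 * sd / np.sqrt(8000))
        vecs = draws.transpose(0, 2, 1).reshape(8000, -1)  # vec(B) per draw
        emp_cov = np.cov(vecs.T)
        scale = np.sqrt(np.outer(np.diag(target_cov), np.diag(target_cov)))
        assert np.abs((emp_cov - target_cov) / scale).max() < 0.1

    def test_covariance_draws_spd_and_unbiased(self, toy):
        y, x = toy
        b = bv.posterior_location(y, x)
        rng = np.random.default_rng(2)
        draws = np.array([bv.draw_covariance(b, y, x, 0, rng) for _ in range(6000)])
        for d in draws[:50]:
            assert np.linalg.eigvalsh(d).min() > 0
        resid = y - x @ b
        s_star = resid.T @ resid
        dof = 40 - 2
        target = s_star / (dof - 2 - 1)
        assert np.abs(draws.mean(axis=0) / target - 1).max() < 0.05

    def test_zero_residuals_rejected(self, toy):
        _, x = toy
        b = np.ones((2, 2))
        y_exact = x @ b
        with pytest.raises(ValueError, match="S\\*"):
            bv.draw_covariance(b, y_exact, x, 0, np.random.default_rng(0))

    def test_insufficient_dof_rejected(self):
        x = np.eye(3)
        y = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError, match="dof"):
            bv.draw_covariance(np.zeros((3, 3)), y, x, 0, np.random.default_rng(0))


class TestRunGibbs:
    def test_schedule_arithmetic(self):
        cfg = bv.GibbsConfig(n_total=55_000, n_burn=45_000, thin=1, seed=0)
        assert cfg.n_retained == 10_000
        with pytest.raises(ValueError):
            bv.GibbsConfig(n_total=100, n_burn=100)

    def test_reproducible_and_correct_counts(self, small_design, small_spec):
        hyper = bv.PriorHyperparams(1.0, 1.0, 0.001, 10.0, np.ones(3), np.zeros(3))
        dum = bv.build_dummies(small_spec, hyper, small_design.n_countries)
        cfg = bv.GibbsConfig(n_total=300, n_burn=100, thin=2, seed=12)
        a = bv.run_gibbs(small_design, dum, cfg, spec=small_spec)
        b = bv.run_gibbs(small_design, dum, cfg, spec=small_spec)
        assert a.n_retained == 100
        np.testing.assert_array_equal(a.B_draws, b.B_draws)
        np.testing.assert_array_equal(a.Omega_draws, b.Omega_draws)
        for omega in a.Omega_draws[::10]:
            assert np.linalg.eigvalsh(omega).min() > 0

    def test_posterior_draws_roundtrip(self, small_design, small_spec, tmp_path):
        dum = bv.DummyObservations.empty(3, small_design.K)
        cfg = bv.GibbsConfig(n_total=120, n_burn=20, seed=1)
        draws = bv.run_gibbs(small_design, dum, cfg, spec=small_spec)
        draws.save(tmp_path / "draws")
        back = bv.PosteriorDraws.load(tmp_path / "draws")
        np.testing.assert_array_equal(back.B_draws, draws.B_draws)
        assert back.spec == small_spec
        assert back.config == cfg

    def test_tight_prior_pins_first_own_lags(self, small_panel, small_spec, small_design):
        sigma = bv.estimate_scales(small_panel, small_spec)
        mu = bv.presample_means(small_panel, small_spec)
        hyper = bv.PriorHyperparams(1.0, 1e-6, 0.001, 10.0, sigma, mu)
        dum = bv.build_dummies(small_spec, hyper, small_design.n_countries)
        y_star, x_star = bv.stack_with_dummies(small_design, dum)
        b_star = bv.posterior_location(y_star, x_star)
        own = np.diag(b_star[:3, :])
        np.testing.assert_allclose(own, 1.0, atol=1e-6)
        off = b_star[:3, :][~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-6

    def test_lag_block_extraction_orientation(self):
        b = np.arange(12.0).reshape(4, 3)  # K=4 (1 lag of 3 vars + 1 exog), M=3
        (a1,) = lag_block(b, 3, 1)
        assert a1.shape == (3, 3)
        assert a1[2, 0] == b[0, 2]  # equation 2, lagged variable 0
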