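"""Bayesian mixed model: sampler correctness, Rhat, WAIC, Bayes R2."""

import math

import numpy as np
import pandas as pd
import pytest

from mandmorph import blmm
from mandmorph.blmm import (
    ModelSpec,
    PosteriorDraws,
    compare,
    fit,
    marginal_effect,
    split_rhat,
    standardize,
    summarize,
    waic,
)


def _simple_data(n=80, beta=(0.5, -0.3), sigma=0.4, groups=None, seed=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    y = X @ np.array(beta) + rng.normal(0, sigma, n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    if groups is not None:
        g = np.repeat(np.arange(groups), n // groups)
        u = rng.normal(0, 0.3, groups)
        y = y + u[g]
        df["population"] = [f"g{i}" for i in g]
    df["y"] = y
    return df


def _manual_draws(pointwise):
    """Minimal PosteriorDraws carrying only a pointwise log-likelihood."""
    S, n = pointwise.shape
    return PosteriorDraws(
        fixed=np.zeros((S, 1, 1)),
        intercepts=np.zeros((S, 1)),
        group_levels=None,
        group_scale=None,
        residual_scale=np.ones((S, 1)),
        pointwise_loglik=pointwise,
        chain_index=np.zeros(S, dtype=int),
        response_names=["y"],
        predictor_names=["x"],
        group_labels=None,
        X=np.zeros((n, 1)),
        Y=np.zeros((n, 1)),
        group_codes=None,
        scaling=None,
        spec=ModelSpec(responses=["y"], fixed_effects=["x"], iterations=2, burn_in=1),
    )


class TestStandardize:
    def test_zscore_properties(self):
        df = _simple_data()
        out, record = standardize(df, ["y", "x0", "x1"])
        for col in ("y", "x0", "x1"):
            assert abs(out[col].mean()) < 1e-12
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_inverse_recovers_originals(self):
        df = _simple_data()
        out, record = standardize(df, ["y", "x0"])
        back = record.inverse(out[["y", "x0"]])
        np.testing.assert_allclose(back["y"], df["y"], atol=1e-12)

    def test_captivity_codes_hand_formula(self):
        codes = np.array([0] * 84 + [1] * 39 + [2] * 54)
        df = pd.DataFrame({"captivity": codes})
        out, _ = standardize(df, ["captivity"])
        mu = codes.mean()
        sd = codes.std(ddof=1)
        np.testing.assert_allclose(out["captivity"], (codes - mu) / sd, atol=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            standardize(df, ["a", "b"])


class TestSamplerConjugate:
    def test_posterior_matches_closed_form(self):
        """Known sigma, no random effect, flat prior: the posterior is
        exactly N(beta_hat, sigma^2 (W'W)^-1); the Gibbs draws are then iid,
        so Monte-Carlo error is sd/sqrt(S)."""
        sigma = 0.4
        df = _simple_data(n=120, sigma=sigma, seed=3)
        spec = ModelSpec(
            responses=["y"],
            fixed_effects=["x0", "x1"],
            random_group=None,
            standardize=False,
            sigma_fixed=sigma,
            chains=4,
            iterations=1500,
            burn_in=500,
            seed=11,
        )
        draws = fit(df, spec)
        W = np.column_stack([np.ones(len(df)), df[["x0", "x1"]].to_numpy()])
        WtWinv = np.linalg.inv(W.T @ W)
        bhat = WtWinv @ W.T @ df["y"].to_numpy()
        sd_exact = sigma * np.sqrt(np.diag(WtWinv))
        S = draws.n_draws
        means = np.concatenate([[draws.intercepts.mean()], draws.fixed[:, 0, :].mean(axis=0)])
        sds = np.concatenate(
            [[draws.intercepts.std(ddof=1)], draws.fixed[:, 0, :].std(ddof=1, axis=0)]
        )
        for j in range(3):
            mcse = sd_exact[j] / math.sqrt(S)
            assert abs(means[j] - bhat[j]) < 3 * mcse
            assert sds[j] == pytest.approx(sd_exact[j], rel=0.05)

    def test_duplicated_response_exchangeable(self):
        df = _simple_data(n=60, groups=4, seed=9)
        df["y2"] = df["y"]
        spec = ModelSpec(
            responses=["y", "y2"],
            fixed_effects=["x0", "x1"],
            chains=2,
            iterations=800,
            burn_in=300,
            seed=1,
        )
        draws = fit(df, spec)
        m = draws.fixed.mean(axis=0)  # R x p
        sd = draws.fixed.std(axis=0)
        np.testing.assert_allclose(m[0], m[1], atol=3 * sd[0].max() / 10)

    def test_recovers_known_coefficients_with_groups(self):
        df = _simple_data(n=200, beta=(0.8, 0.0), sigma=0.3, groups=8, seed=21)
        spec = ModelSpec(
            responses=["y"],
            fixed_effects=["x0", "x1"],
            chains=2,
            iterations=1200,
            burn_in=400,
            seed=2,
        )
        draws = fit(df, spec)
        summ = summarize(draws)
        row = summ.table[summ.table.parameter == "x0"].iloc[0]
        # standardized scale: true value scaled by sd(x)/sd(y)
        scale = df["x0"].std(ddof=1) / df["y"].std(ddof=1)
        assert row.lower < 0.8 * scale < row.upper
        row1 = summ.table[summ.table.parameter == "x1"].iloc[0]
        assert row1.lower < 0.0 < row1.upper


class TestRhat:
    def test_identical_distribution_near_one(self, rng):
        chains = rng.standard_normal((4, 2000))
        assert abs(split_rhat(chains) - 1.0) < 0.05

    def test_separated_chains_flagged(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert split_rhat(chains) > 1.1

    def test_matches_textbook_formula(self, rng):
        chains = rng.standard_normal((3, 40)) + np.array([[0.0], [0.2], [-0.1]])
        # independent split-Rhat computation
        half = 20
        splits = np.vstack([chains[:, :half], chains[:, half:]])
        m, n = splits.shape
        means = splits.mean(axis=1)
        W = splits.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
        expected = np.sqrt(var_plus / W)
        assert split_rhat(chains) == pytest.approx(expected, rel=1e-12)

    def test_matches_arviz(self, rng):
        import arviz as az

        chains = rng.standard_normal((4, 100)) * [[1], [1.2], [0.9], [1.1]]
        ours = split_rhat(chains)
        theirs = float(
            az.rhat(az.convert_to_dataset(chains[:, :, None]), method="split")["x"][0]
        )
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_zero_variance_convention(self):
        assert split_rhat(np.ones((2, 100))) == 1.0


class TestWAIC:
    def test_degenerate_posterior(self):
        ll = np.tile(np.array([-1.2, -0.7, -2.0]), (50, 1))
        total, se, table = waic(_manual_draws(ll))
        assert np.allclose(table["p_waic"], 0.0)
        assert total == pytest.approx(-2 * ll[0].sum())

    def test_matches_brute_force(self, rng):
        ll = rng.normal(-1.0, 0.3, size=(200, 17))
        total, se, _ = waic(_manual_draws(ll))
        # independent summation with explicit loops
        S, n = ll.shape
        pointwise = []
        for i in range(n):
            lppd_i = math.log(np.mean([math.exp(v) for v in ll[:, i]]))
            p_i = np.var(ll[:, i], ddof=1)
            pointwise.append(-2 * (lppd_i - p_i))
        assert total == pytest.approx(sum(pointwise), rel=1e-10)
        assert se == pytest.approx(
            math.sqrt(n) * np.std(pointwise, ddof=1), rel=1e-10
        )

    def test_nonfinite_rejected(self):
        ll = np.zeros((10, 4))
        ll[3, 2] = np.inf
        with pytest.raises(ValueError):
            waic(_manual_draws(ll))


class TestCompare:
    def test_model_against_itself(self, rng):
        ll = rng.normal(-1, 0.2, (100, 12))
        d = _manual_draws(ll)
        table = compare([("a", d), ("b", _manual_draws(ll.copy()))])
        other = table[table.model != table.iloc[0].model].iloc[0]
        assert other.d_waic == pytest.approx(0.0, abs=1e-12)
        assert other.d_se == pytest.approx(0.0, abs=1e-12)

    def test_paired_se_hand_computed(self, rng):
        ll_a = rng.normal(-1.0, 0.2, (50, 3))
        ll_b = rng.normal(-1.3, 0.2, (50, 3))
        da, db = _manual_draws(ll_a), _manual_draws(ll_b)
        table = compare([("a", da), ("b", db)])
        wa = waic(da)[2]["waic"].to_numpy()
        wb = waic(db)[2]["waic"].to_numpy()
        best_is_a = wa.sum() < wb.sum()
        diff = (wb - wa) if best_is_a else (wa - wb)
        expected_se = math.sqrt(3) * np.std(diff, ddof=1)
        worst = table.iloc[1]
        assert worst.d_waic == pytest.approx(abs(wb.sum() - wa.sum()), rel=1e-10)
        assert worst.d_se == pytest.approx(expected_se, rel=1e-10)

    def test_best_model_blank_and_first(self, rng):
        ll_a = rng.normal(-1.0, 0.2, (50, 5))
        ll_b = ll_a - 0.5  # uniformly worse
        table = compare([("worse", _manual_draws(ll_b)), ("better", _manual_draws(ll_a))])
        assert table.iloc[0].model == "better"
        assert np.isnan(table.iloc[0].d_waic)
        assert table.iloc[1].d_waic > 0

    def test_observation_mismatch(self, rng):
        with pytest.raises(ValueError, match="different observations"):
            compare(
                [
                    ("a", _manual_draws(rng.normal(size=(10, 5)))),
                    ("b", _manual_draws(rng.normal(size=(10, 6)))),
                ]
            )


class TestBayesR2:
    def test_near_noiseless_close_to_one(self):
        df = _simple_data(n=100, sigma=0.01, seed=13)
        spec = ModelSpec(
            responses=["y"], fixed_effects=["x0", "x1"], random_group=None,
            chains=2, iterations=600, burn_in=200, seed=3,
        )
        r2 = blmm.bayes_r2(fit(df, spec))
        assert r2["mean"] > 0.98

    def test_pure_noise_near_zero(self, rng):
        df = pd.DataFrame(
            {"y": rng.standard_normal(120), "x0": rng.standard_normal(120)}
        )
        spec = ModelSpec(
            responses=["y"], fixed_effects=["x0"], random_group=None,
            chains=2, iterations=600, burn_in=200, seed=4,
        )
        r2 = blmm.bayes_r2(fit(df, spec))
        assert r2["mean"] < 0.1

    def test_single_draw_hand_oracle(self):
        """One draw, one response, 4 observations: R2 from the stored
        parameters must equal the hand formula var(mu)/(var(mu)+sigma^2)."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        d = PosteriorDraws(
            fixed=np.array([[[0.5]]]),
            intercepts=np.array([[0.2]]),
            group_levels=None,
            group_scale=None,
            residual_scale=np.array([[0.3]]),
            pointwise_loglik=np.zeros((1, 4)),
            chain_index=np.zeros(1, dtype=int),
            response_names=["y"],
            predictor_names=["x"],
            group_labels=None,
            X=X,
            Y=np.zeros((4, 1)),
            group_codes=None,
            scaling=None,
            spec=ModelSpec(responses=["y"], fixed_effects=["x"], iterations=2, burn_in=1),
        )
        mu = 0.2 + 0.5 * X[:, 0]
        expected = mu.var() / (mu.var() + 0.3**2)
        assert blmm.bayes_r2(d)["mean"] == pytest.approx(expected, rel=1e-12)


class TestMarginalEffect:
    def test_profile_slope_matches_beta(self):
        df = _simple_data(n=150, beta=(0.6, 0.0), sigma=0.1, seed=17)
        spec = ModelSpec(
            responses=["y"], fixed_effects=["x0", "x1"], random_group=None,
            chains=2, iterations=800, burn_in=300, seed=5,
        )
        draws = fit(df, spec)
        prof = marginal_effect(draws, "x0", [0.0, 1.0])
        slope = prof.iloc[1]["mean"] - prof.iloc[0]["mean"]
        # standardized scale: slope per raw unit = beta_std * z-step
        z_step = 1.0 / draws.scaling.sd["x0"]
        beta_std = draws.fixed_draws("x0").mean()
        assert slope == pytest.approx(beta_std * z_step, abs=0.02)

    def test_matches_drawwise_oracle(self):
        df = _simple_data(n=60, groups=3, seed=23)
        spec = ModelSpec(
            responses=["y"], fixed_effects=["x0", "x1"],
            chains=2, iterations=500, burn_in=200, seed=6,
        )
        draws = fit(df, spec)
        prof = marginal_effect(draws, "x1", [0.5])
        z = draws.scaling.z("x1", 0.5)
        fitted = draws.intercepts[:, 0] + draws.fixed_draws("x1", "y") * z
        assert prof.iloc[0]["mean"] == pytest.approx(fitted.mean(), rel=1e-12)
        assert prof.iloc[0]["lower"] == pytest.approx(
            np.quantile(fitted, 0.025), rel=1e-9
        )

    def test_extrapolation_flagged(self):
        df = _simple_data(n=40, seed=29)
        spec = ModelSpec(
            responses=["y"], fixed_effects=["x0", "x1"], random_group=None,
            chains=2, iterations=300, burn_in=100, seed=7,
        )
        draws = fit(df, spec)
        prof = marginal_effect(draws, "x0", [99.0])
        assert bool(prof.iloc[0]["extrapolated"])


def test_fit_reproducible_with_fixed_seed():
    df = _simple_data(n=50, groups=5, seed=31)
    spec = ModelSpec(
        responses=["y"], fixed_effects=["x0", "x1"],
        chains=2, iterations=400, burn_in=100, seed=99,
    )
    d1, d2 = fit(df, spec), fit(df, spec)
    np.testing.assert_array_equal(d1.fixed, d2.fixed)
    np.testing.assert_array_equal(d1.pointwise_loglik, d2.pointwise_loglik)
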