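"""Sampler correctness, HDI, contrasts, DIC and posterior predictive checks."""

import math

import numpy as np
import pytest

import shootddm as S
from shootddm import inference
from shootddm.hierarchy import FAMILIES
from shootddm.inference import (PosteriorDraws, adaptive_mwg,
                                contrast, dic, hdi, marginal_contrast,
                                posterior_predictive, sample_posterior)


class TestHdi:
    def test_constant_sample_zero_width(self):
        lo, hi = hdi(np.full(100, 3.7))
        assert lo == hi == 3.7

    def test_standard_normal_endpoints(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = hdi(x, 0.95)
        assert abs(lo + 1.96) < 0.02 and abs(hi - 1.96) < 0.02

    def test_skewed_hdi_no_wider_than_equal_tail(self, rng):
        x = rng.gamma(2.0, 1.0, 200_000)
        lo, hi = hdi(x, 0.95)
        eq = np.quantile(x, [0.025, 0.975])
        assert (hi - lo) <= (eq[1] - eq[0])
        assert (hi - lo) == pytest.approx(eq[1] - eq[0], rel=0.5)

    def test_matches_arviz_on_unimodal_sample(self, rng):
        import arviz as az
        x = rng.normal(2.0, 0.7, 50_000)
        lo, hi = hdi(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hdi([], 0.95)
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], 1.5)


class TestGenericSampler:
    def test_conjugate_normal_matches_closed_form(self):
        """Normal likelihood, normal prior: posterior mean and variance of
        the sampled chain match the analytic conjugate posterior."""
        rng = np.random.default_rng(4)
        y = rng.normal(1.4, 1.0, 40)
        sigma2, mu0, tau02 = 1.0, 0.0, 4.0
        post_var = 1.0 / (len(y) / sigma2 + 1.0 / tau02)
        post_mean = post_var * (y.sum() / sigma2 + mu0 / tau02)

        def logpdf(x):
            th = x[0]
            return (-0.5 * np.sum((y - th) ** 2) / sigma2
                    - 0.5 * (th - mu0) ** 2 / tau02)

        draws, _ = adaptive_mwg(logpdf, np.array([0.0]), 500, 4000, seed=11)
        assert draws[:, 0].mean() == pytest.approx(post_mean, abs=4 * math.sqrt(post_var / 400))
        assert draws[:, 0].var() == pytest.approx(post_var, rel=0.15)

    def test_sample_posterior_callable_route(self):
        d = sample_posterior(lambda x: -0.5 * float(x[0] ** 2), chains=2,
                             iterations=400, warmup=200, seed=3,
                             x0=np.array([0.5]))
        assert d.group["x"].shape == (2, 400, 1)
        assert abs(d.group["x"].mean()) < 0.2


class TestDeterminism:
    def test_identical_seeds_identical_draws(self, small_trials):
        trials, _ = small_trials
        m = S.HierarchicalDDM(trials)
        d1 = sample_posterior(m, chains=2, iterations=50, warmup=50, seed=42)
        d2 = sample_posterior(m, chains=2, iterations=50, warmup=50, seed=42)
        for f in FAMILIES:
            np.testing.assert_array_equal(d1.group[f], d2.group[f])
            np.testing.assert_array_equal(d1.subject[f], d2.subject[f])
        d3 = sample_posterior(m, chains=1, iterations=50, warmup=50, seed=43)
        assert not np.array_equal(d1.group["delta"][:1], d3.group["delta"])


def _fake_draws(diff_mean, sd_group, n=40_000, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(1.0 + diff_mean, 0.01, (1, n))
    b = rng.normal(1.0, 0.01, (1, n))
    tau = np.full((1, n), 1.0 / sd_group**2)
    return PosteriorDraws(
        group={"delta": np.stack([a, b], axis=2)},
        tau={"delta": tau},
        cells={"delta": [("black",), ("white",)]},
        factors={"delta": ("race",)})


class TestContrast:
    def test_identical_cells_give_exact_zero(self, small_fit):
        _, draws = small_fit
        c = contrast(draws, "beta", {"race": "black"}, {"race": "black"})
        assert c.mean == 0.0 and c.d_mean == 0.0 and not c.excludes_zero

    def test_standardized_effect_reproduces_reported_pair(self):
        """A 0.62 group-mean difference with group SD 0.58 standardizes to
        d ~ 1.07 (the inversion of a published mean/d pair)."""
        draws = _fake_draws(0.62, 0.58)
        c = contrast(draws, "delta", {"race": "black"}, {"race": "white"})
        assert c.mean == pytest.approx(0.62, abs=0.01)
        assert c.d_mean == pytest.approx(1.07, abs=0.02)
        assert c.excludes_zero

    def test_marginal_contrast_averages_cells(self):
        rng = np.random.default_rng(1)
        g = np.stack([rng.normal(m, 0.01, (1, 5000)) for m in (2.3, -1.7, 2.0, -2.0)],
                     axis=2)
        draws = PosteriorDraws(
            group={"delta": g}, tau={"delta": np.ones((1, 5000))},
            cells={"delta": [("black", "gun"), ("black", "nongun"),
                             ("white", "gun"), ("white", "nongun")]},
            factors={"delta": ("race", "object")})
        c = marginal_contrast(draws, "delta", "race", "black", "white")
        assert c.mean == pytest.approx(0.5 * ((2.3 - 2.0) + (-1.7 + 2.0)), abs=0.01)

    def test_unknown_cell_raises(self, small_fit):
        _, draws = small_fit
        with pytest.raises(KeyError):
            contrast(draws, "beta", {"race": "purple"}, {"race": "white"})
        with pytest.raises(KeyError):
            marginal_contrast(draws, "beta", "object", "gun", "nongun")


class TestDic:
    def test_degenerate_draws_zero_complexity(self, small_fit):
        """With every draw identical, the effective parameter count is 0."""
        model, draws = small_fit
        frozen = PosteriorDraws(
            group={f: np.repeat(draws.group[f][:1, :1], 10, axis=1) for f in FAMILIES},
            tau={f: np.repeat(draws.tau[f][:1, :1], 10, axis=1) for f in FAMILIES},
            subject={f: np.repeat(draws.subject[f][:1, :1], 10, axis=1)
                     for f in FAMILIES},
            cells=draws.cells, factors=draws.factors,
            log_likelihood=np.repeat(draws.log_likelihood[:1, :1], 10, axis=1))
        dic_val, p_d = dic(frozen, model)
        assert p_d == pytest.approx(0.0, abs=1e-6)
        assert dic_val == pytest.approx(float(-2 * draws.log_likelihood[0, 0]),
                                        abs=1e-6)

    def test_matches_independent_formula(self, small_fit):
        """DIC from the packaged routine equals D(theta_bar) + 2 p_D
        assembled from the reference (pure-Python) likelihood."""
        model, draws = small_fit
        dic_val, p_d = dic(draws, model)
        mean_dev = float(np.mean(-2.0 * draws.log_likelihood))
        theta_bar = S.SubjectParams(
            theta={f: draws.subject[f].mean(axis=(0, 1)) for f in FAMILIES})
        d_hat = -2.0 * model.log_likelihood(theta_bar)
        assert p_d == pytest.approx(mean_dev - d_hat, rel=1e-6)
        assert dic_val == pytest.approx(d_hat + 2 * (mean_dev - d_hat), rel=1e-6)
        assert p_d > 0

    def test_loglik_trace_matches_reference(self, small_fit):
        model, draws = small_fit
        c, d = 1, 7
        subj = S.SubjectParams(theta={f: draws.subject[f][c, d] for f in FAMILIES})
        assert draws.log_likelihood[c, d] == pytest.approx(
            model.log_likelihood(subj), rel=1e-9)


class TestPosteriorPredictive:
    def test_reproducible_and_window_respected(self, study4_scale_fit):
        _, _, model, draws = study4_scale_fit
        t1 = posterior_predictive(draws, model, reps=3, seed=9)
        t2 = posterior_predictive(draws, model, reps=3, seed=9)
        assert t1.equals(t2)
        assert (t1["statistic"] == "p_shoot").any()

    def test_self_consistency_coverage(self, study4_scale_fit):
        """Data simulated from the fitted model itself should mostly fall
        inside the 95% predictive intervals."""
        _, _, model, draws = study4_scale_fit
        t = posterior_predictive(draws, model, reps=40, seed=5)
        t = t.dropna(subset=["observed", "pred_lo"])
        inside = ((t["observed"] >= t["pred_lo"]) &
                  (t["observed"] <= t["pred_hi"])).mean()
        assert inside >= 0.85

    def test_invalid_reps(self, study4_scale_fit):
        _, _, model, draws = study4_scale_fit
        with pytest.raises(ValueError):
            posterior_predictive(draws, model, reps=0)


class TestConvergence:
    def test_group_level_rhat_small(self, study4_scale_fit):
        """Split-Rhat of every group-level mean at default settings."""
        _, _, _, draws = study4_scale_fit
        summary = draws.summary()
        means = summary[~summary["parameter"].str.startswith("tau_")]
        assert means["rhat"].max() <= 1.05
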