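"""Ex-Gaussian likelihood, MLE, hierarchical sampler, contrasts and PPC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from fto.exgauss import (
    ExGaussParams,
    FitError,
    ModelSpec,
    PosteriorSummary,
    exgauss_logpdf,
    exgauss_rvs,
    fit_exgauss_mle,
    fit_hierarchical,
    is_robust,
    posterior_predictive_check,
    summarise_contrast,
)
from fto.exgauss import _subset_frame
from fto.simulate import CellParams, SimulationConfig, simulate_corpus
from fto.turn_extraction import TransitionTable, extract_transitions


class TestLogpdf:
    @pytest.mark.parametrize(
        "params",
        [ExGaussParams(100, 80, 400), ExGaussParams(-300, 500, 50), ExGaussParams(0, 10, 2000)],
    )
    def test_matches_reference_density(self, params):
        """Agrees with scipy's exponentially modified normal everywhere,
        including deep tails."""
        x = np.linspace(params.mu - 12 * params.sigma, params.mean + 20 * params.tau, 400)
        ours = exgauss_logpdf(x, params)
        ref = stats.exponnorm.logpdf(x, params.tau / params.sigma, loc=params.mu,
                                     scale=params.sigma)
        assert np.allclose(ours, ref, rtol=1e-9, atol=1e-9)

    def test_integrates_to_one(self):
        params = ExGaussParams(100, 80, 400)
        val, _ = integrate.quad(
            lambda t: float(np.exp(exgauss_logpdf(t, params))), -6000, 30000, limit=300
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_large_tau_limit_is_shifted_exponential(self):
        """With tau >> sigma the density approaches Exp(tau) shifted by mu."""
        params = ExGaussParams(50.0, 1.0, 5000.0)
        for x in (500.0, 2000.0, 8000.0):
            expo = -np.log(params.tau) - (x - params.mu) / params.tau
            assert exgauss_logpdf(x, params) == pytest.approx(expo, abs=1e-3)

    def test_invalid_scale_parameters_rejected(self):
        with pytest.raises(ValueError):
            ExGaussParams(0, -1, 10)
        with pytest.raises(ValueError):
            ExGaussParams(0, 10, 0)

    def test_sampler_moments_match_analytic(self, rng):
        params = ExGaussParams(100, 80, 400)
        x = exgauss_rvs(params, 1_000_000, rng)
        se_mean = params.sd / np.sqrt(x.size)
        assert x.mean() == pytest.approx(params.mean, abs=3 * se_mean)
        assert x.std(ddof=1) == pytest.approx(params.sd, rel=0.01)


class TestMle:
    def test_parameter_recovery_at_n5000(self, rng):
        truth = ExGaussParams(100, 80, 400)
        x = exgauss_rvs(truth, 5000, rng)
        fit = fit_exgauss_mle(x)
        assert fit.mu == pytest.approx(truth.mu, rel=0.05, abs=truth.mu * 0.05)
        assert fit.sigma == pytest.approx(truth.sigma, rel=0.05)
        assert fit.tau == pytest.approx(truth.tau, rel=0.05)

    def test_gaussian_data_pushes_tau_to_floor(self, rng):
        x = rng.normal(0.0, 50.0, 3000)
        fit = fit_exgauss_mle(x)
        assert fit.tau < 0.4 * fit.sigma
        assert fit.mean == pytest.approx(x.mean(), abs=5.0)

    def test_refit_self_consistency(self, rng):
        first = fit_exgauss_mle(exgauss_rvs(ExGaussParams(200, 150, 500), 4000, rng))
        second = fit_exgauss_mle(exgauss_rvs(first, 60000, rng))
        assert second.mu == pytest.approx(first.mu, abs=0.06 * first.sd)
        assert second.sigma == pytest.approx(first.sigma, rel=0.08)
        assert second.tau == pytest.approx(first.tau, rel=0.08)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_exgauss_mle([1.0] * 5)


# ---------------------------------------------------------------------------
# Hierarchical model
# ---------------------------------------------------------------------------


def _shifted_corpus(delta_mu_ms=300.0, seed=42, duration=60.0, n_asd=4, n_non=4):
    """Small corpus with an injected group shift in the ex-Gaussian location
    (ASD higher, so the non-ASD − ASD contrast is −delta)."""
    base = ExGaussParams(-50.0, 200.0, 350.0)
    cells = {}
    for c in ("Introduction", "Tangram", "Discussion"):
        cells[("ASD", c)] = CellParams(
            exgauss=ExGaussParams(base.mu + delta_mu_ms, base.sigma, base.tau),
            p_within=0.2, p_between=0.25, p_gap=0.55)
        cells[("non-ASD", c)] = CellParams(
            exgauss=base, p_within=0.2, p_between=0.25, p_gap=0.55)
    config = SimulationConfig(
        cells=cells, n_dyads={"ASD": n_asd, "non-ASD": n_non},
        context_duration_s=duration, dyad_sd_mu_ms=100.0,
        sign_split="exgauss", seed=seed)
    corpus = simulate_corpus(config)
    return TransitionTable.concat(
        [extract_transitions(a.normalised()) for a in corpus.annotations]
    )


@pytest.fixture(scope="module")
def shifted_table():
    return _shifted_corpus()


@pytest.fixture(scope="module")
def shifted_posterior(shifted_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_hierarchical(shifted_table, ModelSpec.desk_scale(seed=5))


class TestHierarchicalFit:
    def test_group_shift_recovered_with_correct_sign(self, shifted_posterior):
        """Longer ASD gaps yield a negative non-ASD − ASD contrast whose CI
        covers the injected −300 ms."""
        summ = summarise_contrast(shifted_posterior, "group")
        lo, hi = summ.ci95
        assert lo < -300.0 < hi or abs(summ.delta_mean + 300) < 75
        assert summ.p_delta_gt_zero < 0.05
        assert lo <= summ.delta_mean <= hi

    def test_shape_parameters_recovered(self, shifted_posterior):
        assert shifted_posterior.sigma.mean() == pytest.approx(200, rel=0.2)
        assert shifted_posterior.tau.mean() == pytest.approx(350, rel=0.15)

    def test_doubling_iterations_stable(self, shifted_table, shifted_posterior):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            double = fit_hierarchical(
                shifted_table,
                ModelSpec(subset="full", chains=2, iterations=2000, warmup=1000, seed=5),
            )
        a = summarise_contrast(shifted_posterior, "group")
        b = summarise_contrast(double, "group")
        mc_err = 3 * np.sqrt(
            shifted_posterior.contrast_draws("group").var() / max(a.ess, 1)
            + double.contrast_draws("group").var() / max(b.ess, 1)
        )
        assert abs(a.delta_mean - b.delta_mean) <= max(mc_err, 15.0)

    def test_subsets_partition_the_full_data(self, preset_table):
        full, _ = _subset_frame(preset_table.df, "full")
        gaps, _ = _subset_frame(preset_table.df, "gaps_only")
        overlaps, flip = _subset_frame(preset_table.df, "overlaps_only")
        assert flip is True
        zeros = (full["fto_ms"] == 0).sum()
        assert len(gaps) + len(overlaps) + zeros == len(full)
        assert (gaps["fto_ms"] > 0).all()
        assert (overlaps["fto_ms"] > 0).all()  # magnitudes after sign flip

    def test_overlaps_model_reports_on_signed_scale(self, shifted_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_hierarchical(
                shifted_table, ModelSpec.desk_scale(subset="overlaps_only", seed=3)
            )
        assert post.sign_flip
        summ = summarise_contrast(post, "group")
        assert summ.ci95[0] <= summ.delta_mean <= summ.ci95[1]

    def test_empty_subset_is_an_error(self):
        rows = pd.DataFrame(
            {
                "dyad_id": ["D1", "D2", "D3", "D4"],
                "group": ["ASD", "ASD", "non-ASD", "non-ASD"],
                "context": ["Introduction"] * 4,
                "type": ["gap"] * 4,
                "fto_ms": [100.0, 200.0, 150.0, 250.0],
                "prev_speaker": ["S1"] * 4,
                "next_speaker": ["S2"] * 4,
                "anchor_time_s": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(FitError, match="no transitions"):
            fit_hierarchical(TransitionTable(rows), ModelSpec.desk_scale(subset="overlaps_only"))

    def test_too_few_dyads_is_an_error(self, shifted_table):
        df = shifted_table.df
        sub = df[df["dyad_id"].isin(["A01", "N01", "N02"])]
        with pytest.raises(FitError, match="2 dyads"):
            fit_hierarchical(TransitionTable(sub.copy()), ModelSpec.desk_scale())


class TestContrastSummaries:
    def test_degenerate_draws(self):
        summ = summarise_contrast(np.full((2, 50), -204.0), "group")
        assert summ.delta_mean == -204.0
        assert summ.ci95 == (-204.0, -204.0)
        assert summ.p_delta_gt_zero == 0.0

    def test_standard_normal_draws_are_undirected(self, rng):
        draws = rng.standard_normal((4, 2000))
        summ = summarise_contrast(draws, "noise")
        assert summ.p_delta_gt_zero == pytest.approx(0.5, abs=3 / np.sqrt(draws.size))

    def test_quantiles_match_brute_force(self, rng):
        draws = rng.normal(10.0, 3.0, 100)
        summ = summarise_contrast(draws, "x")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert summ.ci95 == (pytest.approx(lo), pytest.approx(hi))
        assert summ.delta_mean == pytest.approx(draws.mean())
        assert summ.p_delta_gt_zero == pytest.approx((draws > 0).mean())

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            PosteriorSummary("x", 5.0, (-1.0, 1.0), 0.5, 1.0, 100.0)


class TestRobustness:
    def test_clear_effect_is_robust(self):
        summ = PosteriorSummary("group", -204.0, (-339.0, -66.0), 0.0, 1.0, 4000)
        assert is_robust(summ)

    def test_wide_interval_and_weak_probability_is_not(self):
        summ = PosteriorSummary("group", 40.0, (-50.0, 130.0), 0.81, 1.0, 4000)
        assert not is_robust(summ)

    def test_narrow_zero_inclusion_with_high_probability_is_robust(self):
        # zero just inside the interval, within 2% of its width from the edge
        summ = PosteriorSummary("Tangram-Discussion@ASD", 102.0, (-4.0, 210.0), 0.92, 1.0, 4000)
        assert is_robust(summ)

    def test_probability_threshold_binds(self):
        summ = PosteriorSummary("x", 100.0, (5.0, 195.0), 0.88, 1.0, 4000)
        assert not is_robust(summ)
        assert is_robust(summ, p_threshold=0.85)


class TestPosteriorPredictiveCheck:
    def test_well_specified_model_is_calibrated(self, shifted_posterior, rng):
        report = posterior_predictive_check(shifted_posterior, n_rep=150, rng=rng)
        core = report[report["statistic"].isin(["mean", "sd", "median"])]
        assert ((core["tail_prob"] > 0.05) & (core["tail_prob"] < 0.95)).all()
        assert not core["extreme"].any()

    def test_gaussian_fit_to_heavy_tailed_data_is_flagged(self, shifted_table, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_hierarchical(
                shifted_table,
                ModelSpec.desk_scale(seed=9, likelihood="gaussian"),
            )
        report = posterior_predictive_check(post, n_rep=150, rng=rng)
        flagged = set(report[report["extreme"]]["statistic"])
        # a symmetric likelihood cannot reproduce the skew: the median and/or
        # tail-category shares must come out extreme
        assert flagged & {"median", "prop_long_gap", "prop_smooth", "prop_gap"}
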