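"""Rank-frequency model fitting, R^2/AIC, selection rule, correlations."""

import math

import numpy as np
import pytest

import kmerlex as kx
from kmerlex.simulate import exact_frequencies


class TestPredict:
    def test_zipf_direct_evaluation(self):
        f = kx.predict(kx.ZipfModel(C=0.5), np.arange(1, 5))
        assert np.allclose(f, [0.5, 0.25, 0.5 / 3, 0.125])

    def test_zm_reduces_to_zipf_at_zero_shift(self):
        ranks = np.arange(1, 101)
        zm = kx.predict(kx.ZipfMandelbrotModel(C=1.0, s=1.0, q=0.0), ranks)
        assert np.allclose(zm, kx.predict(kx.ZipfModel(C=1.0), ranks), atol=1e-12)

    def test_tpl_pure_exponential_limit(self):
        f = kx.predict(kx.TruncatedPowerLawModel(C=1.0, alpha=0.0, lam=0.5), np.arange(1, 4))
        assert np.allclose(f, np.exp([-0.5, -1.0, -1.5]))

    def test_tpl_reduces_to_power_law_without_cutoff(self):
        ranks = np.arange(1, 101)
        tpl = kx.predict(kx.TruncatedPowerLawModel(C=0.3, alpha=1.2, lam=0.0), ranks)
        assert np.allclose(tpl, 0.3 * ranks**-1.2, atol=1e-12)

    def test_nonpositive_rank_rejected(self):
        with pytest.raises(ValueError):
            kx.predict(kx.ZipfModel(C=0.5), np.array([0, 1]))


class TestRSquaredAic:
    def test_perfect_prediction(self):
        y = np.array([0.5, 0.3, 0.2])
        assert kx.r_squared(y, y) == 1.0

    def test_mean_baseline_is_zero(self):
        y = np.array([0.5, 0.3, 0.2])
        assert kx.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_negative_value(self):
        obs = np.array([0.5, 0.3, 0.2])
        pred = np.array([0.2, 0.3, 0.5])
        expected = 1 - 0.18 / float(np.sum((obs - obs.mean()) ** 2))
        assert kx.r_squared(obs, pred) == pytest.approx(expected)
        assert expected == pytest.approx(-2.857, abs=2e-3)

    def test_degenerate_constant_observations(self):
        assert math.isnan(kx.r_squared(np.ones(3), np.ones(3) * 2))

    def test_aic_parameter_penalty(self):
        assert kx.aic(1.0, 50, 3) - kx.aic(1.0, 50, 1) == pytest.approx(4.0)

    def test_aic_halved_residuals(self):
        delta = kx.aic(0.5, 100, 2) - kx.aic(1.0, 100, 2)
        assert delta == pytest.approx(-100 * math.log(2))

    def test_aic_perfect_fit_sentinel(self):
        assert kx.aic(0.0, 10, 3) == float("-inf")


class TestFitZipf:
    def test_exact_zipfian_table(self):
        c = exact_frequencies(kx.ZipfModel(C=1.0), 50)
        fit = kx.fit_zipf(kx.RankFrequencyTable(counts=c))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.p_free == 1

    def test_uniform_table_negative_r2(self):
        fit = kx.fit_zipf(kx.RankFrequencyTable(counts=np.ones(100)))
        assert fit.r_squared < 0

    def test_single_row_degenerate(self):
        fit = kx.fit_zipf(kx.RankFrequencyTable(counts=np.array([3.0])))
        assert fit.degenerate and math.isnan(fit.r_squared)

    def test_free_scale_variant(self):
        c = exact_frequencies(kx.ZipfModel(C=1.0), 50)
        fit = kx.fit_zipf(kx.RankFrequencyTable(counts=c), free_scale=True)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.p_free == 2


@pytest.mark.parametrize("s", [1.2, 2.0, 3.0])
@pytest.mark.parametrize("q", [1.0, 5.0, 20.0])
def test_zm_noiseless_recovery(s, q):
    true = kx.ZipfMandelbrotModel(C=1.0, s=s, q=q)
    table = kx.synth_rank_table(true, 1000)
    fit = kx.fit_zipf_mandelbrot(table)
    true_c = exact_frequencies(true, 1000)[0] * (1 + q) ** s
    assert fit.converged
    assert fit.params.s == pytest.approx(s, rel=1e-3)
    assert fit.params.q == pytest.approx(q, rel=1e-3)
    assert fit.params.C == pytest.approx(true_c, rel=1e-3)


@pytest.mark.parametrize("alpha", [0.3, 0.8, 1.5])
@pytest.mark.parametrize("lam", [0.001, 0.01, 0.05])
def test_tpl_noiseless_recovery(alpha, lam):
    true = kx.TruncatedPowerLawModel(C=1.0, alpha=alpha, lam=lam)
    table = kx.synth_rank_table(true, 1000)
    fit = kx.fit_truncated_power_law(table)
    true_c = exact_frequencies(true, 1000)[0] * math.exp(lam)
    assert fit.converged
    assert fit.params.alpha == pytest.approx(alpha, rel=1e-3, abs=1e-6)
    assert fit.params.lam == pytest.approx(lam, rel=1e-3)
    assert fit.params.C == pytest.approx(true_c, rel=1e-3)


class TestFitBehaviour:
    def test_zm_multinomial_recovery(self):
        true = kx.ZipfMandelbrotModel(C=1.0, s=2.0, q=5.0)
        table = kx.synth_rank_table(true, 1000, n_draws=10**6, seed=42)
        fit = kx.fit_zipf_mandelbrot(table)
        assert fit.params.s == pytest.approx(2.0, rel=0.05)
        assert fit.params.q == pytest.approx(5.0, rel=0.05)
        assert fit.r_squared > 0.99

    def test_zm_pure_zipf_data_collapses_shift(self):
        table = kx.synth_rank_table(kx.ZipfModel(C=1.0), 1000)
        fit = kx.fit_zipf_mandelbrot(table)
        assert fit.params.q < 1e-3
        assert fit.params.s == pytest.approx(1.0, abs=1e-4)

    def test_tpl_pure_power_law_collapses_cutoff(self):
        table = kx.synth_rank_table(
            kx.TruncatedPowerLawModel(C=1.0, alpha=1.0, lam=0.0), 1000
        )
        fit = kx.fit_truncated_power_law(table)
        assert fit.params.lam < 1e-4

    def test_flat_then_cliff_table_returns_flagged_result(self):
        # uniform head with an abrupt absent tail, like sparse high-k spectra
        counts = np.concatenate([np.full(50, 100.0), [1.0]])
        fit = kx.fit_truncated_power_law(kx.RankFrequencyTable(counts=counts))
        assert fit.converged  # result returned even if quality is poor
        assert fit.r_squared < 1.0

    def test_stored_r2_consistent_with_params(self, small_genome):
        table = kx.to_rank_frequency(kx.count_canonical_kmers(small_genome, 5))
        for fit in (kx.fit_zipf_mandelbrot(table), kx.fit_truncated_power_law(table)):
            recomputed = kx.r_squared(table.frequencies, fit.predict(table.ranks))
            assert recomputed == pytest.approx(fit.r_squared, abs=1e-12)

    def test_fit_determinism(self, small_genome):
        table = kx.to_rank_frequency(kx.count_canonical_kmers(small_genome, 4))
        assert kx.fit_zipf_mandelbrot(table) == kx.fit_zipf_mandelbrot(table)
        assert kx.fit_truncated_power_law(table) == kx.fit_truncated_power_law(table)

    def test_aic_prefers_true_zm_over_zipf(self):
        wins = 0
        for seed in range(30):
            table = kx.synth_rank_table(
                kx.ZipfMandelbrotModel(C=1.0, s=2.0, q=5.0), 500,
                n_draws=10**5, seed=seed,
            )
            zm = kx.fit_zipf_mandelbrot(table)
            zipf = kx.fit_zipf(table)
            wins += zm.aic <= zipf.aic
        assert wins >= int(0.95 * 30)


class TestSelectModel:
    def _fits(self, zm_r2, tpl_r2, zm_aic, tpl_aic):
        zm = kx.FitResult(
            model="zipf_mandelbrot",
            params=kx.ZipfMandelbrotModel(C=0.1, s=1.0, q=1.0),
            r_squared=zm_r2, ss_res=1.0, ss_tot=2.0, aic=zm_aic,
            n_points=100, p_free=3, converged=True,
        )
        tpl = kx.FitResult(
            model="truncated_power_law",
            params=kx.TruncatedPowerLawModel(C=0.1, alpha=1.0, lam=0.0),
            r_squared=tpl_r2, ss_res=1.0, ss_tot=2.0, aic=tpl_aic,
            n_points=100, p_free=3, converged=True,
        )
        return {"zipf_mandelbrot": zm, "truncated_power_law": tpl}

    def test_k7_failing_tpl_flagged_and_avoided(self):
        choice = kx.select_model(7, self._fits(0.96, -0.4, -100, -50))
        assert choice.chosen == "zipf_mandelbrot"
        assert choice.negative_r2_flags["truncated_power_law"]

    def test_mid_k_tie_goes_to_tpl(self):
        choice = kx.select_model(5, self._fits(0.9, 0.9, -100, -100))
        assert choice.chosen == "truncated_power_law"

    def test_mid_k_lower_aic_wins(self):
        choice = kx.select_model(4, self._fits(0.95, 0.94, -120, -100))
        assert choice.chosen == "zipf_mandelbrot"


class TestCorrelateFitQuality:
    def test_monotone_pairs(self):
        x = np.arange(20.0)
        up = kx.correlate_fit_quality(x, x)
        down = kx.correlate_fit_quality(-x, x)
        assert up.rho[0] == pytest.approx(1.0)
        assert down.rho[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        rep = kx.correlate_fit_quality(np.ones(10), np.arange(10.0))
        assert math.isnan(rep.rho[0])

    def test_u_shape_detected_by_quartiles(self):
        # noise comparable to the within-quartile signal of the middle
        # quartiles, so only the limbs of the U retain strong correlations
        rng = np.random.default_rng(11)
        gc = rng.uniform(0.1, 0.9, size=400)
        r2 = (gc - 0.5) ** 2 + rng.normal(0, 0.05, size=400)
        rep = kx.correlate_fit_quality(r2, gc, quartile_stratify=True)
        by = dict(zip(rep.strata, rep.rho))
        assert by["Q1"] < -0.5
        assert by["Q4"] > 0.5
        assert abs(by["Q2"]) < 0.5 and abs(by["Q3"]) < 0.5
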