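"""GLS MR estimation: Wald ratios, IVW/Egger, heterogeneity, model selection,
outlier pruning, and multivariable MR."""

import numpy as np
import pytest
from scipy import stats

from conftest import identity_ld, instrument_set, make_keys
from targetmr.errors import (CollinearityError, DegenerateInstrumentError,
                             InsufficientInstrumentsError,
                             UndefinedHeterogeneityError)
from targetmr.mr import (cochran_q, gls_fit, mvmr_fit, prune_outliers,
                         select_model, wald_ratio)
from targetmr.simulate import ar1_matrix, simulate_instrument_set
from targetmr.sumstats import LDMatrix


class TestWaldRatio:
    def test_exact_division_with_zero_exposure_se(self):
        ratio, se = wald_ratio(0.5, 0.0, 0.2, 0.05)
        assert ratio == pytest.approx(0.4)
        assert se == pytest.approx(0.1)

    def test_null_outcome_gives_zero_ratio(self):
        ratio, _ = wald_ratio(1.0, 0.1, 0.0, 0.05)
        assert ratio == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.2, 0.05)

    def test_delta_se_matches_monte_carlo(self, rng):
        """First-order se vs 10^6 resamples of by*/bx*.

        The ratio of normals has heavy tails (no finite variance), so the
        comparison uses the 16-84% interquantile half-width, which equals the
        sd for the near-normal bulk the delta method approximates.
        """
        bx, sx, by, sy = 0.5, 0.1, 0.2, 0.05
        _, se = wald_ratio(bx, sx, by, sy)
        draws = (by + sy * rng.standard_normal(1_000_000)) / \
                (bx + sx * rng.standard_normal(1_000_000))
        q16, q84 = np.quantile(draws, [0.158655, 0.841345])
        assert se == pytest.approx((q84 - q16) / 2, rel=0.05)


class TestGLSFit:
    def test_single_variant_equals_wald_ratio_exactly(self, rng):
        keys = make_keys(1)
        instr = instrument_set(keys, [0.4], [0.01], [0.12], [0.03])
        fit = gls_fit(instr, "ivw", "fixed")
        ratio, se = wald_ratio(0.4, 0.0, 0.12, 0.03)
        assert fit.beta == pytest.approx(ratio, rel=1e-14)
        assert fit.se == pytest.approx(se, rel=1e-14)

    def test_identity_ld_matches_closed_form_ivw(self, rng):
        for _ in range(20):
            instr = simulate_instrument_set(rng, 15, 0.3, rho=0.0)
            fit = gls_fit(instr, "ivw", "fixed")
            bx, by, sy = instr.bx(), instr.by(), instr.sy()
            w = bx ** 2 / sy ** 2
            oracle = np.sum(w * by / bx) / np.sum(w)
            assert fit.beta == pytest.approx(oracle, abs=1e-10)
            assert fit.se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-10)

    def test_duplicated_variant_adds_no_information(self, rng):
        keys = make_keys(2)
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        instr = instrument_set(keys, [0.4, 0.4], [0.01, 0.01],
                               [0.12, 0.12], [0.03, 0.03],
                               ld=LDMatrix(keys, r))
        single = instrument_set(make_keys(1), [0.4], [0.01], [0.12], [0.03])
        fit2 = gls_fit(instr, "ivw", "fixed")
        fit1 = gls_fit(single, "ivw", "fixed")
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-6)
        assert fit2.se == pytest.approx(fit1.se, rel=1e-3)

    def test_egger_needs_three_variants(self, rng):
        instr = simulate_instrument_set(rng, 2, 0.3)
        with pytest.raises(InsufficientInstrumentsError):
            gls_fit(instr, "egger", "fixed")

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(30):
            instr = simulate_instrument_set(rng, 10, 0.2, pleiotropy_sd=0.01)
            assert gls_fit(instr, "ivw", "random").se >= gls_fit(instr, "ivw", "fixed").se

    def test_slope_equivariance_under_allele_flip(self, rng):
        instr = simulate_instrument_set(rng, 10, 0.3)
        flipped = instrument_set(
            [v for v in instr.ld.variants],
            -instr.bx(), instr.sx(), -instr.by(), instr.sy(),
            ld=instr.ld, px=instr.pairs["pvalue_x"].to_numpy())
        for family in ("ivw", "egger"):
            a = gls_fit(instr, family, "fixed")
            b = gls_fit(flipped, family, "fixed")
            assert b.beta == pytest.approx(a.beta, rel=1e-9)

    def test_slope_scales_inversely_with_exposure_units(self, rng):
        instr = simulate_instrument_set(rng, 10, 0.3)
        c = 2.5
        scaled = instrument_set(
            [v for v in instr.ld.variants],
            c * instr.bx(), c * instr.sx(), instr.by(), instr.sy(),
            ld=instr.ld, px=instr.pairs["pvalue_x"].to_numpy())
        a = gls_fit(instr, "ivw", "fixed")
        b = gls_fit(scaled, "ivw", "fixed")
        assert b.beta == pytest.approx(a.beta / c, rel=1e-9)


class TestCochranQ:
    def test_perfect_fit_gives_zero_q(self):
        keys = make_keys(4)
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        instr = instrument_set(keys, bx, 0.01 * np.ones(4),
                               0.5 * bx, 0.02 * np.ones(4))
        fit = gls_fit(instr, "ivw", "fixed")
        q, df, p, _ = cochran_q(instr, fit)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)
        assert df == 3

    def test_planted_outlier_has_maximal_contribution(self):
        keys = make_keys(10)
        bx = np.linspace(0.1, 0.3, 10)
        by = 0.5 * bx
        sy = 0.02 * np.ones(10)
        by[6] += 10 * sy[6]
        instr = instrument_set(keys, bx, 0.01 * np.ones(10), by, sy)
        fit = gls_fit(instr, "ivw", "fixed")
        _, _, _, contrib = cochran_q(instr, fit)
        assert int(np.argmax(contrib)) == 6

    def test_null_q_mean_matches_degrees_of_freedom(self, rng):
        n_snps, reps = 8, 1000
        qs = []
        for _ in range(reps):
            instr = simulate_instrument_set(rng, n_snps, 0.4, rho=0.0,
                                            n_x=10**8)  # negligible bx noise
            fit = gls_fit(instr, "ivw", "fixed")
            qs.append(fit.q)
        df = n_snps - 1
        tol = 4 * np.sqrt(2 * df / reps)
        assert np.mean(qs) == pytest.approx(df, abs=tol)

    def test_undefined_below_minimum_df(self):
        instr = instrument_set(make_keys(1), [0.1], [0.01], [0.05], [0.02])
        fit = gls_fit(instr, "ivw", "fixed")
        with pytest.raises(UndefinedHeterogeneityError):
            cochran_q(instr, fit)


class TestSelectModel:
    def test_two_variants_force_ivw_family(self, rng):
        instr = simulate_instrument_set(rng, 2, 0.3)
        est = select_model(instr)
        assert est.model.family == "ivw"

    def test_clean_null_prefers_ivw(self, rng):
        picks = [select_model(simulate_instrument_set(rng, 20, 0.0)).model.family
                 for _ in range(500)]
        assert picks.count("ivw") >= 450

    def test_directional_pleiotropy_power_grows_with_instruments(self, rng):
        freqs = []
        for n_snps in (5, 15, 40):
            hits = sum(
                select_model(simulate_instrument_set(
                    rng, n_snps, 0.3, intercept=0.05)).model.family == "egger"
                for _ in range(150))
            freqs.append(hits / 150)
        assert freqs[0] < freqs[-1]
        assert freqs[-1] > 0.9


class TestPruneOutliers:
    def test_homogeneous_set_unchanged(self, rng):
        instr = simulate_instrument_set(rng, 10, 0.3)
        pruned = prune_outliers(instr)
        assert pruned.n_snps == 10

    def test_planted_pleiotropic_variant_removed(self, rng):
        keys = make_keys(10)
        bx = np.linspace(0.1, 0.3, 10)
        by = 0.5 * bx + 0.002 * rng.standard_normal(10)
        sy = 0.02 * np.ones(10)
        by[3] += 12 * sy[3]
        instr = instrument_set(keys, bx, 0.01 * np.ones(10), by, sy)
        pruned = prune_outliers(instr)
        assert pruned.n_snps == 9
        assert keys[3].ident not in {v.ident for v in pruned.ld.variants}

    def test_stops_at_floor(self):
        keys = make_keys(2)
        instr = instrument_set(keys, [0.1, 0.2], [0.01, 0.01],
                               [0.5, -0.5], [0.01, 0.01])
        pruned = prune_outliers(instr)
        assert pruned.n_snps >= 1


class TestMVMR:
    def test_single_exposure_reduces_to_univariable_gls(self, rng):
        instr = simulate_instrument_set(rng, 12, 0.4)
        uni = gls_fit(instr, "ivw", "fixed")
        mv = mvmr_fit(instr.bx().reshape(-1, 1), instr.by(), instr.sy(),
                      instr.ld.r, ["x"])
        assert mv.beta[0] == pytest.approx(uni.beta, abs=1e-12)
        assert mv.se[0] == pytest.approx(uni.se, abs=1e-12)

    def test_recovers_two_orthogonal_exposure_effects(self, rng):
        """beta = (0.5, -0.3): each exposure's 95% CI covers its truth in
        >=93% of reps (two independent 95% CIs cannot jointly exceed ~90%).

        Exposure associations come from a large biomarker-consortium-scale
        GWAS (n=188k) paired with a smaller disease GWAS, the usual
        two-sample shape; the error model ignores exposure-side noise, so
        coverage runs slightly below nominal by design.
        """
        truth = np.array([0.5, -0.3])
        n_snps, reps = 20, 1000
        sx, sy = 1 / np.sqrt(188_000), 1 / np.sqrt(50_000 * 0.21)
        hits = np.zeros(2)
        for _ in range(reps):
            bx_true = np.zeros((n_snps, 2))
            bx_true[:10, 0] = rng.uniform(0.05, 0.15, 10)
            bx_true[10:, 1] = rng.uniform(0.05, 0.15, 10)
            bx_hat = bx_true + sx * rng.standard_normal((n_snps, 2))
            by = bx_true @ truth + sy * rng.standard_normal(n_snps)
            est = mvmr_fit(bx_hat, by, np.full(n_snps, sy), np.eye(n_snps),
                           ["a", "b"])
            hits += (est.ci_low <= truth) & (truth <= est.ci_high)
        assert np.all(hits / reps >= 0.93)

    def test_duplicated_exposure_column_raises_collinearity(self, rng):
        instr = simulate_instrument_set(rng, 10, 0.3)
        bx = np.column_stack([instr.bx(), instr.bx()])
        with pytest.raises(CollinearityError):
            mvmr_fit(bx, instr.by(), instr.sy(), instr.ld.r, ["a", "b"])

    def test_requires_more_variants_than_exposures(self, rng):
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_fit(np.ones((2, 2)), np.ones(2), np.ones(2), np.eye(2), ["a", "b"])
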