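"""Constraint ratios, bootstrap, SFS/alpha machinery, and the two tests."""

import numpy as np
import pytest
from scipy import stats

from tfselect import selstats as ss


class TestConstraintRatio:
    @pytest.mark.parametrize(
        "args,expected",
        [((10, 100, 10, 100), 1.0), ((5, 300, 10, 100), 1 / 6), ((0, 300, 10, 100), 0.0)],
    )
    def test_examples(self, args, expected):
        assert ss.constraint_ratio(*args) == pytest.approx(expected)

    def test_zero_neutral_count_is_undefined(self):
        with pytest.raises(ValueError, match="pool"):
            ss.constraint_ratio(5, 100, 0, 100)

    def test_zero_site_lengths_rejected(self):
        with pytest.raises(ValueError):
            ss.constraint_ratio(5, 0, 10, 100)


class TestBootstrap:
    def test_constant_statistic_gives_zero_width_ci(self):
        units = [(5, 100, 5, 100)] * 10
        est = ss.constraint_ratio_bootstrap(units, seed=1)
        assert est.ci == (1.0, 1.0)

    def test_fixed_seed_reproduces_replicates(self):
        rng = np.random.default_rng(0)
        units = [tuple(rng.integers(1, 50, 4)) for _ in range(12)]
        a = ss.constraint_ratio_bootstrap(units, seed=5)
        b = ss.constraint_ratio_bootstrap(units, seed=5)
        assert np.array_equal(a.replicates, b.replicates)

    def test_needs_two_units(self):
        with pytest.raises(ValueError):
            ss.bootstrap_ci([1], lambda u: 1.0)

    def test_ci_coverage_on_known_ratio(self):
        """95% bootstrap CI covers the true ratio in roughly 95% of simulations."""
        rng = np.random.default_rng(42)
        n_sim, n_units, covered = 200, 40, 0
        for s in range(n_sim):
            # per-gene Poisson counts with true ratio (5/300)/(10/300) = 0.5
            test = rng.poisson(5.0, n_units)
            neut = rng.poisson(10.0, n_units)
            units = [(t, 300.0, u, 300.0) for t, u in zip(test, neut)]
            try:
                est = ss.constraint_ratio_bootstrap(units, n_reps=200, seed=s)
            except ValueError:
                continue
            if est.ci[0] <= 0.5 <= est.ci[1]:
                covered += 1
        # binomial tolerance around 0.95
        assert 0.90 <= covered / n_sim <= 0.99


class TestSfs:
    def test_singletons_fall_in_first_bin(self):
        counts = ss.build_sfs(np.full(30, 1 / 100), n_classes=50)
        assert counts[0] == 30 and counts[1:].sum() == 0

    def test_total_binned_count_is_conserved(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.001, 0.999, 500)
        assert ss.build_sfs(f, 50).sum() == 500

    def test_uniform_frequencies_fill_bins_evenly(self):
        rng = np.random.default_rng(2)
        counts = ss.build_sfs(rng.uniform(0.0001, 0.9999, 5000), 10)
        chi2 = ((counts - 500.0) ** 2 / 500.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_fixed_and_absent_rejected(self):
        with pytest.raises(ValueError):
            ss.build_sfs([0.0, 0.5])
        with pytest.raises(ValueError):
            ss.build_sfs([0.5, 1.0])


class TestAlphaCurve:
    def test_equal_counts_give_zero_alpha(self):
        c = ss.alpha_curve(np.full(10, 7.0), np.full(10, 7.0), 12, 12)
        assert np.allclose(c.alpha, 0.0)

    def test_missing_classes_flagged_not_imputed(self):
        ps = np.array([5.0, 0.0, 5.0, 5.0])
        c = ss.alpha_curve(np.ones(4), ps, 10, 10)
        assert np.isnan(c.alpha[1]) and np.isfinite(c.alpha[[0, 2, 3]]).all()

    def test_zero_divergence_is_an_error(self):
        with pytest.raises(ValueError):
            ss.alpha_curve(np.ones(5), np.ones(5), 0, 10)


class TestAsymptoticFit:
    def test_noiseless_exponential_recovered_to_four_decimals(self):
        x = ss.sfs_midpoints(50)
        y = 0.3 - 0.5 * np.exp(-5 * x)
        curve = ss.AlphaCurve(x, y, np.ones(50), np.ones(50), 10, 10)
        fit = ss.fit_asymptote(curve, n_reps=0)
        assert fit.a == pytest.approx(0.3, abs=1e-4)
        assert fit.b == pytest.approx(-0.5, abs=1e-4)
        assert fit.c == pytest.approx(5.0, abs=1e-3)
        assert fit.asymptote == pytest.approx(0.3 - 0.5 * np.exp(-5), abs=1e-4)

    def test_constant_curve_recovers_flat_asymptote(self):
        x = ss.sfs_midpoints(20)
        curve = ss.AlphaCurve(x, np.full(20, 0.2), np.ones(20), np.ones(20), 5, 5)
        fit = ss.fit_asymptote(curve, n_reps=0)
        assert fit.asymptote == pytest.approx(0.2, abs=1e-3)

    def test_too_few_classes_rejected(self):
        x = ss.sfs_midpoints(5)
        a = np.array([0.1, np.nan, np.nan, 0.2, 0.3])
        curve = ss.AlphaCurve(x, a, np.ones(5), np.ones(5), 5, 5)
        with pytest.raises(ValueError):
            ss.fit_asymptote(curve, n_reps=0)


class TestSelectCutoffs:
    def _curve(self, a, b, c, n=50):
        # large counts: per-class noise is negligible for these noiseless curves
        x = ss.sfs_midpoints(n)
        y = a + b * np.exp(-c * x)
        return ss.AlphaCurve(x, y, np.full(n, 1e6), np.full(n, 1e6), 1e6, 1e6)

    def test_constant_curve_puts_f_low_at_first_class(self):
        curve = self._curve(0.2, 0.0, 1.0)
        fit = ss.fit_asymptote(curve, n_reps=0)
        cuts = ss.select_cutoffs(fit, curve)
        assert cuts.f_low == pytest.approx(curve.midpoints[0])

    def test_matches_closed_form_threshold_to_one_class_width(self):
        """f_low agrees with x = ln(|b| / (delta * range)) / c analytically."""
        delta = 0.1
        for a, b, c in [(0.3, -0.5, 5.0), (0.0, -2.0, 8.0), (0.1, -1.0, 3.5)]:
            curve = self._curve(a, b, c)
            fit = ss.fit_asymptote(curve, n_reps=0)
            cuts = ss.select_cutoffs(fit, curve, delta=delta, delta_abs=0.0, f_high=1.0)
            mids = curve.midpoints
            span = abs(fit.predict(mids).max() - fit.predict(mids).min())
            x_analytic = np.log(abs(b) / (delta * span)) / c
            assert abs(cuts.f_low - x_analytic) <= 1.0 / 50 + 1e-9

    def test_steeper_curves_converge_no_later(self):
        fits = []
        for c in (8.0, 2.0):
            curve = self._curve(0.3, -0.5, c)
            fit = ss.fit_asymptote(curve, n_reps=0)
            fits.append(ss.select_cutoffs(fit, curve).f_low)
        assert fits[0] <= fits[1]

    def test_f_high_defaults_to_09_and_is_overridable(self):
        curve = self._curve(0.3, -0.5, 5.0)
        fit = ss.fit_asymptote(curve, n_reps=0)
        assert ss.select_cutoffs(fit, curve).f_high == 0.9
        assert ss.select_cutoffs(fit, curve, f_high=0.8).f_high == 0.8

    def test_f_low_never_exceeds_f_high(self):
        curve = self._curve(0.0, -5.0, 0.5)  # never converges in range
        fit = ss.fit_asymptote(curve, n_reps=0)
        with pytest.warns(UserWarning):
            cuts = ss.select_cutoffs(fit, curve, delta=0.01)
        assert cuts.f_low <= cuts.f_high


class TestPooledMK:
    def test_symmetric_counts_give_zero(self):
        res = ss.pooled_mk_alpha(np.full(8, 0.5), np.full(8, 0.5), 8, 8, seed=0)
        assert res.alpha == pytest.approx(0.0)

    def test_no_nonsynonymous_polymorphism_gives_one(self):
        res = ss.pooled_mk_alpha([], np.full(10, 0.5), 10, 10, seed=0)
        assert res.alpha == pytest.approx(1.0)

    def test_direct_formula(self):
        assert ss.mk_alpha(5, 10, 10, 10) == pytest.approx(0.5)

    def test_cutoffs_filter_frequencies(self):
        fn = np.array([0.05, 0.5, 0.95])
        fs = np.array([0.05, 0.5, 0.5, 0.95])
        res = ss.pooled_mk_alpha(fn, fs, 10, 10, ss.FrequencyCutoffs(0.2, 0.9), seed=0)
        assert (res.Pn, res.Ps) == (1, 2)

    def test_undefined_without_divergence(self):
        with pytest.raises(ValueError):
            ss.pooled_mk_alpha([0.5], [0.5], 0, 10, seed=0)


class TestWelch:
    def test_textbook_vectors(self):
        a, b = [1, 2, 3, 4, 5], [11, 12, 13, 14, 15]
        t, p = ss.compare_classes_welch(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
        assert p < 0.01 and t < 0

    def test_swapping_arguments_flips_sign_same_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 25)
        t1, p1 = ss.compare_classes_welch(a, b)
        t2, p2 = ss.compare_classes_welch(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_identical_degenerate_vectors(self):
        assert ss.compare_classes_welch([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)


class TestFisher:
    def test_balanced_table(self):
        odds, p, prop_bd, prop_nonbd = ss.pathogenic_enrichment(10, 10, 10, 10)
        assert odds == 1.0 and p == 1.0
        assert prop_bd == prop_nonbd == 0.5

    def test_enriched_table_matches_hypergeometric_enumeration(self):
        odds, p, _, _ = ss.pathogenic_enrichment(9, 1, 1, 9)
        assert odds == pytest.approx(81.0)
        # independent oracle: enumerate the hypergeometric tail two-sidedly
        pmf = [stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_exact = sum(q for k, q in enumerate(pmf) if q <= pmf[9] + 1e-12)
        assert p == pytest.approx(p_exact, rel=1e-6)
        assert p == pytest.approx(0.0011, abs=2e-4)
        assert p < 0.01

    def test_zero_margin_gives_p_one(self):
        odds, p, _, _ = ss.pathogenic_enrichment(0, 0, 5, 5)
        assert p == 1.0
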