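"""Kinetic model fits, normalization, population curves, group statistics."""

import numpy as np
import pandas as pd
import pytest

from spherofuse import kinetics as kn
from spherofuse.features import FeatureRecord


def _records(n=12, area=1000.0, contact=40.0, widths=(80.0, 80.0)):
    out = []
    for t in range(n):
        out.append(FeatureRecord(
            frame=t, time=t * 5 / 60, stage=2, area=area, roundness=0.7,
            contact_length=contact, width_left=widths[0],
            width_right=widths[1]))
    return out


class TestNormalizeSeries:
    def test_constant_area_normalizes_to_one(self):
        df = kn.normalize_series(_records())
        assert np.allclose(df["norm_area"], 1.0)

    def test_contact_normalized_by_initial_width(self):
        df = kn.normalize_series(_records(contact=40.0, widths=(80.0, 80.0)))
        assert df["norm_contact"].iloc[0] == pytest.approx(0.5)

    def test_growing_area(self):
        recs = _records()
        for r in recs:
            r.area = 1000.0 * (1 + 0.05 * r.frame / (len(recs) - 1))
        df = kn.normalize_series(recs)
        assert df["norm_area"].iloc[-1] == pytest.approx(1.05, abs=0.01)

    def test_too_few_frames_rejected(self):
        with pytest.raises(kn.NormalizationError):
            kn.normalize_series(_records(n=5))

    def test_zero_initial_area_rejected(self):
        recs = _records()
        recs[0].area = 0.0
        with pytest.raises(kn.NormalizationError):
            kn.normalize_series(recs)


class TestFitExponential:
    def test_noiseless_self_consistency(self):
        t = np.arange(100) * 5 / 60
        y = 0.9 - 0.3 * np.exp(-t / 3.0)
        fit = kn.fit_exponential(t, y)
        assert fit.plateau == pytest.approx(0.9, abs=1e-4)
        assert fit.b == pytest.approx(-0.3, abs=1e-4)
        assert fit.tau == pytest.approx(3.0, abs=1e-3)
        assert fit.converged

    def test_tau_interpretation_63_percent(self):
        fit = kn.FusionFit(plateau=0.85, b=-0.25, tau=4.0, rss=0.0,
                           n_points=0, converged=True)
        r0 = fit.predict(0.0)
        frac = (fit.predict(4.0) - r0) / (fit.plateau - r0)
        assert frac == pytest.approx(1 - 1 / np.e, abs=1e-12)

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(0)
        t = np.arange(349) * 5 / 60
        for _ in range(10):
            y = rng.uniform(0.3, 1.1, t.size)  # garbage data
            fit = kn.fit_exponential(t, y)
            assert kn.PLATEAU_BOUNDS[0] <= fit.plateau <= kn.PLATEAU_BOUNDS[1]
            assert kn.B_BOUNDS[0] <= fit.b <= kn.B_BOUNDS[1]
            assert fit.tau > 0

    def test_monte_carlo_recovery(self):
        """tau within 10% and plateau within 0.01 (median over seeds)."""
        t = np.arange(349) * 5 / 60
        rng = np.random.default_rng(42)
        tau_errs, plat_errs = [], []
        for _ in range(100):
            tau = rng.uniform(1.0, 12.0)
            plateau = rng.uniform(0.75, 0.95)
            b = rng.uniform(-0.4, -0.2)
            y = plateau + b * np.exp(-t / tau) + rng.normal(0, 0.01, t.size)
            fit = kn.fit_exponential(t, y)
            tau_errs.append(abs(fit.tau - tau) / tau)
            plat_errs.append(abs(fit.plateau - plateau))
        assert np.median(tau_errs) < 0.10
        assert np.median(plat_errs) < 0.01

    def test_input_validation(self):
        t = np.arange(20) * 0.1
        with pytest.raises(ValueError):
            kn.fit_exponential(t[:5], np.ones(5))
        with pytest.raises(ValueError):
            kn.fit_exponential(t, np.full(20, np.nan))
        bad_t = t.copy()
        bad_t[5] = bad_t[4]
        with pytest.raises(ValueError):
            kn.fit_exponential(bad_t, np.ones(20))


class TestFitLinearContact:
    def test_exact_line_recovered(self):
        t = np.arange(0, 5, 5 / 60)
        fit = kn.fit_linear_contact(t, 0.3 + 0.08 * t)
        assert fit.intercept == pytest.approx(0.3, abs=1e-6)
        assert fit.slope == pytest.approx(0.08, abs=1e-6)

    def test_negative_trend_clamped_to_zero_slope(self):
        t = np.arange(0, 5, 5 / 60)
        fit = kn.fit_linear_contact(t, 0.5 - 0.02 * t)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_points_beyond_5h_ignored(self):
        t = np.arange(0, 10, 5 / 60)
        y = 0.3 + 0.08 * np.minimum(t, 5.0)  # plateau after 5 h
        fit = kn.fit_linear_contact(t, y)
        assert fit.intercept == pytest.approx(0.3, abs=1e-6)
        assert fit.slope == pytest.approx(0.08, abs=1e-6)
        assert fit.n_points == np.sum(t <= 5.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kn.fit_linear_contact(np.array([0, 1, 6, 7, 8.0]),
                                  np.array([1, 1, 1, 1, 1.0]))


class TestPopulationCurves:
    def test_identical_series_have_zero_sem(self):
        samples = [np.ones(20)] * 10
        mean, sem, n, trunc = kn.population_curves(samples)
        assert np.allclose(mean, 1.0) and np.allclose(sem, 0.0)
        assert trunc == 20

    def test_truncation_at_30_percent_dropout(self):
        samples = [np.ones(30)] * 7 + [np.ones(20)] * 3
        *_, trunc = kn.population_curves(samples)
        assert trunc == 20

    def test_later_dropout_does_not_move_truncation(self):
        samples = [np.ones(30)] * 6 + [np.ones(25)] + [np.ones(20)] * 3
        *_, trunc = kn.population_curves(samples)
        assert trunc == 20

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(size=15) for _ in range(6)]
        mean, sem, n, trunc = kn.population_curves(samples)
        for t in range(trunc):
            vals = [s[t] for s in samples if len(s) > t]
            assert mean[t] == pytest.approx(float(np.mean(vals)))


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 1.0, 1.0, 1.0])
        res = kn.compare_groups({"a": g, "b": g})
        assert res.omnibus_p > 0.9
        assert (res.pairwise["stars"] == "").all()

    def test_gaussian_separated_groups_use_parametric_branch(self):
        hits = 0
        branch_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = kn.compare_groups({"a": rng.normal(0, 1, 30),
                                     "b": rng.normal(3, 1, 30)})
            branch_hits += res.branch == "anova_tukey"
            hits += res.omnibus_p < 0.001
        assert hits >= 99
        # two Shapiro tests + Bartlett at alpha 0.05 reject ~14% of
        # genuinely Gaussian draws; expect the parametric branch ~86%
        assert branch_hits >= 75

    def test_lognormal_heteroscedastic_groups_use_nonparametric(self):
        nonpar = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            res = kn.compare_groups({"a": rng.lognormal(0, 1, 30),
                                     "b": rng.lognormal(0.2, 2.0, 30)})
            nonpar += res.branch == "kruskal_dunn_sidak"
        assert nonpar >= 90

    def test_three_group_pairwise_table(self):
        rng = np.random.default_rng(3)
        res = kn.compare_groups({"d1": rng.normal(0, 1, 25),
                                 "d7": rng.normal(0, 1, 25),
                                 "d21": rng.normal(4, 1, 25)})
        assert len(res.pairwise) == 3
        sig = res.significant_pairs()
        assert ("d1", "d21") in sig or ("d21", "d1") in sig

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            kn.compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
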