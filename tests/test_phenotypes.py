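"""Phenotype statistics: trait tables, ANOVA heritability, slopes, winsorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ridqtl.phenotypes import (fit_strain_slopes, intake_g_per_kg,
                               load_published_slope_table,
                               slope_trait_correlation, strain_anova,
                               trait_series, week_correlation_matrix,
                               weekly_strain_means, winsorize)
from ridqtl.simulate import DidDesign, simulate_did_phenotypes, simulate_ri_genotypes


def _records(rows):
    return pd.DataFrame(rows, columns=["animal_id", "strain", "week", "day",
                                       "access_h", "volume_ml", "body_g", "intake_gkg"])


class TestIntakeConversion:
    @pytest.mark.parametrize("volume_ml, vv, body_g, expected", [
        (0.0, 0.20, 25.0, 0.0),
        (1.0, 0.20, 25.0, 6.3144),        # 1 x 0.2 x 0.7893 / 0.025
        (2.0, 0.20, 50.0, 6.3144),        # scale invariance
    ])
    def test_values(self, volume_ml, vv, body_g, expected):
        assert intake_g_per_kg(volume_ml, vv, body_g) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            intake_g_per_kg(1.0, 0.2, 0.0)
        with pytest.raises(ValueError):
            intake_g_per_kg(1.0, 0.0, 25.0)


class TestWeeklyStrainMeans:
    def test_simple_mean_and_animal_count(self):
        rows = [(f"a1", "S1", 1, d, 2, 0.1, 20.0, v)
                for d, v in zip((1, 2, 3), (1.0, 2.0, 3.0))]
        rows += [(f"a2", "S1", 1, d, 2, 0.1, 20.0, v)
                 for d, v in zip((1, 2, 3), (1.0, 2.0, 3.0))]
        traits = weekly_strain_means(_records(rows))
        w1avg = traits[traits["trait_id"] == "W1avg"].iloc[0]
        assert w1avg["value"] == pytest.approx(2.0)
        assert w1avg["n_animals"] == 2
        w1d1 = traits[traits["trait_id"] == "W1D1"].iloc[0]
        assert w1d1["value"] == pytest.approx(1.0)

    def test_day4_sessions_kept_separate(self):
        rows = [("a1", "S1", 1, 1, 2, 0.1, 20.0, 1.0),
                ("a1", "S1", 1, 4, 4, 0.1, 20.0, 9.0)]
        traits = weekly_strain_means(_records(rows))
        assert trait_series(traits, "W1D4")["S1"] == pytest.approx(9.0)
        assert trait_series(traits, "W1avg")["S1"] == pytest.approx(1.0)

    def test_permutation_invariance_of_record_order(self):
        g = simulate_ri_genotypes(6, {1: (5, 50.0)}, seed=0)
        rec = simulate_did_phenotypes(g, [], DidDesign(replicates=3), seed=1)
        shuffled = rec.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = weekly_strain_means(rec).sort_values(["strain", "trait_id"]).reset_index(drop=True)
        b = weekly_strain_means(shuffled).sort_values(["strain", "trait_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_records_recover_generative_means(self):
        g = simulate_ri_genotypes(5, {1: (5, 50.0)}, seed=2)
        design = DidDesign(replicates=2, strain_sd=0, animal_sd=0, residual_sd=0,
                           slope_mean=0.2, slope_sd=0, baseline_gkg=2.0)
        traits = weekly_strain_means(simulate_did_phenotypes(g, [], design, seed=3))
        for k in range(1, 6):
            expected = 2.0 + 0.2 * (k - 1)
            assert trait_series(traits, f"W{k}avg").to_numpy() == pytest.approx(expected)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            weekly_strain_means(_records([]))


class TestStrainAnova:
    def test_zero_within_variance_gives_h2_one(self):
        res = strain_anova({"A": [1.0, 1.0], "B": [3.0, 3.0]})
        assert res.h2 == pytest.approx(1.0)
        assert res.df_between == 1

    def test_hand_computed_fixture(self):
        # SS_between = 1, SS_total = 5 -> h2 = 0.2
        res = strain_anova({"A": [0.0, 2.0], "B": [1.0, 3.0]})
        assert res.h2 == pytest.approx(0.2)
        assert res.df_between == 1 and res.df_within == 2

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = {f"S{i}": rng.normal(i * 0.1, 1.0, size=rng.integers(2, 9))
                  for i in range(12)}
        res = strain_anova(groups)
        ref = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.df_between == 11

    def test_constant_values_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            res = strain_anova({"A": [1.0, 1.0], "B": [1.0]})
        assert res.h2 == 0.0

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            strain_anova({"A": [1.0], "B": [2.0]})


def _traits_from_weekly(weekly_by_strain, prefix="avg"):
    rows = []
    for strain, values in weekly_by_strain.items():
        for k, v in enumerate(values, start=1):
            tid = f"W{k}avg" if prefix == "avg" else f"W{k}D4"
            rows.append((strain, tid, v, 1))
    return pd.DataFrame(rows, columns=["strain", "trait_id", "value", "n_animals"])


class TestStrainSlopes:
    def test_exact_line(self):
        fits = fit_strain_slopes(_traits_from_weekly({"S1": [1, 2, 3, 4, 5]}))
        row = fits.iloc[0]
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0)  # week-0 convention

    def test_constant_trajectory(self):
        fits = fit_strain_slopes(_traits_from_weekly({"S1": [2.5] * 5}))
        assert fits.iloc[0]["slope"] == pytest.approx(0.0)
        assert fits.iloc[0]["intercept"] == pytest.approx(2.5)

    def test_recovers_published_style_fit(self):
        # a strain escalating 0.329 g/kg per week from a 1.54 baseline
        rng = np.random.default_rng(1)
        weeks = np.arange(1, 6)
        y = 1.54 + 0.329 * weeks + rng.normal(0, 1e-3, 5)
        fits = fit_strain_slopes(_traits_from_weekly({"S1": list(y)}))
        assert fits.iloc[0]["slope"] == pytest.approx(0.329, abs=0.005)
        assert fits.iloc[0]["intercept"] == pytest.approx(1.54, abs=0.01)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        weekly = {f"S{i}": list(rng.normal(2, 1, size=5)) for i in range(20)}
        fits = fit_strain_slopes(_traits_from_weekly(weekly)).set_index("strain")
        x = np.arange(1, 6, dtype=float)
        X = np.column_stack([np.ones(5), x])
        for strain, y in weekly.items():
            beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y))
            assert fits.loc[strain, "intercept"] == pytest.approx(beta[0], abs=1e-10)
            assert fits.loc[strain, "slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_missing_week_skips_strain_with_warning(self):
        traits = _traits_from_weekly({"S1": [1, 2, 3, 4, 5]})
        traits = pd.concat([traits, pd.DataFrame(
            [("S2", "W1avg", 1.0, 1)], columns=traits.columns)])
        with pytest.warns(UserWarning):
            fits = fit_strain_slopes(traits)
        assert list(fits["strain"]) == ["S1"]


class TestSlopeCorrelations:
    def test_published_table_structure(self):
        table = load_published_slope_table()
        assert len(table) == 41
        r = slope_trait_correlation(table, ("slope4h", "intercept4h"))
        assert r < -0.5  # escalators start low: strong negative coupling

    def test_self_correlation_is_one(self):
        table = load_published_slope_table().copy()
        table["slope_4h"] = table["slope_2h"]
        assert slope_trait_correlation(table, ("slope2h", "slope4h")) == pytest.approx(1.0)

    def test_unsupported_pair_and_zero_variance(self):
        table = load_published_slope_table().copy()
        with pytest.raises(KeyError):
            slope_trait_correlation(table, ("slope2h", "intercept4h"))
        table["intercept_2h"] = 1.0
        with pytest.raises(ValueError):
            slope_trait_correlation(table, ("slope2h", "intercept2h"))


class TestWinsorize:
    def test_identity_bounds(self):
        v = np.arange(10.0)
        assert np.array_equal(winsorize(v, 0.0, 1.0), v)

    def test_median_invariant_extremes_clipped(self):
        v = np.arange(1.0, 101.0)
        w = winsorize(v, 0.05, 0.95)
        assert np.median(w) == np.median(v)
        assert w.min() > v.min() and w.max() < v.max()

    def test_outlier_shrinks_variance(self):
        v = np.concatenate([np.random.default_rng(3).normal(0, 1, 50), [40.0]])
        assert winsorize(v, 0.025, 0.975).var() < v.var()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
           st.floats(0.0, 0.4), st.floats(0.6, 1.0))
    def test_bounds_and_length_preserved(self, values, lo, hi):
        v = np.asarray(values)
        w = winsorize(v, lo, hi)
        qlo, qhi = np.quantile(v, [lo, hi])
        assert len(w) == len(v)
        assert w.min() >= qlo - 1e-9 and w.max() <= qhi + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize(np.array([]))


class TestWeekCorrelationMatrix:
    def test_identical_weeks_fully_correlated(self):
        weekly = {f"S{i}": [float(i)] * 5 for i in range(6)}
        m = week_correlation_matrix(_traits_from_weekly(weekly), include_w1d1=False)
        assert np.allclose(m.to_numpy(), 1.0)

    def test_autocorrelated_trajectories_decay_with_lag(self):
        # AR(1) strain trajectories: adjacent weeks beat lag-2 on average
        rng = np.random.default_rng(4)
        rho, n_strains, reps = 0.8, 30, 200
        lag1, lag2 = [], []
        for _ in range(reps):
            x = np.empty((n_strains, 5))
            x[:, 0] = rng.normal(size=n_strains)
            for w in range(1, 5):
                x[:, w] = rho * x[:, w - 1] + np.sqrt(1 - rho ** 2) * rng.normal(size=n_strains)
            c = np.corrcoef(x.T)
            lag1.append(np.mean([c[i, i + 1] for i in range(4)]))
            lag2.append(np.mean([c[i, i + 2] for i in range(3)]))
        assert np.mean(lag1) > np.mean(lag2)

    def test_zero_variance_week_rejected(self):
        weekly = {f"S{i}": [float(i), 1.0, float(i), float(i), float(i)]
                  for i in range(5)}
        with pytest.raises(ValueError):
            week_correlation_matrix(_traits_from_weekly(weekly), include_w1d1=False)
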