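"""Synthetic questionnaire generator: calibration, determinism, recoverability."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.linear_model import LinearRegression

import permwell as pw
from permwell.instruments import score_brs, score_eq5d5l, score_gad7, score_phq9
from permwell.simulate import ORDINAL_ITEMS, write_dataset


class TestSpecValidation:
    def test_default_spec_has_17_predictors(self):
        spec = pw.SyntheticSpec()
        assert spec.n_predictors == 17
        assert spec.predictor_names == pw.PREDICTOR_NAMES

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(prevalences=(1.2,) * 17),
            dict(prevalences=(-0.1,) * 17),
            dict(noise_sd=-1.0),
            dict(effects=(1.0,) * 16),
            dict(n_subjects=0),
            dict(link="cubic"),
            dict(link="nonlinear-interaction"),  # missing interaction triple
            dict(outcome_scale=(5.0, 5.0)),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            pw.SyntheticSpec(**kwargs)

    def test_with_effects_rejects_unknown_predictor(self):
        with pytest.raises(KeyError):
            pw.SyntheticSpec().with_effects({"Astrology": 1.0})


class TestGeneratePredictors:
    def test_empirical_prevalence_within_99pct_binomial_interval(self):
        """Adversity prevalence 0.866 at n=1173 must be statistically consistent."""
        spec = pw.SyntheticSpec(n_subjects=1173, seed=5)
        X = pw.generate_predictors(spec)
        j = pw.PREDICTOR_NAMES.index("Adversity")
        p = spec.prevalences[j]
        count = int(X["Adversity"].sum())
        lo, hi = stats.binom.interval(0.99, 1173, p)
        assert lo <= count <= hi

    def test_zero_prevalence_gives_all_zero_column(self):
        prev = list(pw.DEFAULT_PREVALENCES)
        prev[3] = 0.0
        X = pw.generate_predictors(pw.SyntheticSpec(n_subjects=500, prevalences=prev, seed=2))
        assert (X.iloc[:, 3] == 0).all()

    def test_same_spec_same_seed_bit_identical(self):
        spec = pw.SyntheticSpec(n_subjects=400, seed=9)
        X1 = pw.generate_predictors(spec)
        X2 = pw.generate_predictors(spec)
        pd.testing.assert_frame_equal(X1, X2)

    def test_marginal_calibration_at_large_n(self):
        """Empirical prevalences converge to spec prevalences (n=1e5, tol 0.01)."""
        spec = pw.SyntheticSpec(n_subjects=100_000, seed=3)
        X = pw.generate_predictors(spec)
        empirical = X.mean().to_numpy()
        assert np.abs(empirical - np.asarray(spec.prevalences)).max() < 0.01

    def test_ordinal_flag_emits_five_level_frequency_items(self):
        spec = pw.SyntheticSpec(n_subjects=5000, ordinal=True, seed=4)
        X = pw.generate_predictors(spec)
        for name in ORDINAL_ITEMS:
            assert set(np.unique(X[name])) <= {1, 2, 3, 4, 5}
            # thresholding at >= 4 recovers the dichotomised prevalence
            j = pw.PREDICTOR_NAMES.index(name)
            assert abs((X[name] >= 4).mean() - spec.prevalences[j]) < 0.03
        assert set(np.unique(X["Gender"])) <= {0, 1}


class TestGenerateOutcome:
    def test_no_effects_no_noise_constant_intercept(self):
        spec = pw.SyntheticSpec(n_subjects=50, effects=(0.0,) * 17, intercept=4.2,
                                noise_sd=0.0, outcome_scale=(0.0, 27.0), seed=1)
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        assert np.allclose(y, 4.2)

    def test_noiseless_linear_outcome_exactly_reconstructable(self):
        """With noise_sd=0 the generating equation reproduces y and OLS has MSE 0."""
        effects = (2.0, 1.0) + (0.0,) * 15
        spec = pw.SyntheticSpec(n_subjects=120, effects=effects, intercept=1.0,
                                noise_sd=0.0, outcome_scale=(-100.0, 100.0), seed=8)
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        manual = 1.0 + np.asarray(X, float) @ np.asarray(effects)
        np.testing.assert_allclose(y, manual, atol=0)
        ols = LinearRegression().fit(X, y)
        assert pw.mse(y, ols.predict(X)) < 1e-10

    def test_ols_recovers_planted_effects_to_1e8(self):
        spec = pw.SyntheticSpec(n_subjects=500, noise_sd=0.0,
                                outcome_scale=(-1000.0, 1000.0), seed=6,
                                ).with_effects({"Exercise": 3.0, "Therapy": -1.5})
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        ols = LinearRegression().fit(X, y)
        np.testing.assert_allclose(ols.coef_, spec.effects, atol=1e-8)

    def test_residual_variance_matches_noise_model(self):
        """Monte-Carlo: sample residual variance within 5% of noise_sd**2."""
        spec = pw.SyntheticSpec(n_subjects=10_000, noise_sd=5.0,
                                outcome_scale=(-1000.0, 1000.0), seed=10,
                                ).with_effects({"Gender": 1.0})
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        residuals = y - (spec.intercept + np.asarray(X, float) @ np.asarray(spec.effects))
        assert abs(residuals.var() - 25.0) < 0.05 * 25.0

    def test_clipping_to_outcome_scale_is_recorded(self):
        spec = pw.SyntheticSpec(n_subjects=2000, effects=(0.0,) * 17, intercept=0.0,
                                noise_sd=10.0, outcome_scale=(0.0, 27.0), seed=2)
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        assert y.min() >= 0.0 and y.max() <= 27.0
        assert y.attrs["n_clipped"] > 0

    def test_interaction_link_adds_product_term(self):
        spec = pw.SyntheticSpec(n_subjects=300, effects=(1.0,) + (0.0,) * 16,
                                intercept=0.0, noise_sd=0.0, link="nonlinear-interaction",
                                interaction=(0, 4, 2.5), outcome_scale=(-100.0, 100.0), seed=3)
        X = pw.generate_predictors(spec)
        y = pw.generate_outcome(X, spec)
        arr = np.asarray(X, float)
        np.testing.assert_allclose(y, arr[:, 0] + 2.5 * arr[:, 0] * arr[:, 4], atol=0)

    def test_effects_length_mismatch_raises(self):
        spec = pw.SyntheticSpec(n_subjects=50, seed=1)
        X = pw.generate_predictors(spec).iloc[:, :5]
        with pytest.raises(ValueError, match="columns"):
            pw.generate_outcome(X, spec)


class TestInstrumentItems:
    @pytest.mark.parametrize(
        "total,n_items,rng_bounds,expected",
        [
            (0, 9, (0, 3), np.zeros(9)),
            (27, 9, (0, 3), np.full(9, 3)),
        ],
    )
    def test_forced_compositions(self, total, n_items, rng_bounds, expected):
        items = pw.generate_instrument_items(total, n_items, rng_bounds, seed=0)
        np.testing.assert_array_equal(items, expected)

    def test_infeasible_total_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            pw.generate_instrument_items(28, 9, (0, 3), seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            pw.generate_instrument_items(4, 6, (1, 5), seed=0)

    @pytest.mark.parametrize(
        "scorer,n_items,bounds,totals,to_score",
        [
            (score_phq9, 9, (0, 3), range(0, 28), lambda t: t),
            (score_gad7, 7, (0, 3), range(0, 22), lambda t: t),
            (lambda it: score_brs(it, reverse_items=()), 6, (1, 5), range(6, 31),
             lambda t: t / 6),
            (score_eq5d5l, 5, (1, 5), range(5, 26), lambda t: t),
        ],
    )
    def test_round_trip_with_matching_scorer(self, scorer, n_items, bounds, totals, to_score):
        """Every feasible total survives generate -> score for each instrument."""
        for total in totals:
            items = pw.generate_instrument_items(total, n_items, bounds, seed=total)
            assert scorer(items).total == pytest.approx(to_score(total))

    @given(total=st.integers(0, 21), seed=st.integers(0, 10_000))
    def test_composition_bounds_and_sum(self, total, seed):
        items = pw.generate_instrument_items(total, 7, (0, 3), seed=seed)
        assert items.sum() == total
        assert ((items >= 0) & (items <= 3)).all()


def test_write_dataset_round_trips_with_sidecar(tmp_path, small_spec):
    df = pw.generate_dataset(small_spec)
    path = write_dataset(df, tmp_path / "survey.csv", small_spec)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, df, check_exact=False, atol=1e-12)
    sidecar = json.loads((tmp_path / "survey.csv.spec.json").read_text())
    assert pw.SyntheticSpec.from_dict(sidecar) == small_spec


def test_generate_survey_has_all_outcomes_in_scale():
    df = pw.generate_survey(300, seed=1)
    assert list(df.columns[:17]) == list(pw.PREDICTOR_NAMES)
    for outcome, (lo, hi) in pw.OUTCOME_SCALES.items():
        assert df[outcome].between(lo, hi).all()
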