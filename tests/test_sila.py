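"""SILA core: rate sampling, field smoothing, Euler integration, alignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from amychron import (
    RateField,
    SILAModel,
    simulate_amyloid_trajectory,
    TrajectoryCurve,
    compute_rate_samples,
    estimate_chronicity,
    estimate_cohort_chronicity,
    fit_rate_field,
    integrate_trajectory,
)
from amychron.errors import DegenerateCurveError, InputError, ModelFitError

CUTOFF = 13.3


def _amyloid_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age", "modality", "abl"])


def constant_field(rate, lo=0.1, hi=200.0):
    grid = np.array([lo, hi])
    return RateField(grid, np.full(2, rate), np.zeros(2), np.ones(2, int))


def logistic_field(rho=0.1, K=100.0):
    grid = np.arange(0.01, 110.0, 0.05)
    return RateField(grid, rho * grid * (1 - grid / K),
                     np.zeros_like(grid), np.ones_like(grid, int))


def logistic_exact(t, rho=0.1, K=100.0, a0=CUTOFF):
    return K / (1 + ((K - a0) / a0) * np.exp(-rho * np.asarray(t)))


class TestRateSamples:
    def test_adjacent_pair_finite_difference(self, two_scan_subject):
        s = compute_rate_samples(two_scan_subject)
        assert len(s) == 1
        assert s.burden.iloc[0] == pytest.approx(12.0)
        assert s.rate.iloc[0] == pytest.approx(2.0)

    def test_single_scan_cohort_raises(self):
        table = _amyloid_table(
            [["a", 40.0, "amyloid", 10.0], ["b", 50.0, "amyloid", 20.0]]
        )
        with pytest.raises(ModelFitError):
            compute_rate_samples(table)

    def test_linear_trajectory_gives_identical_rates(self):
        table = _amyloid_table(
            [["a", 40.0, "amyloid", 10.0], ["a", 42.0, "amyloid", 14.0],
             ["a", 44.0, "amyloid", 18.0]]
        )
        s = compute_rate_samples(table)
        assert len(s) == 2
        assert s.rate.iloc[0] == pytest.approx(s.rate.iloc[1])

    def test_ols_strategy_single_sample_per_subject(self):
        table = _amyloid_table(
            [["a", 40.0, "amyloid", 10.0], ["a", 42.0, "amyloid", 14.0],
             ["a", 44.0, "amyloid", 18.0]]
        )
        s = compute_rate_samples(table, strategy="ols")
        assert len(s) == 1
        assert s.rate.iloc[0] == pytest.approx(2.0)
        assert s.weight.iloc[0] == 3

    def test_non_increasing_ages_rejected(self):
        table = _amyloid_table(
            [["a", 42.0, "amyloid", 10.0], ["a", 42.0, "amyloid", 14.0]]
        )
        with pytest.raises(InputError):
            compute_rate_samples(table)


class TestRateFieldFit:
    def test_constant_rate_everywhere(self):
        samples = pd.DataFrame(
            {"subject_id": list("abcd"), "burden": [5.0, 10.0, 15.0, 20.0],
             "rate": [1.5] * 4, "weight": [2] * 4}
        )
        field = fit_rate_field(samples, grid=np.arange(5.0, 21.0, 1.0))
        covered = field.n_per_window > 0
        assert np.allclose(field.mean_rate, 1.5)
        assert np.allclose(field.sd_rate[covered], 0.0)

    def test_empty_window_linear_interpolation(self):
        samples = pd.DataFrame(
            {"subject_id": ["a", "b"], "burden": [10.0, 30.0],
             "rate": [1.0, 3.0], "weight": [2, 2]}
        )
        field = fit_rate_field(samples, grid=[10.0, 20.0, 30.0], window=5.0)
        assert field.n_per_window[1] == 0
        assert field.mean_rate[1] == pytest.approx(2.0)

    def test_floor_clips_negative_smoothed_rates(self):
        samples = pd.DataFrame(
            {"subject_id": ["a"], "burden": [10.0], "rate": [-0.5], "weight": [2]}
        )
        field = fit_rate_field(samples, grid=[8.0, 10.0, 12.0], rate_floor=0.01)
        assert np.all(field.mean_rate >= 0.01)

    def test_all_windows_empty_raises(self):
        samples = pd.DataFrame(
            {"subject_id": ["a"], "burden": [100.0], "rate": [1.0], "weight": [2]}
        )
        with pytest.raises(ModelFitError):
            fit_rate_field(samples, grid=[0.0, 1.0], window=5.0)

    def test_noise_free_cohort_recovers_generating_rate_law(self, noise_free_cohort):
        cfg, df = noise_free_cohort
        field = fit_rate_field(compute_rate_samples(df))
        true_rate = cfg.rate_law(field.grid_burden)
        well = field.n_per_window >= 10
        assert well.sum() > 10
        assert np.max(np.abs(field.mean_rate[well] - true_rate[well])) < 0.1


class TestIntegration:
    def test_constant_rate_closed_form(self):
        curve = integrate_trajectory(constant_field(2.0))
        assert np.allclose(curve.burden, CUTOFF + 2.0 * curve.chronicity, atol=1e-9)

    def test_forward_span_is_fifty_years(self):
        curve = integrate_trajectory(constant_field(1.0), step=0.25, max_iter=200)
        assert curve.chronicity[-1] == pytest.approx(50.0)

    def test_anchor_at_chronicity_zero(self):
        curve = integrate_trajectory(constant_field(0.7))
        assert curve.burden_at(0.0) == pytest.approx(CUTOFF, abs=1e-9)

    def test_burden_strictly_increasing(self):
        curve = integrate_trajectory(logistic_field())
        assert np.all(np.diff(curve.burden) > 0)

    def test_logistic_oracle_deviation(self):
        """Forward-Euler error against the closed-form logistic solution.

        At the 0.25-yr production step the maximum deviation is ≈0.24 Aβ_L
        (frozen from a fine-step reference run); the method is first order, so
        halving the step roughly halves the error.
        """
        errs = {}
        for step in (0.25, 0.125):
            curve = integrate_trajectory(
                logistic_field(), step=step, max_iter=int(round(50 / step))
            )
            errs[step] = np.max(np.abs(curve.burden - logistic_exact(curve.chronicity)))
        assert errs[0.25] == pytest.approx(0.2422, abs=0.01)
        assert errs[0.125] < errs[0.25]
        assert errs[0.125] == pytest.approx(errs[0.25] / 2, rel=0.15)

    def test_degenerate_field_raises(self):
        grid = np.array([1.0, 200.0])
        field = RateField(grid, np.array([-1.0, -1.0]), np.zeros(2), np.ones(2, int))
        with pytest.raises(DegenerateCurveError):
            integrate_trajectory(field)

    def test_backward_stops_at_zero_burden(self):
        curve = integrate_trajectory(constant_field(2.0), max_iter=200)
        assert np.all(curve.burden > 0)

    def test_curve_must_pass_through_anchor(self):
        with pytest.raises(InputError):
            TrajectoryCurve(chronicity=[0.0, 1.0], burden=[20.0, 21.0])


class TestChronicityAssignment:
    @pytest.fixture()
    def unit_curve(self):
        """curve(t) = 13.3 + t (constant unit rate)."""
        return integrate_trajectory(constant_field(1.0))

    def test_single_scan_at_cutoff(self, unit_curve):
        visits = _amyloid_table([["a", 45.0, "amyloid", CUTOFF]])
        est = estimate_chronicity(visits, unit_curve)
        assert est.chronicity_at_reference == pytest.approx(0.0, abs=1e-9)
        assert est.estimated_onset_age == pytest.approx(45.0)
        assert est.method == "inverted_single_scan"

    def test_single_scan_subtraction_rule(self, unit_curve):
        visits = _amyloid_table([["a", 45.0, "amyloid", CUTOFF + 5.0]])
        est = estimate_chronicity(visits, unit_curve)
        assert est.chronicity_at_reference == pytest.approx(5.0)
        assert est.estimated_onset_age == pytest.approx(40.0)

    def test_multi_scan_aligned_at_first_apositive(self, unit_curve):
        visits = _amyloid_table(
            [["a", 40.0, "amyloid", 10.0], ["a", 43.0, "amyloid", CUTOFF + 2.0],
             ["a", 46.0, "amyloid", CUTOFF + 9.0]]
        )
        est = estimate_chronicity(visits, unit_curve)
        assert est.method == "aligned_first_apositive"
        assert est.reference_age == pytest.approx(43.0)
        assert est.chronicity_at_reference == pytest.approx(2.0)
        assert est.estimated_onset_age == pytest.approx(41.0)

    def test_multi_scan_never_positive_uses_most_recent(self, unit_curve):
        visits = _amyloid_table(
            [["a", 40.0, "amyloid", 8.0], ["a", 43.0, "amyloid", 9.5]]
        )
        est = estimate_chronicity(visits, unit_curve)
        assert est.method == "aligned_most_recent_subthreshold"
        assert est.reference_age == pytest.approx(43.0)
        assert est.chronicity_at_reference < 0

    def test_below_range_truncated(self, unit_curve):
        low = unit_curve.burden[0] - 5.0
        visits = _amyloid_table([["a", 40.0, "amyloid", low]])
        est = estimate_chronicity(visits, unit_curve)
        assert est.truncated
        assert est.method == "truncated_below_range"
        assert est.chronicity_at_reference == pytest.approx(unit_curve.chronicity[0])

    def test_above_range_truncated(self, unit_curve):
        visits = _amyloid_table([["a", 80.0, "amyloid", unit_curve.burden[-1] + 10]])
        est = estimate_chronicity(visits, unit_curve)
        assert est.truncated
        assert est.chronicity_at_reference == pytest.approx(unit_curve.chronicity[-1])

    def test_no_amyloid_scan_raises(self, unit_curve):
        visits = pd.DataFrame(
            {"subject_id": ["a"], "age": [40.0], "modality": ["tau"], "abl": [np.nan]}
        )
        with pytest.raises(InputError):
            estimate_chronicity(visits, unit_curve)


class TestCohortEstimation:
    def test_noise_free_recovery_within_one_year(self, noise_free_fit):
        """With noise off, every non-truncated onset estimate lands within
        a year of the generator's ground truth."""
        _, df, est, _ = noise_free_fit
        truth = df.drop_duplicates("subject_id").set_index("subject_id")
        merged = est.set_index("subject_id").join(truth["true_onset_age"])
        ok = ~merged.truncated
        err = (merged.onset_age - merged.true_onset_age)[ok].abs()
        assert err.max() < 1.0
        assert err.median() < 0.25

    def test_noise_free_post_onset_subject_within_half_year(self, noise_free_fit):
        """A noise-free subject with true onset 42 and two post-onset scans,
        placed on the cohort-fitted curve, recovers its onset within 0.5 yr."""
        cfg, _, _, curve = noise_free_fit
        ages = [44.0, 47.0]
        latent = simulate_amyloid_trajectory(cfg, 42.0, ages)
        visits = _amyloid_table(
            [["x", a, "amyloid", b] for a, b in zip(ages, latent)]
        )
        est = estimate_chronicity(visits, curve)
        assert est.method == "aligned_first_apositive"
        assert abs(est.estimated_onset_age - 42.0) < 0.5

    def test_noise_free_aligned_subjects_mostly_within_half_year(self, noise_free_fit):
        _, df, est, _ = noise_free_fit
        truth = df.drop_duplicates("subject_id").set_index("subject_id")
        merged = est.set_index("subject_id").join(truth["true_onset_age"])
        sel = merged.method == "aligned_first_apositive"
        err = (merged.onset_age - merged.true_onset_age)[sel].abs()
        assert sel.sum() > 10
        assert err.median() < 0.1
        assert err.quantile(0.9) < 0.5

    def test_row_permutation_invariance(self, noise_free_cohort):
        _, df = noise_free_cohort
        est1, curve1 = estimate_cohort_chronicity(df)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        est2, curve2 = estimate_cohort_chronicity(shuffled)
        pd.testing.assert_frame_equal(est1, est2)
        np.testing.assert_allclose(curve1.burden, curve2.burden)

    def test_all_subthreshold_cohort(self):
        rows = []
        for i, b0 in enumerate([4.0, 6.0, 8.0]):
            rows += [[f"s{i}", 40.0, "amyloid", b0],
                     [f"s{i}", 43.0, "amyloid", b0 + 1.5]]
        visits = _amyloid_table(rows)
        est, _ = estimate_cohort_chronicity(visits)
        assert (est.chronicity <= 0).all()
        assert est.method.isin(
            ["aligned_most_recent_subthreshold", "truncated_below_range"]
        ).all()

    def test_rigid_alignment_offsets(self, noise_free_fit):
        """Chronicity at any other scan is the reference chronicity plus the
        exact age offset, so within-subject chronicity gaps equal age gaps."""
        _, df, est, curve = noise_free_fit
        row = est[est.method == "aligned_first_apositive"].iloc[0]
        scans = df[(df.subject_id == row.subject_id) & (df.modality == "amyloid")]
        chron = row.chronicity + (scans.age - row.reference_age)
        assert np.allclose(np.diff(chron), np.diff(scans.age))


class TestSILAModelEstimator:
    def test_fit_predict_shapes(self, noise_free_cohort):
        _, df = noise_free_cohort
        model = SILAModel().fit(df)
        assert model.n_subjects_ == 177
        pred = model.predict(df)
        assert pred.shape == (177,)
        assert np.all(np.isfinite(pred))

    def test_matches_functional_interface(self, noise_free_fit):
        _, df, est, curve = noise_free_fit
        model = SILAModel().fit(df)
        pd.testing.assert_frame_equal(model.estimate(df), est)
        np.testing.assert_allclose(model.curve_.burden, curve.burden)

    def test_sklearn_param_protocol(self):
        model = SILAModel(window=4.0)
        assert model.get_params()["window"] == 4.0
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        model.set_params(step=0.5)
        assert model.step == 0.5

    def test_predict_before_fit_raises(self, noise_free_cohort):
        _, df = noise_free_cohort
        with pytest.raises(ModelFitError):
            SILAModel().predict(df)
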