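"""Split plans, metric bookkeeping, and reduced-scale Monte-Carlo protocols."""

import numpy as np
import pytest

from caseus import (
    SeasonEffects,
    StudyDesign,
    generate_dataset,
    make_classification_split,
    percent_correct,
    r_squared,
    rmse,
    run_classification_validation,
    run_imputation_validation,
)
from caseus.validation import (
    MetricCurve,
    SplitPlan,
    ValidationError,
    draw_external_pool,
    make_imputation_holdout,
)


def _month_counts(pm, ids):
    label = dict(zip(pm.sample_ids, pm.labels))
    out = {"January": 0, "April": 0, "June": 0}
    for s in ids:
        out[label[s]] += 1
    return out


class TestMetrics:
    def test_percent_correct_all_right(self):
        assert percent_correct(["a", "b"], ["a", "b"]) == 100.0

    def test_rmse_hand_value(self):
        assert rmse([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_r_squared_of_zero_residuals_is_one(self):
        assert r_squared([0.0, 0.0], [1.0, -2.0]) == 1.0

    def test_mean_prediction_r_squared_is_zero(self):
        """Predicting the calibration mean makes the residuals equal the
        totals, pinning R^2 at 0 by definition."""
        totals = np.array([1.5, -0.3, 2.0, -2.2])
        assert r_squared(totals, totals) == pytest.approx(0.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rmse([])
        with pytest.raises(ValidationError):
            percent_correct([], [])


class TestSplitPlan:
    def test_default_design_reproduces_study_table_counts(self, default_dataset):
        """Default 45-sample design: calibration (10,2),(10,2),(8,4) and
        validation (2,1),(2,1),(1,2) complete/partial cells per month."""
        plan = make_classification_split(default_dataset, seed=4)
        assert _month_counts(default_dataset, plan.calibration_complete) == {
            "January": 10, "April": 10, "June": 8}
        assert _month_counts(default_dataset, plan.calibration_partial) == {
            "January": 2, "April": 2, "June": 4}
        assert _month_counts(default_dataset, plan.validation_complete) == {
            "January": 2, "April": 2, "June": 1}
        assert _month_counts(default_dataset, plan.validation_partial_external) == {
            "January": 1, "April": 1, "June": 2}

    def test_partial_fractions_within_protocol_bands_over_many_seeds(self, default_dataset):
        """Across a seed sweep the calibration partial share stays in
        [15%, 35%] and the validation partial share in [30%, 65%]."""
        for seed in range(300):
            plan = make_classification_split(default_dataset, seed=seed)
            cal_frac = len(plan.calibration_partial) / len(plan.calibration_ids)
            val_frac = len(plan.validation_partial_external) / len(plan.validation_ids)
            assert 0.15 <= cal_frac <= 0.35
            assert 0.30 <= val_frac <= 0.65

    def test_no_partial_samples_degenerates_to_plain_cv(self):
        pm = generate_dataset(StudyDesign(partial_counts=(0, 0, 0)), seed=3)
        plan = make_classification_split(pm, seed=1)
        assert plan.calibration_partial == []
        assert plan.validation_partial_external == []
        assert len(plan.calibration_complete) + len(plan.validation_complete) == 33

    def test_month_with_too_few_complete_samples_errors(self):
        pm = generate_dataset(
            StudyDesign(complete_counts=(1, 12, 9), partial_counts=(0, 3, 6)), seed=3
        )
        with pytest.raises(ValidationError, match="January"):
            make_classification_split(pm, seed=0)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            SplitPlan(["a"], ["a"], [], [])

    def test_external_pool_disjoint_from_all_calibration_sets(self, default_dataset):
        """The external partial pool never enters calibration, whatever the
        iteration seed."""
        ext = draw_external_pool(default_dataset, seed=99)
        for it in range(50):
            plan = make_classification_split(
                default_dataset, np.random.default_rng([7, it]), external_ids=ext
            )
            assert not set(ext) & set(plan.calibration_ids)
            assert sorted(ext) == plan.validation_partial_external

    def test_imputation_holdout_is_20_percent_per_month(self, default_dataset):
        held = make_imputation_holdout(default_dataset, seed=0)
        assert _month_counts(default_dataset, held) == {
            "January": 2, "April": 2, "June": 2}


class TestMetricCurve:
    def test_mean_is_rowwise_average_and_selection_argmax(self):
        per_it = np.array([[50.0, 60.0], [90.0, 80.0], [85.0, 85.0]])
        c = MetricCurve("%CC", [1, 2, 3], per_it)
        assert np.array_equal(c.mean_metric, [55.0, 85.0, 85.0])
        assert c.selected_order == 2  # tie broken toward the smaller order
        c2 = MetricCurve("RMSECV", [1, 2], [[1.0], [2.0]], higher_is_better=False)
        assert c2.selected_order == 1

    def test_dict_roundtrip(self):
        c = MetricCurve("R2", [1, 2], [[1.0, 2.0], [3.0, 4.0]])
        back = MetricCurve.from_dict(c.to_dict())
        assert np.array_equal(back.per_iteration, c.per_iteration)
        assert back.metric_name == "R2"


@pytest.fixture(scope="module")
def small_fast():
    design = StudyDesign(
        complete_counts=(6, 6, 5), partial_counts=(2, 2, 2), n_fame=10, n_minerals=8
    )
    return generate_dataset(design, SeasonEffects(latent_rank=3), seed=2)


class TestClassificationProtocol:
    def test_same_seed_reproduces_identical_curves(self, small_fast):
        kwargs = dict(orders=[2, 3], n_iterations=4, seed=11)
        a = run_classification_validation(small_fast, "ppca_lda", **kwargs)
        b = run_classification_validation(small_fast, "ppca_lda", **kwargs)
        assert np.array_equal(a.per_iteration, b.per_iteration)
        assert a.extras["external_ids"] == b.extras["external_ids"]

    def test_separable_limit_classifies_perfectly(self):
        design = StudyDesign(
            complete_counts=(6, 6, 5), partial_counts=(2, 2, 2), n_fame=10, n_minerals=8
        )
        effects = SeasonEffects(latent_rank=3, class_separation=25.0, noise_sd=0.05)
        pm = generate_dataset(design, effects, seed=4)
        curve = run_classification_validation(
            pm, "ppca_lda", orders=[2, 3], n_iterations=5, seed=0
        )
        assert np.all(curve.per_iteration == 100.0)

    def test_ppca_lda_beats_minerals_only_plsda_on_defaults(self, default_dataset):
        """The fatty-acid block carries most class signal, so feeding partial
        FAME information through PPCA outperforms the minerals-only PLS-DA."""
        kwargs = dict(orders=[2, 5], n_iterations=8, seed=0)
        ppca_curve = run_classification_validation(default_dataset, "ppca_lda", **kwargs)
        plsda_curve = run_classification_validation(default_dataset, "plsda", **kwargs)
        assert ppca_curve.best_mean >= plsda_curve.best_mean

    def test_plsda_order_bounded_by_mineral_count(self, small_fast):
        with pytest.raises(ValidationError, match="mineral"):
            run_classification_validation(small_fast, "plsda", orders=[9], n_iterations=2)

    def test_em_diagnostics_recorded(self, small_fast):
        curve = run_classification_validation(
            small_fast, "ppca_lda", orders=[2], n_iterations=3, seed=5
        )
        assert curve.extras["n_ppca_fits"] == 3
        assert curve.extras["min_ll_increment_normalized"] >= -1e-8


class TestImputationProtocol:
    def test_noiseless_rank_q_imputation_near_perfect(self):
        """With essentially no noise and order = true rank, conditioning on
        the mineral block recovers the held-out FAME block exactly."""
        design = StudyDesign(
            complete_counts=(6, 6, 5), partial_counts=(2, 2, 2), n_fame=10, n_minerals=8
        )
        effects = SeasonEffects(latent_rank=3, noise_sd=1e-6)
        pm = generate_dataset(design, effects, seed=6)
        out = run_imputation_validation(pm, "ppca", orders=[3], n_iterations=5, seed=0)
        assert out["r2"].mean_metric[0] > 99.9

    def test_true_order_beats_order_one_on_average(self, small_fast):
        out = run_imputation_validation(
            small_fast, "ppca", orders=[1, 3], n_iterations=10, seed=1
        )
        curve = out["rmsecv"]
        assert curve.mean_metric[1] <= curve.mean_metric[0]
        assert curve.extras["rmsecv_pooled"][1] <= curve.extras["rmsecv_pooled"][0]

    def test_plsr_route_runs_and_reports_both_scales(self, small_fast):
        out = run_imputation_validation(
            small_fast, "plsr", orders=[2, 4], n_iterations=3, seed=2
        )
        assert out["rmsecv"].extras["rmsecv_original_scale_mean"].shape == (2,)
        assert out["r2"].per_iteration.shape == (2, 3)

    def test_same_seed_reproducible(self, small_fast):
        a = run_imputation_validation(small_fast, "ppca", orders=[2], n_iterations=3, seed=9)
        b = run_imputation_validation(small_fast, "ppca", orders=[2], n_iterations=3, seed=9)
        assert np.array_equal(a["r2"].per_iteration, b["r2"].per_iteration)
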