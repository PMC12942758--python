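import math

import numpy as np
import pytest

from mirselect.modeling_eval import (
    STAGE1_FIXED_PARAMS, STAGE2_GRIDS, STAGE3_RANGES, _stage2_candidates,
    evaluate, make_folds, overfit_gap, percent_improvement,
    sample_stage3_spec, stage1_compare, stage2_light_tune, stage3_fine_tune,
    williams_category,
)
from mirselect.partition import spxy_split
from mirselect.synthetic_mir import SimConfig, simulate_dataset
from mirselect.variable_selection import SelectionResult


class TestMakeFolds:
    def test_152_samples_give_31_31_30_30_30(self):
        plan = make_folds(152, 5, seed=0)
        assert sorted((len(f) for f in plan.folds), reverse=True) == [31, 31, 30, 30, 30]

    def test_same_seed_reproduces_plan(self):
        assert make_folds(40, 5, 3) == make_folds(40, 5, 3)

    def test_leave_one_out(self):
        plan = make_folds(7, 7, 0)
        assert all(len(f) == 1 for f in plan.folds)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, 5, 0)


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.rpd_infinite

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        rep = evaluate(y, np.full(4, y.mean()))
        assert rep.r2 == pytest.approx(0.0)

    def test_rpd_one_when_rmse_equals_reference_sd(self):
        y = np.array([1.0, 2.0, 3.0])
        sd = np.std(y, ddof=1)
        rep = evaluate(y, y + sd * np.array([1.0, -1.0, 1.0]) * math.sqrt(2 / 3)
                       / math.sqrt(2 / 3))
        # rmse of a ±sd perturbation is exactly sd
        assert rep.rmse == pytest.approx(sd)
        assert rep.rpd == pytest.approx(1.0)

    def test_against_brute_force_formulas(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y = rng.normal(size=n)
            if np.ptp(y) == 0:
                continue
            y_hat = y + rng.normal(size=n)
            rep = evaluate(y, y_hat)
            r2 = 1 - sum((a - b) ** 2 for a, b in zip(y, y_hat)) / sum(
                (a - np.mean(y)) ** 2 for a in y)
            rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / n)
            sd = math.sqrt(sum((a - np.mean(y)) ** 2 for a in y) / (n - 1))
            assert rep.r2 == pytest.approx(r2, abs=1e-10)
            assert rep.rmse == pytest.approx(rmse, abs=1e-10)
            assert rep.rpd == pytest.approx(sd / rmse, abs=1e-10)
            # RPD × RMSE recovers the reference standard deviation identically
            assert rep.rpd * rep.rmse == pytest.approx(rep.sd_ref, abs=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(5), np.zeros(5))


class TestWilliamsCategories:
    @pytest.mark.parametrize("rpd,label", [
        (1.2, "unreliable"),
        (1.5, "rough screening"),
        (2.0, "approximate quantification"),
        (2.5, "good prediction"),
        (2.999, "good prediction"),
        (3.0, "excellent prediction"),
        (3.4674, "excellent prediction"),
    ])
    def test_band_boundaries(self, rpd, label):
        assert williams_category(rpd) == label

    def test_negative_rpd_rejected(self):
        with pytest.raises(ValueError):
            williams_category(-0.1)


class TestDerivedStatistics:
    def test_percent_improvement_examples(self):
        assert percent_improvement(0.9097, 0.7823) == 16.3
        assert percent_improvement(3.3270, 2.1431) == 55.2
        assert percent_improvement(1.7, 1.7) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_improvement(1.0, 0.0)

    def test_overfit_gap(self):
        assert overfit_gap(0.9633, 0.9168) == 0.0465
        assert overfit_gap(0.9, 0.9) == 0.0
        assert overfit_gap(0.8, 0.9) == -overfit_gap(0.9, 0.8)


@pytest.fixture(scope="module")
def split_sim(small_sim):
    ds, truth = small_sim
    split = spxy_split(ds, 0.8)
    return (ds.subset(split.calibration_ids), ds.subset(split.prediction_ids),
            truth)


class TestStage1:
    def test_frozen_booster_params_on_every_row(self, split_sim):
        cal, test, truth = split_sim
        p = cal.X.shape[1]
        rng = np.random.default_rng(0)
        pool = [
            SelectionResult(truth.informative_mask, "oracle"),
            SelectionResult(np.ones(p, dtype=bool), "full"),
            SelectionResult(rng.random(p) < 0.2, "random20"),
        ]
        rows = stage1_compare(pool, cal, test, seed=0)
        assert len(rows) == 3
        for row in rows:
            assert row.booster_params == dict(STAGE1_FIXED_PARAMS)
        r2s = [r.test_report.r2 for r in rows]
        assert r2s == sorted(r2s, reverse=True)

    def test_oracle_mask_wins_on_clean_data(self, clean_sim):
        ds, truth = clean_sim
        split = spxy_split(ds, 0.8)
        cal, test = ds.subset(split.calibration_ids), ds.subset(split.prediction_ids)
        p = cal.X.shape[1]
        rng = np.random.default_rng(1)
        noise_mask = ~truth.informative_mask
        pool = [
            SelectionResult(truth.informative_mask, "oracle"),
            SelectionResult(noise_mask, "complement"),
            SelectionResult(rng.random(p) < 0.1, "random10"),
        ]
        rows = stage1_compare(pool, cal, test, seed=0)
        # noise-free band tails outside the planted mask still carry signal,
        # so competitors can approach the oracle; it must not be beaten by
        # more than booster fitting noise
        by_label = {r.label: r.test_report.r2 for r in rows}
        assert by_label["oracle"] >= max(by_label.values()) - 0.02

    def test_empty_selection_reported_not_raised(self, split_sim):
        cal, test, _ = split_sim
        p = cal.X.shape[1]
        pool = [SelectionResult(np.zeros(p, dtype=bool), "empty"),
                SelectionResult(np.ones(p, dtype=bool), "full")]
        rows = stage1_compare(pool, cal, test, seed=0)
        empty_row = next(r for r in rows if r.label == "empty")
        assert empty_row.test_report is None
        assert empty_row.note == "empty selection"


class TestStage2:
    def test_pls_grid_has_eleven_component_counts(self):
        specs = _stage2_candidates("pls", n_cal=152, p_sel=984, seed=0)
        assert [s.params["n_components"] for s in specs] == list(range(5, 16))

    def test_rfr_grid_has_twelve_candidates(self):
        specs = _stage2_candidates("rfr", n_cal=152, p_sel=984, seed=0)
        assert len(specs) == 12

    def test_svr_grid_is_three_by_three(self):
        assert len(_stage2_candidates("svr_rbf", 152, 984, 0)) == 9

    def test_all_families_fit_and_report(self, split_sim):
        cal, test, truth = split_sim
        folds = make_folds(cal.n_samples, 5, 0)
        rows = stage2_light_tune(truth.informative_mask, cal, test, folds,
                                 seed=0)
        assert [r.family for r in rows] == ["pls", "rfr", "svr_rbf", "gbt"]
        for row in rows:
            assert row.error is None
            assert row.cv_report.tag == "cv"
            assert row.test_report.tag == "test"
            grid = STAGE2_GRIDS[row.family]
            for key, values in grid.items():
                assert row.spec.params[key] in values


class TestStage3:
    def test_sampled_specs_stay_inside_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            spec = sample_stage3_spec(rng, seed=0)
            for key, (lo, hi) in STAGE3_RANGES.items():
                assert lo <= spec.params[key] <= hi

    def test_test_set_evaluated_exactly_once(self, split_sim):
        cal, test, truth = split_sim
        folds = make_folds(cal.n_samples, 5, 0)
        result = stage3_fine_tune(truth.informative_mask, cal, test, folds,
                                  budget=3, seed=0)
        assert result.n_test_evaluations == 1
        assert result.n_specs_tried == 3
        assert result.rmsecv == min(r for _, r in result.search_trace)

    def test_zero_budget_rejected(self, split_sim):
        cal, test, truth = split_sim
        folds = make_folds(cal.n_samples, 5, 0)
        with pytest.raises(ValueError):
            stage3_fine_tune(truth.informative_mask, cal, test, folds,
                             budget=0)

    def test_fine_tuning_does_not_hurt_cv_score(self):
        # median over replicate datasets: the stage-3 CV optimum is at least
        # as good as the stage-2 booster grid optimum
        diffs = []
        for seed in range(5):
            ds, truth = simulate_dataset(SimConfig(n=50, p=60, seed=seed))
            split = spxy_split(ds, 0.8)
            cal = ds.subset(split.calibration_ids)
            test = ds.subset(split.prediction_ids)
            folds = make_folds(cal.n_samples, 5, seed)
            s2 = stage2_light_tune(truth.informative_mask, cal, test, folds,
                                   seed=seed, families=("gbt",))
            s3 = stage3_fine_tune(truth.informative_mask, cal, test, folds,
                                  budget=8, seed=seed)
            diffs.append(s2[0].cv_report.rmse - s3.rmsecv)
        assert np.median(diffs) >= 0
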