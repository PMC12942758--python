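import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirselect.modeling_eval import make_folds
from mirselect.variable_selection import (
    ImportanceProfile, StrategyPoolConfig, build_strategy_pool, cars,
    cars_retention_ratio, intersect, pls_vip, reduction_percent,
    rfr_importance, select_by_threshold, select_top_fraction,
)


def _linear_data(n, p, n_informative, noise, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:n_informative] = 1.0
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


class TestPlsVip:
    @pytest.mark.parametrize("n,p,A", [(40, 25, 3), (60, 100, 5), (30, 10, 2)])
    def test_sum_of_squared_vip_equals_p(self, n, p, A):
        X, y = _linear_data(n, p, 5, 0.3, seed=n + p)
        prof = pls_vip(X, y, A)
        assert np.sum(prof.scores**2) == pytest.approx(p, abs=1e-6)

    def test_identical_columns_all_score_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        X = np.tile(col[:, None], (1, 8))
        y = col + rng.normal(0, 0.01, 50)
        prof = pls_vip(X, y, 1)
        np.testing.assert_allclose(prof.scores, 1.0, atol=1e-8)

    def test_single_component_matches_direct_formula(self):
        # for one latent variable the weight vector is the normalized X'y
        # cross-covariance, so VIP_j = sqrt(p)·|w_j| can be computed directly
        X, y = _linear_data(200, 100, 1, 0.5, seed=3)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        expected = np.sqrt(100) * np.abs(w)
        prof = pls_vip(X, y, 1)
        np.testing.assert_allclose(prof.scores, expected, atol=1e-8)
        assert prof.scores.argmax() == 0
        assert prof.scores[0] > 1.0

    def test_zero_variance_target_rejected(self):
        X = np.random.default_rng(1).normal(size=(20, 5))
        with pytest.raises(ValueError):
            pls_vip(X, np.ones(20), 2)


class TestRfrImportance:
    def test_scores_normalized(self):
        X, y = _linear_data(60, 15, 3, 0.2, seed=5)
        prof = rfr_importance(X, y, {"n_estimators": 100}, seed=0)
        assert prof.scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_never_split(self):
        X, y = _linear_data(60, 10, 3, 0.2, seed=6)
        X[:, 7] = 4.2
        prof = rfr_importance(X, y, {"n_estimators": 100}, seed=0)
        assert prof.scores[7] == 0.0

    def test_dominant_signal_variable_ranks_first(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 20))
            y = X[:, 7] + rng.normal(0, 0.1, 120)
            prof = rfr_importance(X, y, {"n_estimators": 200}, seed=seed)
            wins += int(prof.scores.argmax() == 7)
        assert wins >= 19

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rfr_importance(np.zeros((1, 3)), np.zeros(1))


class TestStrategyAlgebra:
    @pytest.fixture
    def profile(self):
        rng = np.random.default_rng(8)
        return ImportanceProfile(rng.uniform(0, 2, 300), "vip")

    def test_threshold_zero_selects_all(self, profile):
        assert select_by_threshold(profile, 0.0).cardinality == 300

    def test_threshold_above_max_is_empty_but_legal(self, profile):
        sel = select_by_threshold(profile, profile.scores.max() + 1)
        assert sel.is_empty

    def test_threshold_matches_linear_scan(self, profile):
        for tau in (0.3, 1.0, 1.7):
            sel = select_by_threshold(profile, tau)
            assert sel.cardinality == int(sum(s >= tau for s in profile.scores))

    @pytest.mark.parametrize("p,q,expected", [
        (7468, 0.30, 2240),
        (7468, 0.10, 746),
        (10, 0.25, 2),
    ])
    def test_top_fraction_cardinality(self, p, q, expected):
        prof = ImportanceProfile(np.random.default_rng(p).uniform(size=p),
                                 "gini")
        assert select_top_fraction(prof, q).cardinality == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=st.integers(5, 400), q=st.floats(0.01, 1.0),
           seed=st.integers(0, 10**6))
    def test_top_fraction_against_sort_oracle(self, p, q, seed):
        scores = np.random.default_rng(seed).uniform(size=p).round(2)  # ties
        prof = ImportanceProfile(scores, "gini")
        k = int(np.floor(q * p))
        if k == 0:
            with pytest.raises(ValueError):
                select_top_fraction(prof, q)
            return
        sel = select_top_fraction(prof, q)
        assert sel.cardinality == k
        if 0 < k < p:
            assert scores[sel.mask].min() >= scores[~sel.mask].max()

    def test_top_fraction_ties_break_to_lower_index(self):
        prof = ImportanceProfile(np.array([0.5, 0.9, 0.5, 0.5]), "gini")
        sel = select_top_fraction(prof, 0.5)
        np.testing.assert_array_equal(sel.indices, [0, 1])

    def test_intersection_laws(self, profile):
        a = select_by_threshold(profile, 0.8)
        b = select_top_fraction(profile, 0.3)
        ab, ba = intersect(a, b), intersect(b, a)
        np.testing.assert_array_equal(ab.mask, ba.mask)
        np.testing.assert_array_equal(intersect(a, a).mask, a.mask)
        assert ab.cardinality <= min(a.cardinality, b.cardinality)

    def test_intersection_p_mismatch_rejected(self, profile):
        other = ImportanceProfile(np.ones(10), "gini")
        with pytest.raises(ValueError):
            intersect(select_by_threshold(profile, 1.0),
                      select_top_fraction(other, 0.5))


class TestReductionPercent:
    @pytest.mark.parametrize("total,selected,expected", [
        (7468, 984, 86.8),
        (100, 25, 75.0),
        (50, 50, 0.0),
    ])
    def test_values(self, total, selected, expected):
        assert reduction_percent(total, selected) == expected

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            reduction_percent(10, 11)
        with pytest.raises(ValueError):
            reduction_percent(0, 0)


@pytest.fixture(scope="module")
def pool(small_sim):
    ds, _ = small_sim
    cfg = StrategyPoolConfig(cars_iterations=10, cars_mc_runs=3,
                             vip_max_components=8)
    return build_strategy_pool(ds.X, ds.y, cfg)


class TestStrategyPool:
    def test_six_labeled_strategies(self, pool):
        strategies, _ = pool
        assert [s.label for s in strategies] == [
            "VIP1.0∩RFR30%", "RFR-top10%", "VIP-1.2∩RFR-20%",
            "PLS-VIP-1.2", "PLS-VIP-0.8", "CARS",
        ]

    def test_vip_threshold_monotonicity(self, pool):
        strategies, profiles = pool
        vip = profiles["vip"]
        n08 = select_by_threshold(vip, 0.8).cardinality
        n10 = select_by_threshold(vip, 1.0).cardinality
        n12 = select_by_threshold(vip, 1.2).cardinality
        assert n08 >= n10 >= n12

    def test_strict_hybrid_nested_in_balanced(self, pool):
        strategies, _ = pool
        by_label = {s.label: s for s in strategies}
        strict = by_label["VIP-1.2∩RFR-20%"].mask
        balanced = by_label["VIP1.0∩RFR30%"].mask
        assert not np.any(strict & ~balanced)


@pytest.fixture(scope="module")
def cars_run(small_sim):
    ds, _ = small_sim
    folds = make_folds(ds.n_samples, 5, 0)
    return cars(ds.X, ds.y, n_iterations=12, n_mc_runs=4, folds=folds,
                seed=11)


class TestCars:
    @pytest.mark.parametrize("p,N", [(100, 10), (7468, 50), (500, 18)])
    def test_retention_ratio_endpoints(self, p, N):
        assert cars_retention_ratio(1, p, N) == pytest.approx(1.0)
        assert cars_retention_ratio(N, p, N) == pytest.approx(2 / p)

    def test_retained_counts_non_increasing(self, cars_run):
        trace, _ = cars_run
        counts = [it.retained_count for it in trace.iterations]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_chosen_iteration_minimizes_rmsecv(self, cars_run):
        trace, sel = cars_run
        rmse = [it.rmsecv for it in trace.iterations]
        best = trace.iterations[trace.chosen_iteration - 1]
        assert best.rmsecv == min(rmse)
        assert sel.cardinality == best.retained_count

    def test_seeded_determinism(self, small_sim):
        ds, _ = small_sim
        folds = make_folds(ds.n_samples, 5, 0)
        kw = dict(n_iterations=8, n_mc_runs=3, folds=folds, seed=21)
        t1, s1 = cars(ds.X, ds.y, **kw)
        t2, s2 = cars(ds.X, ds.y, **kw)
        assert t1 == t2
        np.testing.assert_array_equal(s1.mask, s2.mask)

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 1))
        with pytest.raises(ValueError):
            cars(X, np.arange(20.0), n_iterations=5)
        with pytest.raises(ValueError):
            cars(np.random.default_rng(0).normal(size=(20, 5)),
                 np.arange(20.0), n_iterations=1)
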