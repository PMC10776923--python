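"""Stability selection: score, calibration, subsampling, reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stabsel import (
    DesignMatrix,
    StabilitySelection,
    calibrate,
    default_pi_grid,
    lasso_path,
    make_lambda_grid,
    reproducibility_runs,
    run_subsampling,
    stability_score,
    stable_features,
)
from stabsel.preprocess import assemble_design, median_normalise, transform_and_centre
from stabsel.stability import SelectionResult

from oracles import binomial_score_oracle


def _design_from(sc):
    proteins = transform_and_centre(median_normalise(sc.proteins))
    return assemble_design(sc.cohort, proteins, "age_sex", sc.cohort["status"])


class TestStabilityScore:
    def test_two_subsample_worked_example(self):
        # K=2, q/p=0.5, pi=0.75: low = {0}, high = {2}, mid = {1} with null
        # probabilities 0.25, 0.5, 0.25. A count of 2 contributes -ln .25,
        # a count of 0 contributes -ln .25, each count of 1 contributes
        # -ln .5. (q is integer here so the round-q convention is inert.)
        counts = np.array([2, 0, 1, 1])
        score = stability_score(counts, K=2, q=2.0, pi=0.75)
        expected = -(math.log(0.25) + math.log(0.25) + 2 * math.log(0.5))
        assert score == pytest.approx(expected, abs=1e-12)
        base = -(math.log(0.25) + math.log(0.25) + math.log(0.5))
        assert base == pytest.approx(3.4657, abs=5e-5)
        assert score == pytest.approx(base + math.log(2.0), abs=1e-12)

    def test_null_concordant_counts_score_near_zero(self):
        # every count at the binomial mode with a wide mid band: the observed
        # pattern is almost certain under the null, so the score is ~0
        K, p = 100, 40
        counts = np.full(p, 50)
        score = stability_score(counts, K=K, q=p / 2, pi=0.99)
        assert 0.0 < score < 0.1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exact_rational_oracle(self, data):
        K = data.draw(st.integers(3, 120))
        p = data.draw(st.integers(3, 30))
        q = data.draw(st.floats(0.51, p - 0.51))
        pi = data.draw(st.sampled_from(list(np.arange(51, 100) / 100)))
        counts = np.array(data.draw(
            st.lists(st.integers(0, K), min_size=p, max_size=p)))
        ours = stability_score(counts, K=K, q=q, pi=pi)
        oracle = binomial_score_oracle(counts, K, q, pi)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_domain_validation(self):
        counts = np.array([1, 2, 3])
        with pytest.raises(ValueError, match="pi"):
            stability_score(counts, K=5, q=1.0, pi=0.5)
        with pytest.raises(ValueError, match="q"):
            stability_score(counts, K=5, q=0.0, pi=0.7)
        with pytest.raises(ValueError, match="q"):
            stability_score(counts, K=5, q=3.0, pi=0.7)
        with pytest.raises(ValueError, match="counts"):
            stability_score(np.array([9, 0, 0]), K=5, q=1.0, pi=0.7)


def _manual_result(counts, q, K=50, lambdas=None):
    counts = np.asarray(counts)
    L, p = counts.shape
    lambdas = np.geomspace(1.0, 0.01, L) if lambdas is None else lambdas
    return SelectionResult(
        lambdas=lambdas, K=K, fraction=0.5,
        feature_names=[f"f{j}" for j in range(p)],
        counts=counts, q=np.asarray(q, dtype=float), seed=0,
    )


class TestCalibrate:
    def test_bimodal_column_wins(self):
        K, p = 50, 12
        rng = np.random.default_rng(0)
        diffuse = rng.integers(10, 40, size=(3, p))
        bimodal = np.concatenate([np.full(3, K), np.zeros(p - 3, dtype=int)])
        counts = np.vstack([diffuse[0], bimodal, diffuse[1], diffuse[2]])
        q = np.array([25.0, 3.0, 25.0, 25.0])
        res = _manual_result(counts, q, K=K, lambdas=np.geomspace(1, 0.01, 4))
        lam_star, pi_star, surface = calibrate(res)
        assert res.lambda_star_idx == 1
        assert stable_features(res) == ["f0", "f1", "f2"]

    def test_single_lambda_reduces_to_pi_search(self):
        counts = np.array([[50, 50, 0, 0, 1, 2]])
        res = _manual_result(counts, [2.1], K=50, lambdas=np.array([0.3]))
        lam_star, pi_star, surface = calibrate(res)
        assert lam_star == 0.3
        assert surface.shape == (1, len(default_pi_grid()))
        # tie policy: the largest pi among maximisers
        best_pi = default_pi_grid()[np.flatnonzero(surface[0] == surface[0].max()).max()]
        assert pi_star == best_pi

    def test_pi_star_always_above_half(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 51, size=(5, 20))
        res = _manual_result(counts, counts.mean(axis=1) * 20 / 50)
        calibrate(res)
        assert res.pi_star > 0.5

    def test_degenerate_q_rows_excluded(self):
        counts = np.vstack([np.zeros(6, dtype=int), [30, 2, 1, 0, 0, 0]])
        res = _manual_result(counts, [0.0, 1.2], K=50, lambdas=np.array([1.0, 0.5]))
        calibrate(res)
        assert res.lambda_star == 0.5  # q=0 row cannot be calibrated

    def test_all_degenerate_rejected(self):
        counts = np.zeros((2, 4), dtype=int)
        res = _manual_result(counts, [0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(res)


class TestStableFeatures:
    def test_threshold_and_ordering(self):
        counts = np.array([[99, 70, 30]])
        res = _manual_result(counts, [1.99], K=100, lambdas=np.array([0.2]))
        res.pi_grid = default_pi_grid()
        res.lambda_star_idx, res.pi_star_idx = 0, 15
        res.lambda_star, res.pi_star = 0.2, 0.66
        assert stable_features(res) == ["f0", "f1"]

    def test_unreachable_threshold_gives_empty_list(self):
        counts = np.array([[80, 70, 30]])
        res = _manual_result(counts, [1.8], K=100, lambdas=np.array([0.2]))
        res.lambda_star_idx, res.pi_star_idx = 0, 0
        res.lambda_star, res.pi_star = 0.2, 1.0
        assert stable_features(res) == []

    def test_ties_broken_by_name(self):
        counts = np.array([[90, 90, 90]])
        res = _manual_result(counts, [2.7], K=100, lambdas=np.array([0.2]))
        res.lambda_star_idx, res.pi_star_idx = 0, 0
        res.lambda_star, res.pi_star = 0.2, 0.6
        assert stable_features(res) == ["f0", "f1", "f2"]


class TestRunSubsampling:
    def test_degenerate_single_full_subsample_equals_full_fit(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        res = run_subsampling(design, K=1, fraction=1.0, seed=0)
        grid = make_lambda_grid(design.X, design.y, design.penalty_factors)
        coefs, _ = lasso_path(design.X, design.y, grid, design.penalty_factors)
        full_support = (coefs[:, design.penalised] != 0).astype(int)
        assert set(np.unique(res.counts)) <= {0, 1}
        np.testing.assert_array_equal(res.counts, full_support)

    def test_same_seed_is_reproducible(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        a = run_subsampling(design, K=8, seed=42)
        b = run_subsampling(design, K=8, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.q, b.q)

    def test_forced_covariates_absent_from_counts(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        res = run_subsampling(design, K=4, seed=0)
        assert res.counts.shape[1] == int(design.penalised.sum())
        assert set(res.feature_names) == set(design.penalised_names)

    def test_q_non_increasing_in_lambda(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        res = run_subsampling(design, K=25, seed=1)
        # lambdas decrease along the grid, so q should (noisily) increase
        assert np.all(np.diff(res.q) > -0.5)
        assert res.q[-1] > res.q[0]

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = np.zeros(40, dtype=int)
        y[:3] = 1
        design = DesignMatrix(X, [f"x{j}" for j in range(6)], np.ones(6), y,
                              pd.RangeIndex(40))
        with pytest.raises(ValueError, match="larger"):
            run_subsampling(design, K=2, fraction=0.5, seed=0)


class TestEstimator:
    def test_recovers_strong_causal_proteins(self, small_signal_cohort):
        _, sc = small_signal_cohort
        proteins = transform_and_centre(median_normalise(sc.proteins))
        X = pd.concat(
            [sc.cohort[["age"]],
             proteins.data], axis=1,
        )
        pf = np.ones(X.shape[1])
        pf[0] = 0.0
        model = StabilitySelection(n_subsamples=60, penalty_factors=pf,
                                   random_state=0)
        model.fit(X, sc.cohort["status"].to_numpy())
        stable = set(model.stable_features_)
        assert len(stable & set(sc.true_support)) >= 3
        # forced covariate is reported with proportion exactly 1 and always kept
        assert model.selection_proportions_["age"] == 1.0
        assert model.stable_mask_[0]
        assert model.transform(X).shape[1] == int(model.stable_mask_.sum())

    def test_sklearn_contract(self):
        from sklearn.base import clone

        model = StabilitySelection(n_subsamples=12, random_state=3)
        params = model.get_params()
        assert params["n_subsamples"] == 12
        clone(model)  # must be cloneable from constructor params

    def test_results_deterministic_under_random_state(self, small_signal_cohort):
        _, sc = small_signal_cohort
        proteins = transform_and_centre(median_normalise(sc.proteins))
        X = proteins.data.iloc[:, :30]
        y = sc.cohort["status"].to_numpy()
        a = StabilitySelection(n_subsamples=10, random_state=7).fit(X, y)
        b = StabilitySelection(n_subsamples=10, random_state=7).fit(X, y)
        assert a.lambda_star_ == b.lambda_star_
        assert a.pi_star_ == b.pi_star_
        assert a.stable_features_ == b.stable_features_


class TestReproducibilityRuns:
    def test_zero_runs_rejected(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        with pytest.raises(ValueError, match="B"):
            reproducibility_runs(design, B=0)

    def test_identical_seeds_give_identical_runs(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        rep = reproducibility_runs(design, B=2, K=12, seeds=[123, 123])
        assert rep.stable_sets[0] == rep.stable_sets[1]
        pd.testing.assert_series_equal(rep.proportions.iloc[0],
                                       rep.proportions.iloc[1],
                                       check_names=False)

    def test_causal_proteins_more_frequently_stable(self, small_signal_cohort):
        _, sc = small_signal_cohort
        design = _design_from(sc)
        rep = reproducibility_runs(design, B=5, K=40, seed=1)
        causal = rep.frequency[sc.true_support]
        noise = rep.frequency.drop(sc.true_support)
        assert causal.median() > noise.median()
        assert causal.mean() > noise.mean() + 0.2
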