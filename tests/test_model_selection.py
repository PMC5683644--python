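"""OLS machinery, VIF, the constrained subset search and the full pipeline."""

import numpy as np
import pytest

import dictreg as dr
from dictreg import (
    Hyperparams,
    ScreenedDictionary,
    SingularFitError,
    baseline_best_subset,
    best_subset,
    fit_ols,
    run_parameter_selection,
    vif,
)
from conftest import brute_force_best_subset, random_candidate_set


class TestFitOls:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 40)
        y = 3.0 - 2.0 * x
        m = fit_ols(x[:, None], y)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(m.residuals)) < 1e-10
        assert m.intercept == pytest.approx(3.0)
        assert m.coefficients[0] == pytest.approx(-2.0)

    def test_orthogonal_response_gives_zero_slope(self):
        n = 50
        x = np.arange(n, dtype=float)
        y = np.ones(n)
        y[::2] = -1.0
        y -= y.mean()
        xc = x - x.mean()
        y -= (y @ xc) / (xc @ xc) * xc  # exactly orthogonal to x
        m = fit_ols(x[:, None], y)
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_normal_equations_oracle(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 3.0], [5.0, 9.0]])
        y = np.array([2.0, 1.0, 7.0, 4.0, 12.0])
        A = np.column_stack([np.ones(5), X])
        beta = np.linalg.inv(A.T @ A) @ (A.T @ y)
        m = fit_ols(X, y)
        np.testing.assert_allclose(
            np.r_[m.intercept, m.coefficients], beta, rtol=0, atol=1e-10
        )
        resid = y - A @ beta
        assert m.rmse == pytest.approx(float(np.sqrt(resid @ resid / 2)), abs=1e-10)

    def test_residuals_sum_to_zero_and_r2_ordering(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=60)
        m = fit_ols(X, y)
        assert abs(m.residuals.mean()) < 1e-10
        assert m.r2_adj <= m.r2 <= 1.0
        np.testing.assert_allclose(m.fitted + m.residuals, y, atol=1e-10)

    def test_rank_deficient_design_raises(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularFitError):
            fit_ols(X, x + 1)


class TestVif:
    def test_orthogonal_columns_are_unity(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(200, 3))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        np.testing.assert_allclose(vif(Q), np.ones(3), atol=1e-10)

    @pytest.mark.parametrize("r", [0.5, 0.9, 0.95])
    def test_closed_form_for_two_columns(self, r):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(100, 2))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        cols = np.column_stack([Q[:, 0], r * Q[:, 0] + np.sqrt(1 - r**2) * Q[:, 1]])
        np.testing.assert_allclose(vif(cols), np.full(2, 1.0 / (1.0 - r**2)), rtol=1e-8)

    def test_r_squared_09_hits_the_limit(self):
        # pairwise r^2 = 0.9 between two columns corresponds to VIF = 10,
        # the conventional multicollinearity ceiling.
        r = np.sqrt(0.9)
        rng = np.random.default_rng(4)
        A = rng.normal(size=(300, 2))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        cols = np.column_stack([Q[:, 0], r * Q[:, 0] + np.sqrt(1 - r**2) * Q[:, 1]])
        np.testing.assert_allclose(vif(cols), np.full(2, 10.0), rtol=1e-8)

    def test_collinear_columns_give_infinity(self):
        x = np.linspace(1, 2, 50)
        out = vif(np.column_stack([x, 3 * x]))
        assert np.all(np.isinf(out))

    def test_single_column_is_one(self):
        assert vif(np.arange(10.0)[:, None]) == pytest.approx([1.0])


class TestBestSubset:
    def test_single_candidate_selected(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=80)
        y = 2 + 3 * z + rng.normal(size=80)
        cand = ScreenedDictionary.from_columns(["z"], z[:, None], y)
        res = best_subset(cand, y)
        assert res.best.term_names == ("z",)
        assert res.n_subsets_evaluated == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        names, cols, y = random_candidate_set(seed)
        cand = ScreenedDictionary.from_columns(names, cols, y)
        res = best_subset(cand, y, vif_limit=10.0, k_max=8)
        oracle = brute_force_best_subset(names, cols, y, vif_limit=10.0, k_max=8)
        assert set(res.best.term_names) == set(oracle[2])
        assert res.best.r2_adj == pytest.approx(oracle[0], abs=1e-12)

    def test_parsimony_tie_break(self):
        # y depends on one column; a duplicate pair must not both enter.
        rng = np.random.default_rng(6)
        z = rng.normal(size=100)
        w = rng.normal(size=100)
        y = z.copy()
        cand = ScreenedDictionary.from_columns(["w", "z"], np.column_stack([w, z]), y)
        res = best_subset(cand, y)
        assert res.best.term_names == ("z",)

    def test_empty_candidates_rejected(self):
        cand = ScreenedDictionary.from_columns([], np.empty((20, 0)))
        with pytest.raises(dr.NoFeasibleModelError):
            best_subset(cand, np.arange(20.0))


class TestRunParameterSelection:
    def test_noise_response_returns_a_model_without_crashing(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(1, 10, size=(200, 3))
        y = rng.normal(size=200)
        m = run_parameter_selection(X, y)
        assert np.isfinite(m.r2_adj)
        assert m.r2_adj < 0.2
        assert np.max(m.vif) <= 10.0

    def test_provenance_counts_are_consistent(self, example1_model):
        prov = example1_model.provenance
        assert prov.n_terms_dictionary >= prov.n_after_delta >= prov.n_after_redundancy
        assert prov.n_after_redundancy >= len(example1_model.terms)
        delta_drops = sum(1 for d in prov.dropped if d.stage == "delta")
        assert prov.n_terms_dictionary - delta_drops == prov.n_after_delta

    def test_noise_robust_selection_of_true_interaction(self):
        # Additive N(0,1) noise is tiny against a response spanning ~8e5:
        # the selected term set should be stable across replicates.
        hits = 0
        for rep in range(100):
            X, y = dr.gen_example1(n=1000, seed=50_000 + rep, noise_sd=1.0)
            m = run_parameter_selection(X, y, Hyperparams(sigma=0.5))
            hits += m.term_names == ("x1*x3",)
        assert hits >= 95

    def test_explicit_delta_too_high_raises(self, example1):
        X, y = example1
        with pytest.raises(dr.NoFeasibleModelError):
            run_parameter_selection(X, y, Hyperparams(delta=1.0, sigma=0.5))


class TestBaseline:
    def test_linear_truth_recovered_exactly(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 10, size=(100, 3))
        y = 1.5 + 2.0 * X[:, 0]
        m = baseline_best_subset(X, y)
        assert m.term_names == ("x1",)
        assert m.r2_adj == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_three_columns_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, 0.0, -2.0]) + rng.normal(size=80)
        m = baseline_best_subset(X, y, variable_names=["a", "b", "c"])
        oracle = brute_force_best_subset(["a", "b", "c"], X, y)
        assert set(m.term_names) == set(oracle[2])
        assert m.r2_adj == pytest.approx(oracle[0], abs=1e-12)


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0},
            {"M": 0},
            {"delta": 1.2},
            {"sigma": 0.0},
            {"sigma": 1.5},
            {"vif_limit": 1.0},
            {"k_max": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(dr.ConfigError):
            Hyperparams(**kwargs)
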