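"""Shapley oracle, kernel-regression estimator and the LIME surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_predictor
from explainstab import (
    ExplainerConfig,
    exact_shapley,
    explain_cohort,
    kernel_shap_explain,
    lime_explain,
    shapley_kernel_weight,
)


class TestShapleyKernelWeight:
    def test_closed_forms(self):
        assert shapley_kernel_weight(4, 2) == pytest.approx(3 / (6 * 2 * 2))
        assert shapley_kernel_weight(3, 1) == pytest.approx(1 / 3)
        assert shapley_kernel_weight(3, 2) == pytest.approx(1 / 3)

    def test_boundary_sizes_are_constraints(self):
        with pytest.raises(ValueError, match="constraint"):
            shapley_kernel_weight(5, 0)
        with pytest.raises(ValueError, match="constraint"):
            shapley_kernel_weight(5, 5)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(2, 80), st.data())
    def test_symmetry(self, P, data):
        s = data.draw(st.integers(1, P - 1))
        assert shapley_kernel_weight(P, s) == pytest.approx(
            shapley_kernel_weight(P, P - s), rel=1e-12
        )


class TestExactShapley:
    def test_linear_predictor_closed_form(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=6)
        f = lambda X: np.atleast_2d(X) @ w + 3.0
        x = rng.normal(size=6)
        bg = rng.normal(size=(10, 6))
        phi = exact_shapley(f, x, bg)
        np.testing.assert_allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-10)

    def test_dummy_axiom(self):
        f = lambda X: np.atleast_2d(X)[:, 0] * 2.0  # never reads features 1, 2
        phi = exact_shapley(f, np.array([1.0, 5.0, -3.0]), np.zeros((4, 3)))
        assert phi[1] == pytest.approx(0.0, abs=1e-12)
        assert phi[2] == pytest.approx(0.0, abs=1e-12)
        assert phi[0] == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_axiom(self):
        f = lambda X: np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
        x = np.array([2.0, 2.0, 1.0])
        bg = np.tile([0.5, 0.5, 0.0], (3, 1))
        phi = exact_shapley(f, x, bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_refuses_large_p(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        with pytest.raises(ValueError, match="infeasible"):
            exact_shapley(f, np.zeros(15), np.zeros((2, 15)))


class TestKernelShap:
    @pytest.mark.parametrize("P,seed", [(4, 0), (6, 1), (8, 2)])
    def test_full_enumeration_matches_oracle(self, P, seed):
        f = random_predictor(P, seed)
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=P)
        bg = rng.normal(size=(6, P))
        phi_oracle = exact_shapley(f, x, bg)
        cfg = ExplainerConfig(n_samples=2**P, seed=0)
        res = kernel_shap_explain(f, x, bg, cfg)
        assert np.max(np.abs(res.phi - phi_oracle)) < 1e-6

    def test_local_accuracy(self):
        f = random_predictor(5, 7)
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        bg = rng.normal(size=(8, 5))
        res = kernel_shap_explain(f, x, bg, ExplainerConfig(n_samples=64))
        fx = float(f(x[None, :])[0])
        assert res.base_value + res.phi.sum() == pytest.approx(fx, abs=1e-6)

    def test_constant_predictor_gives_zero_attributions(self):
        f = lambda X: np.full(len(np.atleast_2d(X)), 7.5)
        res = kernel_shap_explain(
            f, np.ones(4), np.zeros((3, 4)), ExplainerConfig(n_samples=16)
        )
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-10)
        assert res.base_value == pytest.approx(7.5)

    def test_sampled_coalitions_keep_local_accuracy(self):
        # P = 12 with a budget far below 2^12 - 2 exercises the paired
        # sampling path; the efficiency constraint is built into the solver
        f = random_predictor(12, 4)
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        bg = rng.normal(size=(5, 12))
        res = kernel_shap_explain(f, x, bg, ExplainerConfig(n_samples=300, seed=5))
        fx = float(f(x[None, :])[0])
        assert np.isfinite(res.phi).all()
        assert res.base_value + res.phi.sum() == pytest.approx(fx, abs=1e-8)
        # and the sampled estimate still tracks the exact values
        phi_oracle = exact_shapley(f, x, bg)
        r = np.corrcoef(res.phi, phi_oracle)[0, 1]
        assert r > 0.8

    def test_rejects_undersized_sample_budget(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        with pytest.raises(ValueError, match="n_samples"):
            kernel_shap_explain(f, np.zeros(8), np.zeros((2, 8)),
                                ExplainerConfig(n_samples=6))

    @settings(derandomize=True, max_examples=8, deadline=None)
    @given(st.integers(4, 7), st.integers(0, 1000))
    def test_oracle_equivalence_property(self, P, seed):
        f = random_predictor(P, seed)
        rng = np.random.default_rng(seed + 1)
        x = rng.normal(size=P)
        bg = rng.normal(size=(4, P))
        res = kernel_shap_explain(f, x, bg, ExplainerConfig(n_samples=2**P, seed=0))
        assert np.max(np.abs(res.phi - exact_shapley(f, x, bg))) < 1e-6


class TestLime:
    def test_linear_recovery(self):
        rng = np.random.default_rng(0)
        P = 10
        w = rng.normal(size=P)
        f = lambda X: np.atleast_2d(X) @ w + 4.0
        x = rng.normal(size=P)
        stats = (rng.normal(size=P), rng.uniform(0.5, 2.0, size=P))
        cfg = ExplainerConfig(method="lime", n_samples=10_000, seed=1)
        res = lime_explain(f, x, stats, cfg)
        assert np.corrcoef(res.phi, w)[0, 1] > 0.99

    def test_constant_predictor_gives_zero_coefficients(self):
        f = lambda X: np.full(len(np.atleast_2d(X)), 2.0)
        res = lime_explain(
            f, np.zeros(5), (np.zeros(5), np.ones(5)),
            ExplainerConfig(method="lime", n_samples=500, seed=0),
        )
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-8)

    def test_seeding_contract(self):
        f = random_predictor(6, 11)
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        stats = (np.zeros(6), np.ones(6))
        cfg = ExplainerConfig(method="lime", n_samples=400, seed=21)
        a = lime_explain(f, x, stats, cfg).phi
        b = lime_explain(f, x, stats, cfg).phi
        c = lime_explain(f, x, stats,
                         ExplainerConfig(method="lime", n_samples=400, seed=22)).phi
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_zero_variance_feature_held_fixed(self):
        rng = np.random.default_rng(5)
        w = np.array([2.0, -1.0, 3.0])
        f = lambda X: np.atleast_2d(X) @ w
        sds = np.array([1.0, 0.0, 1.0])  # feature 1 constant in training
        res = lime_explain(f, np.ones(3), (np.zeros(3), sds),
                           ExplainerConfig(method="lime", n_samples=2000, seed=2))
        assert res.phi[1] == 0.0
        assert res.phi[0] == pytest.approx(2.0, rel=0.05)

    def test_top_k_sparsity(self):
        rng = np.random.default_rng(6)
        w = np.array([5.0, 0.01, -4.0, 0.02, 3.0])
        f = lambda X: np.atleast_2d(X) @ w
        res = lime_explain(
            f, np.zeros(5), (np.zeros(5), np.ones(5)),
            ExplainerConfig(method="lime", n_samples=4000, seed=3, top_k_features=3),
        )
        assert np.count_nonzero(res.phi) == 3
        assert set(np.flatnonzero(res.phi)) == {0, 2, 4}

    def test_gradient_consistency_on_smooth_model(self):
        # shrinking width + many samples: coefficients align with the local
        # gradient of a smooth nonlinear predictor
        a = np.array([1.0, -2.0, 0.5, 1.5])
        f = lambda X: np.tanh(np.atleast_2d(X) @ a)
        x = np.array([0.3, 0.1, -0.2, 0.4])
        grad = (1 - np.tanh(x @ a) ** 2) * a
        res = lime_explain(
            f, x, (np.zeros(4), np.ones(4)),
            ExplainerConfig(method="lime", n_samples=30_000, seed=7,
                            kernel_width=0.3, regularization=1e-4),
        )
        cos = res.phi @ grad / (np.linalg.norm(res.phi) * np.linalg.norm(grad))
        assert cos > 0.95


class TestExplainCohort:
    def test_bookkeeping_and_fold_isolation(self, tiny_loso_run):
        cohort, plan, report, registry = tiny_loso_run
        cfgs = {
            "shap_kernel": ExplainerConfig(n_samples=64, background_size=10, seed=0),
            "lime": ExplainerConfig(method="lime", n_samples=300, seed=0),
        }
        stacks = explain_cohort(registry, cohort, cfgs, n_rounds=plan.n_rounds)
        for method in cfgs:
            assert len(stacks[method]) == cohort.n_subjects
            for s in stacks[method].values():
                assert s.scores.shape == (plan.n_rounds, cohort.n_features)
                assert np.isfinite(s.scores).all()

    def test_identical_models_give_identical_rows(self, tiny_cohort):
        from explainstab import ResamplingPlan, loso_splits, train_regressor
        from conftest import tiny_model_config

        cohort, _ = tiny_cohort
        splits = loso_splits(cohort)
        registry = {"folds": splits}
        for f, (tr, te, site) in enumerate(splits):
            sub = tr[: int(0.8 * len(tr))]
            model = train_regressor(
                cohort.features[sub], cohort.age[sub], tiny_model_config(seed=1, max_epochs=30)
            )
            for n in range(2):  # same model, same subsample in both rounds
                registry[(f, n)] = {"model": model, "train_indices": sub}
        cfgs = {
            "shap_kernel": ExplainerConfig(n_samples=2**8, background_size=10, seed=0),
            "lime": ExplainerConfig(method="lime", n_samples=200, seed=0),
        }
        stacks = explain_cohort(registry, cohort, cfgs, n_rounds=2)
        for method in cfgs:
            for s in stacks[method].values():
                np.testing.assert_array_equal(s.scores[0], s.scores[1])

    def test_missing_round_model_raises(self, tiny_loso_run):
        cohort, plan, report, registry = tiny_loso_run
        broken = {k: v for k, v in registry.items() if k != (0, 1)}
        with pytest.raises(KeyError, match="fold 0 round 1"):
            explain_cohort(
                broken, cohort,
                {"shap_kernel": ExplainerConfig(n_samples=64, background_size=5)},
                n_rounds=plan.n_rounds,
            )
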