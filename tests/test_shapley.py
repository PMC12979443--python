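"""Shapley attribution tests: the game-theoretic axioms as executable checks.

Exact enumeration must satisfy efficiency to machine precision and the
dummy/symmetry axioms; permutation sampling must agree with exact values
within its own Monte-Carlo error and converge at the 1/sqrt(n) rate.
"""

import numpy as np
import pandas as pd
import pytest

from cafrisk.learners import train
from cafrisk.shapley import (
    dependence_data,
    explanation_views,
    global_importance,
    shapley_values,
)


def additive(X):
    return X[:, 0] + X[:, 1]


def product(X):
    return X[:, 0] * X[:, 1]


class TestExactMode:
    def test_additive_model_recovers_terms(self):
        # zero background: v(S) picks out exactly the included terms
        attr = shapley_values(additive, np.array([[2.0, 5.0]]), np.zeros((1, 2)), mode="exact")
        assert attr.base_value == pytest.approx(0.0)
        assert attr.contributions == pytest.approx([2.0, 5.0], abs=1e-12)

    def test_constant_predictor_all_zero(self, rng):
        attr = shapley_values(
            lambda X: np.full(len(X), 0.7), rng.normal(size=(1, 4)),
            rng.normal(size=(20, 4)), mode="exact",
        )
        assert attr.base_value == pytest.approx(0.7)
        assert attr.contributions == pytest.approx(np.zeros(4), abs=1e-12)

    def test_symmetry_axiom(self):
        bg = np.array([[1.0, 1.0], [-1.0, -1.0], [0.5, 0.5]])
        attr = shapley_values(product, np.array([[3.0, 3.0]]), bg, mode="exact")
        assert attr.contributions[0] == pytest.approx(attr.contributions[1], abs=1e-12)

    def test_dummy_axiom(self, rng):
        bg = rng.normal(size=(15, 3))
        attr = shapley_values(
            lambda X: np.sin(X[:, 0]) + X[:, 1] ** 2, rng.normal(size=(1, 3)),
            bg, mode="exact",
        )
        assert attr.contributions[2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("d", [1, 3, 5, 8])
    def test_efficiency_on_fitted_model(self, rng, d):
        X = rng.normal(size=(60, d))
        y = (X.sum(axis=1) + 0.3 * rng.normal(size=60) > 0).astype(int)
        pred = train("lr", {"penalty": "l2", "C": 1.0, "max_iter": 200}, X, y, seed=0)
        row = X[:1]
        attr = shapley_values(pred, row, X[:25], mode="exact")
        assert attr.base_value + attr.contributions.sum() == pytest.approx(
            attr.prediction, abs=1e-9
        )
        assert attr.prediction == pytest.approx(float(pred.score(row)[0]), abs=1e-9)

    def test_dimension_limit_enforced(self, rng):
        with pytest.raises(ValueError, match="exact"):
            shapley_values(additive, rng.normal(size=(1, 13)), rng.normal(size=(5, 13)),
                           mode="exact")

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            shapley_values(additive, np.ones((1, 2)), np.empty((0, 2)))


class TestSampledMode:
    def test_agrees_with_exact_within_monte_carlo_error(self, rng):
        def model(X):
            return X[:, 0] * X[:, 1] + np.tanh(X[:, 2]) - 0.5 * X[:, 3] + X[:, 4] ** 2

        row = rng.normal(size=(1, 5))
        bg = rng.normal(size=(12, 5))
        exact = shapley_values(model, row, bg, mode="exact")
        sampled = shapley_values(model, row, bg, mode="sampled", n_perm=1024, seed=0)
        tol = 3.0 * np.maximum(sampled.mc_se, 1e-12)
        assert np.all(np.abs(sampled.contributions - exact.contributions) <= tol)
        # efficiency also holds in sampled mode (telescoping permutation sums)
        assert sampled.base_value + sampled.contributions.sum() == pytest.approx(
            sampled.prediction, abs=1e-9
        )

    def test_mc_se_shrinks_as_inverse_sqrt(self, rng):
        def model(X):
            return X[:, 0] * X[:, 1] - X[:, 2] * X[:, 3]

        row = rng.normal(size=(1, 4))
        bg = rng.normal(size=(10, 4))
        se = {
            n: shapley_values(model, row, bg, mode="sampled", n_perm=n, seed=1).mc_se.mean()
            for n in (64, 256, 1024)
        }
        assert se[256] == pytest.approx(se[64] / 2, rel=0.5)
        assert se[1024] == pytest.approx(se[256] / 2, rel=0.5)

    def test_seeded_reproducibility(self, rng):
        row = rng.normal(size=(1, 3))
        bg = rng.normal(size=(8, 3))
        a = shapley_values(additive, row[:, :2], bg[:, :2], mode="sampled", n_perm=32, seed=5)
        b = shapley_values(additive, row[:, :2], bg[:, :2], mode="sampled", n_perm=32, seed=5)
        assert np.array_equal(a.contributions, b.contributions)


class TestAggregationAndViews:
    def _toy_attributions(self):
        df_bg = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, -1.0], "c": [0.0, 0.0]})
        rows = pd.DataFrame({"a": [1.0, 2.0, -1.0], "b": [0.5, -0.5, 1.5], "c": [9.0, 9.0, 9.0]})

        def model(X):
            return 2.0 * X[:, 0] - X[:, 1]

        return [
            shapley_values(model, rows.iloc[[i]], df_bg, mode="exact") for i in range(3)
        ]

    def test_global_importance_hand_computed(self):
        attrs = self._toy_attributions()
        imp = global_importance(attrs)
        phis = np.stack([a.contributions for a in attrs])
        expected = np.abs(phis).mean(axis=0)
        assert imp.mean_abs["a"] == pytest.approx(expected[0])
        assert imp.mean_abs["b"] == pytest.approx(expected[1])
        assert imp.ranking[-1] == "c"  # ignored feature ranks last
        # doubling one feature's contributions doubles its score
        for a in attrs:
            a.contributions[1] *= 2
        imp2 = global_importance(attrs)
        assert imp2.mean_abs["b"] == pytest.approx(2 * imp.mean_abs["b"])

    def test_waterfall_telescopes_to_prediction(self):
        attr = self._toy_attributions()[0]
        views = explanation_views(attr)
        assert views["waterfall"][-1]["cumulative"] == pytest.approx(attr.prediction, abs=1e-9)
        force = views["force"]
        signed = sum(e["phi"] for e in force["increasing"]) + sum(
            e["phi"] for e in force["decreasing"]
        )
        assert signed == pytest.approx(attr.prediction - attr.base_value, abs=1e-9)

    def test_dependence_data_shape_and_self_colouring(self):
        attrs = self._toy_attributions()
        triples = dependence_data(attrs, "a", "b")
        assert len(triples) == 3
        self_coloured = dependence_data(attrs, "a", "a")
        assert all(t[0] == t[2] for t in self_coloured)
        with pytest.raises(KeyError):
            dependence_data(attrs, "nope", "a")

    def test_interaction_pattern_recovered_from_dependence_data(self, rng):
        # phi(x1) grows with x1 only when the moderator x2 is high
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        X = np.column_stack([x1, x2])

        def model(Z):
            return Z[:, 0] * (Z[:, 1] > 0)

        bg = rng.normal(size=(30, 2))
        attrs = [shapley_values(model, X[[i]], bg, mode="exact") for i in range(n)]
        triples = dependence_data(attrs, "x1", "x2")
        vals = np.array([(t[0], t[1], t[2]) for t in triples])
        top_q = vals[:, 0] >= np.quantile(vals[:, 0], 0.75)
        high = vals[top_q & (vals[:, 2] > 0), 1]
        low = vals[top_q & (vals[:, 2] <= 0), 1]
        assert high.mean() > low.mean()
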