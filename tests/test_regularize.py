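"""Activation L1, layer entropy, total regularizer, total training loss."""

import numpy as np
import pytest

from kansurv.cox import cox_loss_fast
from kansurv.network import ActivationEdge, KanLayer, init_model
from kansurv.regularize import (
    _entropy_from_l1s,
    activation_l1,
    coefficient_l1,
    layer_activation_l1s,
    layer_entropy,
    regularization_report,
    regularization_total,
    total_loss,
)
from kansurv.splines import Spline
from tests.conftest import make_survival_arrays


def zero_edge():
    return ActivationEdge(w_b=0.0, w_s=0.0)


def identity_edge():
    return ActivationEdge(w_b=1.0, w_s=0.0, basis_kind="identity")


class TestActivationL1:
    def test_zero_edge(self, rng):
        assert activation_l1(zero_edge(), rng.normal(size=10)) == 0.0

    def test_identity_edge_on_plus_minus_one(self):
        assert activation_l1(identity_edge(), np.array([1.0, -1.0])) == 1.0

    def test_matches_explicit_loop(self, rng):
        e = ActivationEdge(spline=Spline(3, 5, coef=rng.normal(size=8)))
        batch = rng.uniform(-1, 1, 37)
        expected = sum(abs(e.evaluate(np.array([x]))[0]) for x in batch) / 37
        assert activation_l1(e, batch) == pytest.approx(expected, rel=1e-12)


class TestEntropy:
    def test_single_nonzero_edge_zero_entropy(self, rng):
        layer = KanLayer([[identity_edge(), zero_edge()]])
        assert layer_entropy(layer, rng.uniform(-1, 1, (20, 2))) == 0.0

    def test_equal_l1_gives_log_m(self, rng):
        m = 6
        layer = KanLayer([[identity_edge() for _ in range(3)] for _ in range(2)])
        X = rng.uniform(-1, 1, (50, 3))
        X = np.abs(X)  # identical distribution per column not needed: use same col
        X = np.repeat(X[:, :1], 3, axis=1)
        assert layer_entropy(layer, X) == pytest.approx(np.log(m))

    def test_matches_direct_formula(self, rng):
        l1s = rng.uniform(0, 2, (3, 4))
        p = l1s / l1s.sum()
        expected = -np.sum(p * np.log(p))
        assert _entropy_from_l1s(l1s) == pytest.approx(expected, rel=1e-12)

    def test_entropy_bounds_random_norm_vectors(self, rng):
        """0 <= S <= log(n_in * n_out) over 1000 random layers' L1 grids."""
        for _ in range(1000):
            shape = (rng.integers(1, 5), rng.integers(1, 5))
            l1s = rng.uniform(0, 1, shape) * (rng.random(shape) > 0.3)
            S = _entropy_from_l1s(l1s)
            assert 0.0 <= S <= np.log(shape[0] * shape[1]) + 1e-12

    def test_entropy_bounds_real_layers(self, rng):
        for seed in range(25):
            model = init_model([3, 2, 1], seed=seed)
            X = np.random.default_rng(seed).uniform(-1, 1, (30, 3))
            for layer, Z in [(model.layers[0], X)]:
                S = layer_entropy(layer, Z)
                assert 0.0 <= S <= np.log(layer.n_in * layer.n_out) + 1e-12


class TestRegularizationTotal:
    def test_reduces_to_activation_l1_sum(self, rng):
        model = init_model([3, 2, 1], seed=1)
        X = rng.uniform(-1, 1, (40, 3))
        total = regularization_total(model, X, lam_ent=0.0, lam_coef=0.0)
        Z = model.normalize_inputs(X)
        expected = 0.0
        for layer in model.layers:
            expected += layer_activation_l1s(layer, Z).sum()
            Z = layer.forward(Z)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_all_zero_network(self, rng):
        model = init_model([3, 1], seed=0, coef_scale=0.0)
        for e in model.layers[0].edges[0]:
            e.w_b = e.w_s = 0.0
        assert regularization_total(model, rng.uniform(-1, 1, (10, 3)), 2.0, 1.0) == 0.0

    def test_matches_term_by_term_oracle(self, rng):
        model = init_model([3, 2, 1], seed=5)
        X = rng.uniform(-1, 1, (30, 3))
        lam_ent, lam_coef = 1.7, 0.3
        Z = model.normalize_inputs(X)
        expected = 0.0
        for layer in model.layers:
            l1s = np.array(
                [[activation_l1(layer.edges[j][i], Z[:, i]) for i in range(layer.n_in)]
                 for j in range(layer.n_out)]
            )
            p = l1s / l1s.sum()
            S = -np.sum(p[p > 0] * np.log(p[p > 0]))
            C = sum(coefficient_l1(e) for row in layer.edges for e in row)
            expected += l1s.sum() + lam_ent * S + lam_coef * C
            Z = layer.forward(Z)
        assert regularization_total(model, X, lam_ent, lam_coef) == pytest.approx(
            expected, rel=1e-10
        )

    def test_non_negative_and_report_consistent(self, rng):
        model = init_model([4, 2, 1], seed=9)
        X = rng.uniform(-1, 1, (25, 4))
        rep = regularization_report(model, X, 2.0, 0.5)
        assert rep.total >= 0.0
        assert rep.total == pytest.approx(regularization_total(model, X, 2.0, 0.5))
        assert all(l >= 0 for l in rep.layer_l1)


class TestTotalLoss:
    def test_lambda_zero_equals_fast_loss(self, rng):
        model = init_model([3, 1], seed=2)
        X, t, delta = make_survival_arrays(rng, n=60)
        expected = cox_loss_fast(model.forward(X), t, delta)
        assert total_loss(model, (X, t, delta), lam=0.0) == expected

    def test_additivity_of_parts(self, rng):
        model = init_model([3, 2, 1], seed=3)
        X, t, delta = make_survival_arrays(rng, n=60)
        lam, le, lc = 0.2, 1.5, 0.4
        expected = cox_loss_fast(model.forward(X), t, delta) + lam * regularization_total(
            model, X, le, lc
        )
        assert total_loss(model, (X, t, delta), lam, le, lc) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_network_decomposition(self, rng):
        """theta == 0 network: loss = uniform-risk Cox loss + lam * R."""
        model = init_model([3, 1], seed=0, coef_scale=0.0)
        for e in model.layers[0].edges[0]:
            e.w_b = e.w_s = 0.0
        X, t, delta = make_survival_arrays(rng, n=50)
        lam = 0.7
        uniform = cox_loss_fast(np.zeros(50), t, delta)
        assert total_loss(model, (X, t, delta), lam, 2.0, 1.0) == pytest.approx(uniform)
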