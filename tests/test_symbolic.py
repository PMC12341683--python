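"""Progressive symbolic fitting: linear gate, operator library, genetic
fallback, categorical maps, and the progressive-ordering contract."""

import numpy as np
import pytest

import kansurv.symbolic as symbolic
from kansurv.network import ActivationEdge
from kansurv.splines import Spline, fit_spline_to_samples
from kansurv.symbolic import (
    GeneticConfig,
    SymbolicFit,
    categorical_to_map,
    fit_genetic,
    fit_linear,
    fit_operator_library,
    symbolize_edge,
)


class TestFitLinear:
    def test_exact_line(self):
        x = np.linspace(-1, 1, 50)
        fit = fit_linear((x, 2 * x + 1))
        assert fit.c == pytest.approx(2.0)
        assert fit.d == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.accepted

    def test_symmetric_parabola_rejected(self):
        x = np.linspace(-1, 1, 101)  # symmetric grid: slope integrates to 0
        fit = fit_linear((x, x**2))
        assert abs(fit.c) < 1e-10
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)
        assert not fit.accepted

    def test_noisy_line_matches_normal_equations(self, rng):
        x = rng.uniform(-2, 2, 200)
        y = 1.3 * x - 0.4 + rng.normal(0, 0.1, 200)
        fit = fit_linear((x, y))
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.c == pytest.approx(slope, rel=1e-9)
        assert fit.d == pytest.approx(intercept, rel=1e-9)

    def test_constant_target_r2_one(self):
        x = np.linspace(-1, 1, 20)
        fit = fit_linear((x, np.full(20, 3.5)))
        assert fit.r2 == 1.0
        assert fit.c == 0.0 and fit.d == pytest.approx(3.5)


class TestOperatorLibrary:
    def test_sin_recovered(self):
        x = np.linspace(-3, 3, 200)
        fit = fit_operator_library((x, np.sin(x)))
        assert fit.operator == "sin"
        assert fit.r2 > 0.999
        np.testing.assert_allclose(fit(x), np.sin(x), atol=1e-3)

    def test_exp_affine_recovery_functional(self):
        """3 exp(2x - 1) + 0.5 is recovered to 1e-2 after refinement."""
        x = np.linspace(-1, 1, 200)
        y = 3 * np.exp(2 * x - 1) + 0.5
        fit = fit_operator_library((x, y))
        assert fit.operator == "exp"
        assert np.max(np.abs(fit(x) - y)) < 1e-2
        # (b, c) share a gauge for exp: compare the identifiable combination
        assert fit.a == pytest.approx(2.0, abs=1e-2)
        assert fit.c * np.exp(fit.b) == pytest.approx(3 * np.exp(-1.0), rel=1e-2)

    def test_constant_pairs_fit_exactly(self):
        x = np.linspace(-1, 1, 30)
        fit = fit_operator_library((x, np.full(30, -2.0)))
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit(x), -2.0, atol=1e-9)

    def test_domain_violations_not_fatal(self):
        # log demands positive arguments on part of the grid only
        x = np.linspace(0.1, 2, 100)
        fit = fit_operator_library((x, np.log(x)))
        assert fit.operator in ("log", "arccosh")  # log-like shapes
        assert fit.r2 > 0.999


class TestGenetic:
    def test_linear_target(self):
        x = np.linspace(-1, 1, 100)
        fit = fit_genetic((x, 2 * x - 0.5), GeneticConfig(seed=0))
        assert fit.r2 > 0.999

    def test_x_sin_3x_target(self):
        x = np.linspace(-1, 1, 200)
        y = x * np.sin(3 * x)
        fit = fit_genetic((x, y), GeneticConfig(seed=1))
        assert fit.r2 >= 0.99

    def test_determinism_same_seed(self):
        x = np.linspace(-1, 1, 100)
        y = np.cos(2 * x) + 0.3 * x
        a = fit_genetic((x, y), GeneticConfig(seed=7, generations=15))
        b = fit_genetic((x, y), GeneticConfig(seed=7, generations=15))
        assert a.tree == b.tree
        assert a.r2 == b.r2


class TestSymbolizeEdge:
    def _edge_for(self, fn, lo=-1, hi=1):
        x = np.linspace(lo, hi, 400)
        sp = fit_spline_to_samples(x, fn(x), degree=3, grid_intervals=10, lo=lo, hi=hi)
        return ActivationEdge(w_b=0.0, w_s=1.0, spline=sp), x

    def test_near_linear_edge_stays_linear(self, rng):
        edge, x = self._edge_for(lambda x: 1.5 * x + 0.2)
        out = symbolize_edge(edge, x)
        assert out.symbolic_fit.stage == "linear"
        assert out.state == "symbolic"

    def test_gaussian_bump_edge(self, rng):
        """A spline trained to exp(-x^2) symbolizes at high fidelity."""
        edge, x = self._edge_for(lambda x: np.exp(-(x**2)))
        out = symbolize_edge(edge, x)
        assert out.symbolic_fit.stage in ("library", "genetic")
        assert out.symbolic_fit.r2 >= 0.99

    def test_progressive_ordering_skips_later_stages(self, monkeypatch):
        calls = {"library": 0, "genetic": 0}
        monkeypatch.setattr(
            symbolic, "fit_operator_library",
            lambda *a, **k: calls.__setitem__("library", calls["library"] + 1),
        )
        monkeypatch.setattr(
            symbolic, "fit_genetic",
            lambda *a, **k: calls.__setitem__("genetic", calls["genetic"] + 1),
        )
        x = np.linspace(-1, 1, 100)
        sp = fit_spline_to_samples(x, 2 * x, degree=3, grid_intervals=5)
        edge = ActivationEdge(w_b=0.0, w_s=1.0, spline=sp)
        out = symbolize_edge(edge, x)
        assert out.symbolic_fit.stage == "linear"
        assert calls == {"library": 0, "genetic": 0}

    def test_hard_shape_engages_genetic(self, rng):
        """A shape no affine-wrapped single operator captures falls through
        the library gate to the genetic stage."""
        edge, x = self._edge_for(lambda x: np.sin(5 * x) * x**2)
        out = symbolize_edge(edge, x, genetic_config=GeneticConfig(seed=3, generations=10))
        assert out.symbolic_fit.stage == "genetic"


class TestCategoricalMap:
    def _trained_edge(self, rng):
        sp = Spline(3, 5, coef=rng.normal(0, 1, 8))
        return ActivationEdge(w_b=1.0, w_s=1.0, spline=sp)

    def test_binary_feature_two_entry_map(self, rng):
        edge = self._trained_edge(rng)
        positions = np.array([-1.0, 1.0])
        expected = edge.evaluate(positions).copy()
        out = categorical_to_map(edge, [0, 1], positions)
        assert out.state == "categorical_map"
        assert sorted(out.category_map) == [0, 1]
        np.testing.assert_allclose(out.evaluate(positions), expected, atol=1e-12)

    def test_five_level_forward_unchanged(self, rng):
        edge = self._trained_edge(rng)
        positions = np.linspace(-1, 1, 5)
        codes = list(range(5))
        spline_values = edge.evaluate(positions).copy()
        out = categorical_to_map(edge, codes, positions)
        rows = positions[np.array([0, 3, 1, 4, 2, 2, 0])]
        np.testing.assert_allclose(
            out.evaluate(rows),
            spline_values[np.array([0, 3, 1, 4, 2, 2, 0])],
            atol=1e-12,
        )

    def test_map_values_match_edge_eval(self, rng):
        edge = self._trained_edge(rng)
        positions = np.linspace(-1, 1, 4)
        reference = edge.evaluate(positions).copy()
        out = categorical_to_map(edge, [0, 1, 2, 3], positions)
        for code, pos, ref in zip(range(4), positions, reference):
            assert abs(out.category_map[code] - ref) <= 1e-12


def test_symbolic_fit_serialization_round_trip():
    x = np.linspace(-1, 1, 50)
    for fit in (
        fit_linear((x, 2 * x + 1)),
        fit_operator_library((x, np.tanh(2 * x))),
        fit_genetic((x, x**2), GeneticConfig(seed=0, generations=5)),
    ):
        again = SymbolicFit.from_dict(fit.to_dict())
        np.testing.assert_array_equal(fit(x), again(x))
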