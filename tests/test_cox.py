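"""Cox losses (exact and fast), concordance, bootstrap, linear CoxPH."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kansurv.cox import (
    bootstrap_cindex,
    concordance_index,
    cox_loss_exact,
    cox_loss_fast,
    coxph_standard_errors,
    fit_coxph,
)
from kansurv.exceptions import UndefinedCIndexError, UndefinedLossError
from tests.conftest import make_survival_arrays


def brute_force_exact_loss(theta, t, delta):
    """Risk-set enumeration oracle for the Breslow partial likelihood."""
    loss = 0.0
    for i in range(len(t)):
        if delta[i] == 1:
            risk = [j for j in range(len(t)) if t[j] >= t[i]]
            loss -= theta[i] - np.log(np.sum(np.exp(theta[risk])))
    return loss


def prefix_rule_oracle(theta, t, delta):
    """Explicit-loop oracle for the fast loss's sorted prefix rule."""
    order = np.lexsort((-delta, -t))
    loss = 0.0
    for pos, i in enumerate(order):
        if delta[i] == 1:
            prefix = order[: pos + 1]
            loss -= theta[i] - np.log(np.sum(np.exp(theta[prefix])))
    return loss


def pair_oracle(theta, t, delta):
    conc, adm = 0.0, 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if delta[i] == 1 and t[i] < t[j]:
                adm += 1
                if theta[i] > theta[j]:
                    conc += 1
                elif theta[i] == theta[j]:
                    conc += 0.5
    return conc / adm


class TestExactLoss:
    def test_uniform_risk_closed_form(self):
        theta = np.zeros(3)
        t = np.array([1.0, 2.0, 3.0])
        delta = np.ones(3)
        assert cox_loss_exact(theta, t, delta) == pytest.approx(
            np.log(3) + np.log(2) + np.log(1), abs=1e-12
        )

    def test_single_event_smallest_time(self):
        n = 9
        t = np.arange(1.0, n + 1)
        delta = np.zeros(n)
        delta[0] = 1
        assert cox_loss_exact(np.zeros(n), t, delta) == pytest.approx(np.log(n))

    def test_matches_risk_set_enumeration_with_ties(self, rng):
        for _ in range(20):
            theta = rng.normal(size=12)
            t = rng.integers(1, 5, 12).astype(float)  # many ties
            delta = rng.integers(0, 2, 12).astype(float)
            if delta.sum() == 0:
                delta[0] = 1
            assert cox_loss_exact(theta, t, delta) == pytest.approx(
                brute_force_exact_loss(theta, t, delta), rel=1e-10
            )

    def test_zero_events_raises(self):
        with pytest.raises(UndefinedLossError):
            cox_loss_exact(np.zeros(4), np.arange(4.0), np.zeros(4))


class TestFastLoss:
    def test_no_ties_equivalence_100_datasets(self, rng):
        """Fast and exact agree to 1e-10 on tie-free data (100 x n=200)."""
        for _ in range(100):
            n = 200
            theta = rng.normal(size=n)
            t = rng.permutation(np.arange(1.0, n + 1))
            delta = rng.integers(0, 2, n).astype(float)
            if delta.sum() == 0:
                delta[0] = 1
            assert abs(
                cox_loss_fast(theta, t, delta) - cox_loss_exact(theta, t, delta)
            ) < 1e-10

    def test_shift_invariance(self, rng):
        X, t, delta = make_survival_arrays(rng, n=80)
        theta = rng.normal(size=80)
        for c in (5.0, -3.0):
            assert cox_loss_fast(theta + c, t, delta) == pytest.approx(
                cox_loss_fast(theta, t, delta), abs=1e-8
            )
            assert cox_loss_exact(theta + c, t, delta) == pytest.approx(
                cox_loss_exact(theta, t, delta), abs=1e-8
            )

    def test_ties_match_prefix_rule_oracle(self, rng):
        for _ in range(20):
            theta = rng.normal(size=15)
            t = rng.integers(1, 4, 15).astype(float)
            delta = rng.integers(0, 2, 15).astype(float)
            if delta.sum() == 0:
                delta[0] = 1
            assert cox_loss_fast(theta, t, delta) == pytest.approx(
                prefix_rule_oracle(theta, t, delta), rel=1e-10
            )


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.arange(1.0, 11)
        theta = -t  # strictly decreasing in t
        assert concordance_index(theta, t, np.ones(10)) == 1.0

    def test_constant_scores_half(self):
        t = np.arange(1.0, 11)
        assert concordance_index(np.zeros(10), t, np.ones(10)) == 0.5

    def test_matches_pair_enumeration(self, rng):
        for _ in range(50):
            theta = rng.normal(size=15)
            t = rng.integers(1, 8, 15).astype(float)
            delta = rng.integers(0, 2, 15).astype(float)
            if not any(
                delta[i] == 1 and t[i] < t[j] for i in range(15) for j in range(15)
            ):
                continue
            assert concordance_index(theta, t, delta) == pytest.approx(
                pair_oracle(theta, t, delta)
            )

    def test_agrees_with_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored

        X, t, delta = make_survival_arrays(rng, n=300)
        theta = rng.normal(size=300)
        ours = concordance_index(theta, t, delta)
        # sksurv ranks higher scores as higher risk, same as our convention
        theirs = concordance_index_censored(delta.astype(bool), t, theta)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        theta = r.normal(size=30)
        t = r.exponential(1, 30)
        delta = r.integers(0, 2, 30).astype(float)
        if delta.sum() == 0:
            delta[0] = 1.0
        base = concordance_index(theta, t, delta)
        for f in (lambda x: 3 * x + 2, np.tanh, lambda x: np.exp(x / 4)):
            assert concordance_index(f(theta), t, delta) == pytest.approx(base)

    def test_no_admissible_pairs_raises(self):
        with pytest.raises(UndefinedCIndexError):
            concordance_index(np.zeros(3), np.ones(3), np.ones(3))  # all tied times


class TestBootstrap:
    def test_perfectly_concordant_interval_collapses(self):
        t = np.arange(1.0, 21)
        res = bootstrap_cindex(-t, t, np.ones(20), n_bootstrap=50, seed=0)
        assert (res.estimate, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_single_resample_degenerate_interval(self, rng):
        X, t, delta = make_survival_arrays(rng, n=40)
        theta = rng.normal(size=40)
        res = bootstrap_cindex(theta, t, delta, n_bootstrap=1, seed=5)
        assert res.ci_low <= res.estimate <= res.ci_high
        # the percentile band collapses onto that single resample's C
        # (then widens only as needed to contain the point estimate)
        idx = np.random.default_rng(5).integers(0, 40, 40)
        c_resample = concordance_index(theta[idx], t[idx], delta[idx])
        assert min(res.ci_low, res.ci_high) == min(c_resample, res.estimate)
        assert max(res.ci_low, res.ci_high) == max(c_resample, res.estimate)

    def test_seed_determinism(self, rng):
        X, t, delta = make_survival_arrays(rng, n=60)
        theta = rng.normal(size=60)
        a = bootstrap_cindex(theta, t, delta, n_bootstrap=100, seed=3)
        b = bootstrap_cindex(theta, t, delta, n_bootstrap=100, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_narrow_at_benchmark_scale(self):
        """At a few thousand subjects the 95% band is a few thousandths wide."""
        from kansurv.simulate import builtin_formula, simulate_survival

        f = builtin_formula("gaussian")
        d = simulate_survival(f, 4000, seed=0)
        res = bootstrap_cindex(f.theta(d.X), d.t, d.delta, n_bootstrap=200, seed=0)
        assert 0.0 < res.ci_high - res.ci_low < 0.05


class TestCoxPHFit:
    def test_null_data_recovers_zero(self, rng):
        X, t, delta = make_survival_arrays(rng, n=400, p=3)
        model = fit_coxph((X, t, delta))
        se = coxph_standard_errors((X, t, delta), model.beta)
        assert np.all(np.abs(model.beta) < 3 * se)

    def test_parameter_recovery(self):
        """Simulated theta = 1.0 x1 - 0.5 x2 is recovered within +/-0.1."""
        from kansurv.simulate import HazardFormula, simulate_survival
        import sympy as sp

        x1, x2 = sp.symbols("x1 x2")
        f = HazardFormula(1.0 * x1 - 0.5 * x2, ["x1", "x2"], n_noise=0)
        d = simulate_survival(f, 5000, seed=42)
        model = fit_coxph(d)
        np.testing.assert_allclose(model.beta, [1.0, -0.5], atol=0.1)

    def test_agrees_with_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, t, delta = make_survival_arrays(
            rng, n=500, p=2, theta=lambda X: 0.8 * X[:, 0]
        )
        ours = fit_coxph((X, t, delta))
        df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "t": t, "e": delta})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(ours.beta, cph.params_.to_numpy(), atol=2e-3)

    def test_heavy_lasso_zeroes_coefficients(self, rng):
        X, t, delta = make_survival_arrays(
            rng, n=300, p=3, theta=lambda X: X[:, 0]
        )
        model = fit_coxph((X, t, delta), l1_penalty=1e4)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-10)
        assert concordance_index(
            model.predict(X) + np.zeros(len(t)), t, delta
        ) == pytest.approx(0.5)

    def test_zero_events_raises(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(UndefinedLossError):
            fit_coxph((X, np.arange(10.0), np.zeros(10)))
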