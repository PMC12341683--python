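"""Training loop: checkpointing, determinism, recovery, search."""

import numpy as np
import pytest
import sympy as sp

from kansurv.cox import concordance_index
from kansurv.data import SurvivalDataset
from kansurv.exceptions import ConfigurationError
from kansurv.prune import edge_l1_matrices
from kansurv.simulate import HazardFormula, simulate_survival
from kansurv.train import (
    TrainConfig,
    default_search_space,
    hyperparameter_search,
    stratified_event_split,
    train,
)
from tests.conftest import make_survival_arrays


def linear_data(n=1200, seed=0, beta=2.0):
    x1 = sp.Symbol("x1")
    f = HazardFormula(beta * x1, ["x1"], n_noise=2)
    return f, simulate_survival(f, n, seed=seed)


def test_returned_checkpoint_is_best_val_c():
    _, d = linear_data()
    cfg = TrainConfig(shape=[3, 1], steps=60, seed=0, checkpoint_tol=0.0)
    model, trace = train(d, cfg)
    best = int(np.argmax(trace["val_cindex"]))
    assert trace["best_epoch"] == best
    # re-train and stop exactly at the best epoch: parameters must agree
    cfg2 = TrainConfig(shape=[3, 1], steps=best + 1, seed=0, checkpoint_tol=0.0)
    model2, _ = train(d, cfg2)
    np.testing.assert_array_equal(model.parameter_vector(), model2.parameter_vector())


def test_checkpoint_tol_keeps_later_tied_epoch():
    _, d = linear_data()
    cfg = TrainConfig(shape=[3, 1], steps=60, seed=0, checkpoint_tol=0.01,
                      early_stop_patience=60)
    _, trace = train(d, cfg)
    best = max(trace["val_cindex"])
    assert trace["val_cindex"][trace["best_epoch"]] >= best - 0.01
    assert trace["best_epoch"] >= int(np.argmax(trace["val_cindex"]))


def test_unregularized_full_batch_loss_nearly_monotone():
    """With lam = 0 the full-batch loss decreases apart from the small
    non-monotonicity inherent to adaptive-moment steps."""
    _, d = linear_data()
    cfg = TrainConfig(shape=[3, 1], steps=120, seed=1, lam=0.0,
                      learning_rate=0.01, early_stop_patience=120)
    _, trace = train(d, cfg)
    losses = np.asarray(trace["train_loss"])
    assert losses[-1] < losses[0]
    increases = np.maximum(np.diff(losses), 0).sum()
    assert increases < 0.05 * (losses[0] - losses[-1])


def test_seed_determinism_identical_json():
    _, d = linear_data()
    cfg = TrainConfig(shape=[3, 1], steps=40, seed=9)
    m1, _ = train(d, cfg)
    m2, _ = train(d, cfg)
    assert m1.to_json() == m2.to_json()


def test_recovers_linear_signal_within_002():
    """Trained val C on theta = 2 x1 comes within 0.02 of the true-formula
    C on the same validation split."""
    f, d = linear_data(n=3000, seed=3)
    cfg = TrainConfig(shape=[3, 1], steps=300, seed=3, learning_rate=0.05)
    model, trace = train(d, cfg)
    rng = np.random.default_rng(cfg.seed)
    _, va = stratified_event_split(d.t, d.delta, cfg.val_fraction, rng)
    c_true = concordance_index(f.theta(d.X[va]), d.t[va], d.delta[va])
    c_model = max(trace["val_cindex"])
    assert abs(c_model - c_true) < 0.02


def test_regularization_dominance_shrinks_activations(rng):
    """Huge lam on null data drives activation L1s toward 0 and C to 0.5."""
    X, t, delta = make_survival_arrays(rng, n=600, p=3)
    d = SurvivalDataset(X, t, delta, ["x1", "x2", "x3"])
    cfg = TrainConfig(shape=[3, 1], steps=250, seed=0, lam=5.0, lam_ent=0.0,
                      learning_rate=0.05, early_stop_patience=250,
                      checkpoint_tol=1.0)  # keep the final (most shrunk) epoch
    model, trace = train(d, cfg)
    l1s = edge_l1_matrices(model, X)[0]
    assert l1s.max() < 0.1
    assert abs(trace["val_cindex"][-1] - 0.5) < 0.1


def test_mismatched_shape_raises():
    _, d = linear_data()
    with pytest.raises(ConfigurationError):
        train(d, TrainConfig(shape=[5, 1], steps=5))


def test_config_yaml_round_trip(tmp_path):
    cfg = TrainConfig(shape=[4, 2, 1], lam=0.03, seed=5)
    p = tmp_path / "c.yaml"
    cfg.to_yaml(p)
    assert TrainConfig.from_yaml(p) == cfg


class TestHyperparameterSearch:
    def _tiny(self, seed=0):
        _, d = linear_data(n=400, seed=seed)
        return d

    def test_budget_one_returns_single_sample(self):
        d = self._tiny()
        space = {"shape": [[3, 1]], "lam": ("log", 1e-4, 1e-2),
                 "steps": [20]}
        cfg = hyperparameter_search(d, space, budget=1, seed=0, cv_folds=2)
        assert cfg.shape == [3, 1]

    def test_point_space_returns_that_point(self):
        d = self._tiny()
        space = {"shape": [[3, 1]], "lam": [0.02], "learning_rate": [0.05],
                 "steps": [20]}
        cfg = hyperparameter_search(d, space, budget=3, seed=1, cv_folds=2)
        assert (cfg.shape, cfg.lam, cfg.learning_rate) == ([3, 1], 0.02, 0.05)

    def test_dominated_config_loses(self):
        """A 1-step learning-rate-0 config loses to a real training config
        under cross-validated C."""
        d = self._tiny(seed=2)
        space = {
            "shape": [[3, 1]],
            "steps": [1, 150],  # 1-step training is dominated
            "learning_rate": [0.05],
            "early_stop_patience": [150],
        }
        cfg = hyperparameter_search(d, space, budget=8, seed=3, cv_folds=3)
        assert cfg.steps == 150

    def test_all_failures_raise_with_details(self):
        d = self._tiny()
        space = {"shape": [[7, 1]]}  # wrong width: every candidate fails
        with pytest.raises(ConfigurationError, match="failed"):
            hyperparameter_search(d, space, budget=2, seed=0, cv_folds=2)

    def test_default_space_shapes(self):
        space = default_search_space(6)
        assert [6, 2, 1] in space["shape"]
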