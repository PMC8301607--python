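"""Go-ZT generator: weighted-sum layer, training, prediction pipeline."""

import numpy as np
import pytest

from zebratox.chemio import fixture_molecule
from zebratox.nets import (
    GoZTConfig,
    assemble_batch,
    build_generator,
    forward,
    load_model,
    predict_activity,
    predict_matrices,
    save_model,
    train_go_zt,
    weighted_sum,
)
from zebratox.pipeline import featurize
from zebratox.synth import SynthConfig, make_dataset
from zebratox.toxdata import N_ENDPOINTS
from zebratox.views import ViewConfig, ViewTensor


class _StubNet:
    """Identity feature/toxicity net for isolating the weighted-sum layer."""

    params: list = []

    def forward(self, x, train=False):
        return x


def _tensors(n=6, seed=0, max_atoms=16):
    ds = make_dataset(SynthConfig(n_chemicals=n, seed=seed))
    return featurize(ds.molecules, ViewConfig(max_atoms_per_view=max_atoms)), ds


def test_weighted_sum_matches_bruteforce_oracle(rng):
    for _ in range(10):
        n_views, d, n_mol = 30, 7, 5
        F = rng.standard_normal((n_views, d))
        w = rng.random(n_views)
        seg = rng.integers(0, n_mol, n_views)
        S = weighted_sum(F, w, seg, n_mol)
        oracle = np.zeros((n_mol, d))
        for i in range(n_views):  # brute-force summation
            oracle[seg[i]] += F[i] * w[i]
        assert np.abs(S - oracle).max() < 1e-6


def test_forward_with_stub_nets_is_weighted_average_of_views():
    tensors, _ = _tensors(4)
    cfg = GoZTConfig(max_atoms=16, seed=0)
    model = build_generator(cfg, np.random.default_rng(0))
    model.feature_net = _StubNet()
    model.toxicity_net = _StubNet()
    out = forward(model, tensors)
    for k, t in enumerate(tensors):
        flat = t.views.reshape(t.views.shape[0], -1)
        assert np.abs(out[k] - (flat * t.weights[:, None]).sum(axis=0)).max() < 1e-9


def test_duplicating_views_with_halved_weights_preserves_output():
    tensors, _ = _tensors(3)
    cfg = GoZTConfig(max_atoms=16, seed=1)
    model = build_generator(cfg, np.random.default_rng(1))
    base = forward(model, tensors)
    doubled = [
        ViewTensor(
            molecule_id=t.molecule_id,
            views=np.concatenate([t.views, t.views]),
            weights=np.concatenate([t.weights / 2, t.weights / 2]),
        )
        for t in tensors
    ]
    assert np.abs(forward(model, doubled) - base).max() < 1e-9


def test_view_order_invariance(rng):
    tensors, _ = _tensors(3)
    model = build_generator(GoZTConfig(max_atoms=16, seed=2), np.random.default_rng(2))
    base = forward(model, tensors)
    shuffled = []
    for t in tensors:
        perm = rng.permutation(len(t.weights))
        shuffled.append(
            ViewTensor(molecule_id=t.molecule_id, views=t.views[perm], weights=t.weights[perm])
        )
    assert np.abs(forward(model, shuffled) - base).max() < 1e-9


def test_forward_shape_mismatch_raises():
    tensors, _ = _tensors(2, max_atoms=8)
    model = build_generator(GoZTConfig(max_atoms=16, seed=0), np.random.default_rng(0))
    with pytest.raises(ValueError, match="expects"):
        forward(model, tensors)


def test_training_reduces_loss_and_is_deterministic():
    tensors, ds = _tensors(30, seed=5)
    cfg = GoZTConfig(width=32, feature_dim=8, epochs=75, seed=3)
    data = list(zip(tensors, ds.matrices))
    m1 = train_go_zt(data, cfg)
    assert len(m1.loss_history) == 75
    assert m1.loss_history[-1] < m1.loss_history[0]
    m2 = train_go_zt(data, cfg)
    assert m1.loss_history == m2.loss_history
    assert np.array_equal(predict_matrices(m1, tensors), predict_matrices(m2, tensors))


def test_memorizes_single_repeated_chemical():
    tensors, ds = _tensors(1, seed=2)
    cfg = GoZTConfig(width=32, feature_dim=8, epochs=200, learning_rate=0.1, seed=0)
    model = train_go_zt([(tensors[0], ds.matrices[0])] * 4, cfg)
    assert model.loss_history[-1] < 0.01


def test_nan_loss_aborts_with_learning_rate_guidance():
    tensors, ds = _tensors(4, seed=1)
    # without batch normalization a huge step makes activations overflow
    cfg = GoZTConfig(
        width=16, feature_dim=8, epochs=10, learning_rate=1e9, batchnorm=False, seed=0
    )
    with pytest.raises(RuntimeError, match="learning rate"):
        train_go_zt(list(zip(tensors, ds.matrices)), cfg)


def test_training_requires_two_chemicals():
    tensors, ds = _tensors(1, seed=0)
    with pytest.raises(ValueError):
        train_go_zt([(tensors[0], ds.matrices[0])], GoZTConfig())


def test_loss_nonincreasing_without_batchnorm_small_lr():
    tensors, ds = _tensors(10, seed=3)
    data = list(zip(tensors, ds.matrices))
    for seed in range(5):
        cfg = GoZTConfig(
            width=64, feature_dim=16, batchnorm=False, learning_rate=1e-3, epochs=30, seed=seed
        )
        m = train_go_zt(data, cfg)
        assert np.all(np.diff(m.loss_history) <= 1e-6)


class _ConstNet:
    params: list = []

    def __init__(self, value):
        self.value = value

    def forward(self, x, train=False):
        return np.full((x.shape[0], N_ENDPOINTS), self.value)


@pytest.mark.parametrize("value,expect_active", [(0.0, False), (1.0, True)])
def test_predict_activity_constant_models(value, expect_active):
    _, ds = _tensors(5, seed=4)
    model = build_generator(GoZTConfig(seed=0), np.random.default_rng(0))
    model.toxicity_net = _ConstNet(value)
    calls, excluded = predict_activity(model, ds.molecules)
    assert not excluded
    assert len(calls) == 5
    assert all(c.active is expect_active for c in calls)


def test_predict_activity_excludes_out_of_domain():
    _, ds = _tensors(3, seed=6)
    mols = ds.molecules + [fixture_molecule("perfluorodecane")]
    model = build_generator(GoZTConfig(seed=0), np.random.default_rng(0))
    model.toxicity_net = _ConstNet(0.0)
    calls, excluded = predict_activity(model, mols)
    called_ids = {c.chemical_id for c in calls}
    assert "perfluorodecane" not in called_ids
    assert "perfluorinated" in excluded["perfluorodecane"]


def test_checkpoint_roundtrip(tmp_path):
    tensors, ds = _tensors(6, seed=7)
    cfg = GoZTConfig(width=16, feature_dim=8, epochs=5, seed=1)
    model = train_go_zt(list(zip(tensors, ds.matrices)), cfg)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.config == model.config
    assert back.loss_history == model.loss_history
    assert np.array_equal(predict_matrices(back, tensors), predict_matrices(model, tensors))
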