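"""The Go-ZT regression generator.

Architecture: a *feature network* f maps each padded view (flattened
max_atoms x 5 matrix) to a feature vector; the molecule representation is
the weighted sum s = sum_i f(v_i) * w_i over its views; a *toxicity
network* g maps s to the 18-endpoint incidence vector. Both nets are
dense stacks with swish activations on hidden and output layers, batch
normalization between layers, Gaussian weight init and no dropout, trained
end-to-end by SGD on mean squared error.

Predictions are raw regression outputs; they are clipped to [0, 1] only at
the AggE interface so the regression targets are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._mlp import SGD, Sequential, make_mlp, mse_loss
from .chemio import Molecule, domain_filter
from .toxdata import DEFAULT_THRESHOLD, N_ENDPOINTS, ActivityCall, ToxicityMatrix, agg_entropy, classify
from .views import ViewConfig, ViewSet, ViewTensor, build_views, pad_to_tensor

log = logging.getLogger(__name__)

__all__ = [
    "GoZTConfig",
    "GeneratorModel",
    "forward",
    "weighted_sum",
    "train_go_zt",
    "predict_matrices",
    "predict_activity",
    "save_model",
    "load_model",
]


@dataclass
class GoZTConfig:
    """Generator hyperparameters.

    The layer counts (3 feature, 11 toxicity) are the fixed architecture;
    widths and learning rate are the search-tunable knobs. ``max_atoms``
    is the per-view row budget the model was built for.
    """

    feature_hidden_layers: int = 3
    toxicity_hidden_layers: int = 11
    width: int = 128
    feature_dim: int | None = 16
    max_atoms: int = 16
    batchnorm: bool = True
    learning_rate: float = 0.2
    momentum: float = 0.0
    batch_size: int = 32
    epochs: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_hidden_layers < 1 or self.toxicity_hidden_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.feature_dim is None:
            self.feature_dim = self.width


@dataclass
class GeneratorModel:
    feature_net: Sequential
    toxicity_net: Sequential
    config: GoZTConfig
    loss_history: list[float] = field(default_factory=list)

    def n_parameters(self) -> int:
        return self.feature_net.n_parameters() + self.toxicity_net.n_parameters()


def build_generator(cfg: GoZTConfig, rng: np.random.Generator) -> GeneratorModel:
    f = make_mlp(
        n_in=cfg.max_atoms * 5,
        hidden=[cfg.width] * cfg.feature_hidden_layers,
        n_out=cfg.feature_dim,
        rng=rng,
        batchnorm=cfg.batchnorm,
    )
    g = make_mlp(
        n_in=cfg.feature_dim,
        hidden=[cfg.width] * cfg.toxicity_hidden_layers,
        n_out=N_ENDPOINTS,
        rng=rng,
        batchnorm=cfg.batchnorm,
    )
    return GeneratorModel(feature_net=f, toxicity_net=g, config=cfg)


# ---------------------------------------------------------------------------
# forward / backward over variable-size view sets


def assemble_batch(tensors: list[ViewTensor]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack all views of a batch: (X rows, weights, molecule segment ids)."""
    X = np.concatenate([t.views.reshape(t.views.shape[0], -1) for t in tensors])
    w = np.concatenate([t.weights for t in tensors])
    seg = np.concatenate(
        [np.full(t.views.shape[0], k, dtype=int) for k, t in enumerate(tensors)]
    )
    return X, w, seg


def weighted_sum(F: np.ndarray, w: np.ndarray, seg: np.ndarray, n_mol: int) -> np.ndarray:
    """s_m = sum over views i of molecule m of F_i * w_i."""
    S = np.zeros((n_mol, F.shape[1]))
    np.add.at(S, seg, F * w[:, None])
    return S


def forward(
    model: GeneratorModel, tensors: list[ViewTensor], train: bool = False
) -> np.ndarray:
    """Raw 18-endpoint predictions for a batch of padded view sets."""
    X, w, seg = assemble_batch(tensors)
    expect = model.config.max_atoms * 5
    if X.shape[1] != expect:
        raise ValueError(
            f"views padded to {X.shape[1] // 5} atoms but model expects {model.config.max_atoms}"
        )
    F = model.feature_net.forward(X, train=train)
    S = weighted_sum(F, w, seg, len(tensors))
    return model.toxicity_net.forward(S, train=train)


def _backward(model: GeneratorModel, dpred: np.ndarray, w: np.ndarray, seg: np.ndarray) -> None:
    dS = model.toxicity_net.backward(dpred)
    dF = dS[seg] * w[:, None]
    model.feature_net.backward(dF)


# ---------------------------------------------------------------------------
# training


def _as_tensor(vs: ViewSet | ViewTensor, max_atoms: int) -> ViewTensor:
    if isinstance(vs, ViewTensor):
        if vs.views.shape[1] != max_atoms:
            raise ValueError("tensor padding disagrees with model max_atoms")
        return vs
    return pad_to_tensor(vs, max_atoms)


def train_go_zt(
    data: list[tuple[ViewSet | ViewTensor, ToxicityMatrix]], cfg: GoZTConfig
) -> GeneratorModel:
    """Train the regression generator on (views, toxicity) pairs.

    Minimizes MSE between raw predictions and incidence vectors with
    mini-batch SGD for ``cfg.epochs`` epochs; the per-epoch training loss
    is recorded on the model. Deterministic given ``cfg.seed``.
    """
    if len(data) < 2:
        raise ValueError("training needs at least two chemicals")
    rng = np.random.default_rng(cfg.seed)
    model = build_generator(cfg, rng)
    tensors = [_as_tensor(vs, cfg.max_atoms) for vs, _ in data]
    targets = np.stack([tm.incidence for _, tm in data])
    opt = SGD(
        model.feature_net.params + model.toxicity_net.params,
        lr=cfg.learning_rate,
        momentum=cfg.momentum,
    )
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [tensors[i] for i in idx]
            X, w, seg = assemble_batch(batch)
            F = model.feature_net.forward(X, train=True)
            S = weighted_sum(F, w, seg, len(batch))
            pred = model.toxicity_net.forward(S, train=True)
            loss, dpred = mse_loss(pred, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}; "
                    f"lower the learning rate (currently {cfg.learning_rate})"
                )
            model.feature_net.zero_grad()
            model.toxicity_net.zero_grad()
            _backward(model, dpred, w, seg)
            opt.step()
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model


# ---------------------------------------------------------------------------
# prediction


def predict_matrices(
    model: GeneratorModel, tensors: list[ViewTensor], clip: bool = True
) -> np.ndarray:
    pred = forward(model, tensors, train=False)
    return np.clip(pred, 0.0, 1.0) if clip else pred


def predict_activity(
    model: GeneratorModel,
    molecules: list[Molecule],
    view_cfg: ViewConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[ActivityCall], dict[str, str]]:
    """Full pipeline: views -> generator -> AggE -> active/inactive calls.

    Molecules outside the domain of applicability are excluded from the
    calls; the returned mapping records each exclusion reason (also
    logged).
    """
    view_cfg = view_cfg or ViewConfig(max_atoms_per_view=model.config.max_atoms)
    kept, excluded = [], {}
    for mol in molecules:
        ok, reason = domain_filter(mol)
        if ok:
            kept.append(mol)
        else:
            excluded[mol.id] = reason
            log.info("excluded %s: %s", mol.id, reason)
    if not kept:
        return [], excluded
    tensors = [
        pad_to_tensor(build_views(m, view_cfg), model.config.max_atoms) for m in kept
    ]
    preds = predict_matrices(model, tensors)
    calls = []
    for mol, p in zip(kept, preds):
        tm = ToxicityMatrix(chemical_id=mol.id, incidence=p)
        calls.append(classify(agg_entropy(tm), threshold, chemical_id=mol.id))
    return calls, excluded


# ---------------------------------------------------------------------------
# checkpointing (single-file .npz archive)


def save_model(model: GeneratorModel, path: str | Path, extra: dict | None = None) -> None:
    arrays = {}
    for prefix, net in (("f", model.feature_net), ("g", model.toxicity_net)):
        for k, v in net.state_arrays().items():
            arrays[f"{prefix}_{k}"] = v
    meta = {"config": asdict(model.config), "loss_history": model.loss_history}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> GeneratorModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]))
        cfg = GoZTConfig(**meta["config"])
        model = build_generator(cfg, np.random.default_rng(cfg.seed))
        for prefix, net in (("f", model.feature_net), ("g", model.toxicity_net)):
            state = {
                k[len(prefix) + 1 :]: data[k]
                for k in data.files
                if k.startswith(f"{prefix}_")
            }
            net.load_state_arrays(state)
        model.loss_history = list(meta["loss_history"])
    return model
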