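"""The GAN-ZT conditional adversarial trainer.

The generator has the same shape as the Go-ZT generator (feature net,
weighted sum over views, toxicity net). A discriminator — a fully
connected net on the concatenation [s, toxicity matrix], where s is the
chemical's weighted-sum feature vector — scores pairs as real or fake.
Training alternates a least-squares discriminator step (Adam, targets
1 for real / 0 for generated) with a generator step (SGD) that pushes the
discriminator's score on generated pairs toward the real target. The
conditioning signal shared by generator and discriminator is s itself; a
one-hot chemical identifier can be concatenated instead via
``GANConfig.onehot_condition`` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._mlp import SGD, Adam, Sequential, make_mlp, mse_loss
from .chemio import Molecule
from .nets import (
    GeneratorModel,
    GoZTConfig,
    assemble_batch,
    build_generator,
    forward,
    predict_activity,
    weighted_sum,
)
from .toxdata import DEFAULT_THRESHOLD, N_ENDPOINTS, ActivityCall, ToxicityMatrix
from .views import ViewConfig, ViewSet, ViewTensor, pad_to_tensor

log = logging.getLogger(__name__)

__all__ = ["GANConfig", "Discriminator", "discriminate", "train_gan", "predict_activity_gan"]

DIVERGENCE_LIMIT = 1e6


@dataclass
class GANConfig:
    """Adversarial-training hyperparameters.

    The generator config is shared with Go-ZT (same 3 feature / 11
    toxicity hidden layers), so both models have identical generator
    parameter counts for identical settings.
    """

    generator: GoZTConfig = field(default_factory=GoZTConfig)
    disc_hidden_layers: int = 3
    disc_width: int = 128
    disc_learning_rate: float = 1e-3  # Adam
    gen_learning_rate: float | None = None  # SGD; defaults to generator.learning_rate
    epochs: int = 2000
    batch_size: int = 32
    onehot_condition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.gen_learning_rate is None:
            self.gen_learning_rate = self.generator.learning_rate


@dataclass
class Discriminator:
    net: Sequential
    n_condition: int  # length of the conditioning vector (s or one-hot)

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_discriminator(cfg: GANConfig, n_condition: int, rng: np.random.Generator) -> Discriminator:
    net = make_mlp(
        n_in=n_condition + N_ENDPOINTS,
        hidden=[cfg.disc_width] * cfg.disc_hidden_layers,
        n_out=1,
        rng=rng,
        batchnorm=cfg.generator.batchnorm,
        output_activation="linear",
    )
    return Discriminator(net=net, n_condition=n_condition)


def discriminate(
    d: Discriminator, s: np.ndarray, t: np.ndarray, train: bool = False
) -> np.ndarray:
    """Realness scores for (conditioning, toxicity-matrix) pairs."""
    s = np.atleast_2d(np.asarray(s, dtype=float))
    t = np.atleast_2d(np.asarray(t, dtype=float))
    if s.shape[1] != d.n_condition or t.shape[1] != N_ENDPOINTS:
        raise ValueError(
            f"discriminator expects condition dim {d.n_condition} + "
            f"{N_ENDPOINTS} endpoints, got {s.shape[1]} + {t.shape[1]}"
        )
    return d.net.forward(np.concatenate([s, t], axis=1), train=train)[:, 0]


def train_gan(
    data: list[tuple[ViewSet | ViewTensor, ToxicityMatrix]], cfg: GANConfig
) -> tuple[GeneratorModel, Discriminator, dict[str, list[float]]]:
    """Alternating least-squares GAN training.

    Returns the trained generator, the discriminator, and per-epoch
    ``{"generator": [...], "discriminator": [...]}`` loss traces.
    Deterministic given ``cfg.seed``; aborts if either loss diverges.
    """
    if len(data) < 2:
        raise ValueError("training needs at least two chemicals")
    gcfg = cfg.generator
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gcfg, rng)
    tensors = [
        t if isinstance(t, ViewTensor) else pad_to_tensor(t, gcfg.max_atoms)
        for t, _ in data
    ]
    real = np.stack([tm.incidence for _, tm in data])
    n = len(data)
    n_cond = n if cfg.onehot_condition else gcfg.feature_dim
    disc = build_discriminator(cfg, n_cond, rng)
    onehot = np.eye(n) if cfg.onehot_condition else None

    g_opt = SGD(gen.feature_net.params + gen.toxicity_net.params, lr=cfg.gen_learning_rate)
    d_opt = Adam(disc.net.params, lr=cfg.disc_learning_rate)
    traces: dict[str, list[float]] = {"generator": [], "discriminator": []}

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_loss_sum = g_loss_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [tensors[i] for i in idx]
            m = len(idx)

            # ---- discriminator step (generator frozen) --------------------
            X, w, seg = assemble_batch(batch)
            F = gen.feature_net.forward(X, train=False)
            S = weighted_sum(F, w, seg, m)
            fake = gen.toxicity_net.forward(S, train=False)
            cond = onehot[idx] if onehot is not None else S
            inp = np.concatenate(
                [
                    np.concatenate([cond, real[idx]], axis=1),
                    np.concatenate([cond, fake], axis=1),
                ]
            )
            target = np.concatenate([np.ones(m), np.zeros(m)])[:, None]
            score = disc.net.forward(inp, train=True)
            d_loss, dscore = mse_loss(score, target)
            disc.net.zero_grad()
            disc.net.backward(dscore)
            d_opt.step()

            # ---- generator step (discriminator frozen) --------------------
            F = gen.feature_net.forward(X, train=True)
            S = weighted_sum(F, w, seg, m)
            fake = gen.toxicity_net.forward(S, train=True)
            cond = onehot[idx] if onehot is not None else S
            score = disc.net.forward(np.concatenate([cond, fake], axis=1), train=True)
            g_loss, dscore = mse_loss(score, np.ones((m, 1)))
            disc.net.zero_grad()
            dinp = disc.net.backward(dscore)
            d_fake = dinp[:, n_cond:]
            gen.feature_net.zero_grad()
            gen.toxicity_net.zero_grad()
            dS = gen.toxicity_net.backward(d_fake)
            if onehot is None:
                dS = dS + dinp[:, :n_cond]  # s also conditions the discriminator
            gen.feature_net.backward(dS[seg] * w[:, None])
            disc.net.zero_grad()  # discard discriminator grads from this pass
            g_opt.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)) or max(d_loss, g_loss) > DIVERGENCE_LIMIT:
                raise RuntimeError(
                    f"adversarial training diverged at epoch {epoch} "
                    f"(d_loss={d_loss:.3g}, g_loss={g_loss:.3g}); lower the learning rates"
                )
            d_loss_sum += d_loss * m
            g_loss_sum += g_loss * m
        traces["discriminator"].append(d_loss_sum / n)
        traces["generator"].append(g_loss_sum / n)
    return gen, disc, traces


def predict_activity_gan(
    model: GeneratorModel,
    molecules: list[Molecule],
    view_cfg: ViewConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[ActivityCall], dict[str, str]]:
    """Identical pipeline to Go-ZT prediction, with the adversarial generator."""
    return predict_activity(model, molecules, view_cfg, threshold)
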