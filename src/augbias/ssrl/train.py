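"""Training loops over augmented view pairs, including the dual-composition objective.

A single-composition training is the degenerate case of the dual-objective
trainer (weight_b = 0), so the two are trajectory-identical by construction
when the second branch is switched off.

Per optimization step, each active branch draws its own independently
randomized view pair from its transformation composition, feeds it to its own
loss instance (separate momentum network / queue / target state per branch),
and the weighted sum ``weight_a * loss_a + weight_b * loss_b`` is minimized by
momentum SGD with a cosine learning-rate schedule. All randomness (batch
order, augmentation draws, weight init) derives from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..data import ImageDataset
from ..evalrep import RepresentationSet
from ..nn import SGD, Encoder, EncoderSpec, MLP, Tensor, build_encoder, copy_params, ema_update
from ..rng import child_rng
from ..transforms import TransformComposition, apply_composition
from .losses import METHODS, compute_ssrl_loss

__all__ = ["SSRLConfig", "DualObjectiveConfig", "train_encoder",
           "train_dual_objective", "embed_dataset", "save_encoder", "load_encoder"]


@dataclass
class SSRLConfig:
    method: str = "simclr"
    temperature: float | None = None      # method default when None
    queue_len: int = 256                  # moco_v2
    ema_momentum: float = 0.99            # moco_v2 / byol target network
    vicreg_weights: tuple = (25.0, 25.0, 1.0)
    barlow_lambda: float = 5e-3
    lr: float = 0.25
    sgd_momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown SSRL method {self.method!r}")
        if self.epochs <= 0:
            raise ValueError("epochs must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not 0.0 <= self.ema_momentum < 1.0:
            raise ValueError("ema_momentum must lie in [0, 1)")


@dataclass
class DualObjectiveConfig:
    base: SSRLConfig
    comp_a: TransformComposition
    comp_b: TransformComposition
    weight_a: float = 0.5
    weight_b: float = 0.5

    def __post_init__(self):
        if self.weight_a < 0 or self.weight_b < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.weight_a + self.weight_b <= 0:
            raise ValueError("weight_a + weight_b must be > 0")


class _Branch:
    """Per-composition loss instance: its own target nets and queue state."""

    def __init__(self, comp: TransformComposition, cfg: SSRLConfig,
                 encoder: Encoder, seed: int, tag: str):
        self.comp = comp
        self.cfg = cfg
        self.tag = tag
        self.state: dict = {}
        self.target: Encoder | None = None
        self.predictor: MLP | None = None
        if cfg.method in ("moco_v2", "byol"):
            self.target = build_encoder(encoder.spec, encoder.in_channels,
                                        child_seed_int(seed, "target", tag))
            copy_params(encoder, self.target)
        if cfg.method == "byol":
            d = encoder.spec.projector_dims[-1]
            self.predictor = MLP([d, 2 * d, d],
                                 rng=child_rng(seed, "predictor", tag))

    def loss(self, encoder: Encoder, v1: np.ndarray, v2: np.ndarray):
        cfg = self.cfg
        if cfg.method == "moco_v2":
            q = encoder(Tensor(v1))
            k = self.target(Tensor(v2))  # momentum branch: no gradient flows back
            loss, self.state = compute_ssrl_loss(
                "moco_v2", q, k.detach(), self.state, temperature=cfg.temperature,
                queue_len=cfg.queue_len)
        elif cfg.method == "byol":
            p1 = self.predictor(encoder(Tensor(v1)))
            p2 = self.predictor(encoder(Tensor(v2)))
            t1 = self.target(Tensor(v1)).detach()
            t2 = self.target(Tensor(v2)).detach()
            la, self.state = compute_ssrl_loss("byol", p1, t2, self.state)
            lb, self.state = compute_ssrl_loss("byol", p2, t1, self.state)
            loss = (la + lb) * 0.5
        else:
            z1 = encoder(Tensor(v1))
            z2 = encoder(Tensor(v2))
            loss, self.state = compute_ssrl_loss(
                cfg.method, z1, z2, self.state, temperature=cfg.temperature,
                vicreg_weights=cfg.vicreg_weights, barlow_lambda=cfg.barlow_lambda)
        return loss

    def post_step(self, encoder: Encoder):
        if self.target is not None:
            ema_update(encoder, self.target, self.cfg.ema_momentum)

    def extra_parameters(self):
        return self.predictor.parameters() if self.predictor is not None else []


def child_seed_int(seed: int, *keys) -> int:
    from ..rng import child_seed

    return child_seed(seed, *keys)


def _make_views(images: np.ndarray, comp: TransformComposition,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two stacked augmented views of an (N,H,W,C) batch, as float32 NCHW."""
    v1, v2 = [], []
    for img in images:
        v1.append(apply_composition(img, comp, rng))
        v2.append(apply_composition(img, comp, rng))
    a = np.stack(v1).transpose(0, 3, 1, 2).astype(np.float32)
    b = np.stack(v2).transpose(0, 3, 1, 2).astype(np.float32)
    return a, b


def train_dual_objective(dataset: ImageDataset, enc: EncoderSpec,
                         dual: DualObjectiveConfig) -> tuple[Encoder, pd.DataFrame]:
    """Minimize ``weight_a * loss_a + weight_b * loss_b`` over view pairs.

    Returns the frozen encoder and a per-epoch log with columns
    (epoch, loss_a, loss_b, total, lr). Branches with zero weight are skipped
    entirely — no views drawn, no state kept — so ``weight_b = 0`` reproduces a
    single-composition training exactly.
    """
    cfg = dual.base
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images = dataset.images
    n = len(images)
    encoder = build_encoder(enc, dataset.n_channels, child_seed_int(cfg.seed, "init"))

    branches: list[tuple[str, float, _Branch]] = []
    if dual.weight_a > 0:
        branches.append(("a", dual.weight_a,
                         _Branch(dual.comp_a, cfg, encoder, cfg.seed, "a")))
    if dual.weight_b > 0:
        branches.append(("b", dual.weight_b,
                         _Branch(dual.comp_b, cfg, encoder, cfg.seed, "b")))

    params = encoder.parameters()
    for _, _, br in branches:
        params = params + br.extra_parameters()
    opt = SGD(params, lr=cfg.lr, momentum=cfg.sgd_momentum,
              weight_decay=cfg.weight_decay)

    steps_per_epoch = max(1, n // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    rows = []
    step = 0
    for epoch in range(cfg.epochs):
        order = child_rng(cfg.seed, "order", epoch).permutation(n)
        sums = {"a": 0.0, "b": 0.0}
        for s in range(steps_per_epoch):
            batch_idx = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
            if len(batch_idx) < 2:
                continue
            opt.lr = 0.5 * cfg.lr * (1.0 + np.cos(np.pi * step / max(total_steps, 1)))
            opt.zero_grad()
            total = None
            for tag, weight, br in branches:
                aug_rng = child_rng(cfg.seed, "aug", tag, epoch, s)
                v1, v2 = _make_views(images[batch_idx], br.comp, aug_rng)
                loss = br.loss(encoder, v1, v2)
                sums[tag] += float(loss.data)
                term = loss * weight
                total = term if total is None else total + term
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {s}")
            total.backward()
            opt.step()
            for _, _, br in branches:
                br.post_step(encoder)
            step += 1
        rows.append({
            "epoch": epoch,
            "loss_a": sums["a"] / steps_per_epoch,
            "loss_b": sums["b"] / steps_per_epoch,
            "total": sum(w * sums[t] for t, w, _ in branches) / steps_per_epoch,
            "lr": opt.lr,
        })
    return encoder, pd.DataFrame(rows)


def train_encoder(dataset: ImageDataset, enc: EncoderSpec, cfg: SSRLConfig,
                  comp: TransformComposition) -> tuple[Encoder, pd.DataFrame]:
    """Single-composition SSRL training (dual objective with branch b off)."""
    dual = DualObjectiveConfig(base=cfg, comp_a=comp, comp_b=comp,
                               weight_a=1.0, weight_b=0.0)
    return train_dual_objective(dataset, enc, dual)


def save_encoder(encoder: Encoder, path: str):
    """Checkpoint: parameter arrays + norm statistics + a JSON header."""
    import json

    from ..nn.layers import BatchNorm2d

    header = {"architecture": encoder.spec.architecture,
              "embedding_dim": encoder.spec.embedding_dim,
              "projector_dims": list(encoder.spec.projector_dims),
              "in_channels": encoder.in_channels}
    arrays = {f"p{i}": a for i, a in enumerate(encoder.state_arrays())}
    bns = [m for m in encoder.walk() if isinstance(m, BatchNorm2d)]
    for i, bn in enumerate(bns):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_encoder(path: str) -> Encoder:
    import json

    from ..nn.layers import BatchNorm2d

    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        spec = EncoderSpec(architecture=header["architecture"],
                           embedding_dim=header["embedding_dim"],
                           projector_dims=header["projector_dims"])
        encoder = build_encoder(spec, header["in_channels"], seed=0)
        n = len(encoder.state_arrays())
        encoder.load_state_arrays([z[f"p{i}"] for i in range(n)])
        bns = [m for m in encoder.walk() if isinstance(m, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = z[f"bn{i}_mean"]
            bn.running_var = z[f"bn{i}_var"]
    return encoder


def embed_dataset(encoder: Encoder, dataset: ImageDataset) -> RepresentationSet:
    """Pre-projector embeddings of un-augmented images, in dataset order."""
    z = encoder.embed_numpy(dataset.as_nchw())
    return RepresentationSet(
        embeddings=z,
        labels=dataset.labels,
        aux_labels=dataset.aux_labels,
        provenance={"dataset": dataset.meta.get("generator", "unknown"),
                    "architecture": encoder.spec.architecture,
                    "embedding_dim": encoder.spec.embedding_dim},
    )
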