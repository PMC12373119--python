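"""Adversarial training of the colorization GAN.

Per batch the discriminator takes one update on real and generated chroma,
then the generator takes one update (two for the generator-iteration
variant) against the frozen discriminator.  Losses follow the standard
conditional-GAN objective:

* discriminator, on probabilities ``D``:
  ``L_D = -(1/N) Σ [log D(x_i) + log(1 - D(G(L_i)))]``
* generator: ``L_G = -(1/N) Σ log D(G(L_i)) + λ · (1/N) Σ |G(L_i) - C_i|₁``

with the L1 term reduced as a mean over batch, channels and pixels so that
``λ`` (default 100) is resolution-independent.  Inside the loop both
cross-entropy terms are computed in the numerically stable logit form
(softplus), never through an explicit log of a probability.

Three model variants are supported: 1 — plain U-Net; 2 — U-Net with CBAM;
3 — U-Net with CBAM and two generator updates per discriminator update.
Runs are bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .colorspace import normalize_lab, rgb_to_lab
from .models import PatchDiscriminator, UNetGenerator
from .nn import Adam, sigmoid

__all__ = [
    "TrainingConfig",
    "PairedSample",
    "TrainResult",
    "discriminator_loss",
    "generator_loss",
    "train",
    "fine_tune",
    "save_checkpoint",
    "load_checkpoint",
]

_F32 = np.float32


@dataclass
class PairedSample:
    """One phase-contrast / fluorescence image pair (8-bit RGB, same size)."""

    id: str
    phase: np.ndarray
    fluor: np.ndarray

    def __post_init__(self) -> None:
        if self.phase.shape != self.fluor.shape:
            raise ValueError(f"pair {self.id}: phase/fluorescence shapes differ")


@dataclass
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 4
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    l1_weight: float = 100.0
    model_variant: int = 2
    seed: int = 0
    img_size: int = 64
    gen_base: int = 16
    disc_base: int = 16
    cbam_reduction: int = 16
    condition_on_l: bool = True  # discriminator sees L‖ab; False: ab only

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be ≥ 1")
        if self.l1_weight < 0:
            raise ValueError("L1 weight λ must be ≥ 0")
        if self.model_variant not in (1, 2, 3):
            raise ValueError("model_variant must be 1, 2 or 3")

    @property
    def use_cbam(self) -> bool:
        return self.model_variant >= 2

    @property
    def gen_updates_per_batch(self) -> int:
        return 2 if self.model_variant == 3 else 1


@dataclass
class TrainResult:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: TrainingConfig
    history: list[dict] = field(default_factory=list)
    g_updates: int = 0
    d_updates: int = 0

    def epoch_mean(self, key: str, epoch: int) -> float:
        vals = [h[key] for h in self.history if h["epoch"] == epoch and key in h]
        return float(np.mean(vals))


def discriminator_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """Binary cross-entropy of the discriminator on probability scores.

    Real samples carry label 1, generated samples label 0; both terms are
    averaged over the batch (and any patch dimensions).
    """
    real = np.asarray(real_scores, dtype=float)
    fake = np.asarray(fake_scores, dtype=float)
    if real.size == 0 or fake.size == 0:
        raise ValueError("empty batch")
    return float(-(np.log(real).mean() + np.log1p(-fake).mean()))


def generator_loss(
    fake_scores: np.ndarray,
    generated_ab: np.ndarray,
    target_ab: np.ndarray,
    l1_weight: float = 100.0,
) -> tuple[float, float, float]:
    """Return ``(total, adversarial, l1)`` generator losses.

    Adversarial: ``-mean log D(G(L))``; L1: mean absolute deviation between
    generated and target chroma; total = adversarial + λ·L1.
    """
    if l1_weight < 0:
        raise ValueError("L1 weight λ must be ≥ 0")
    fake = np.asarray(fake_scores, dtype=float)
    if fake.size == 0:
        raise ValueError("empty batch")
    gen = np.asarray(generated_ab, dtype=float)
    tgt = np.asarray(target_ab, dtype=float)
    if gen.shape != tgt.shape:
        raise ValueError("generated and target chroma misaligned")
    adv = float(-np.log(fake).mean())
    l1 = float(np.abs(gen - tgt).mean())
    return adv + l1_weight * l1, adv, l1


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _prepare(dataset: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Convert image pairs to normalized (L, ab) training tensors."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    shapes = {s.phase.shape for s in dataset}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent image sizes across dataset: {shapes}")
    xs, ys = [], []
    for s in dataset:
        lab_p = normalize_lab(rgb_to_lab(s.phase))
        lab_f = normalize_lab(rgb_to_lab(s.fluor))
        xs.append(lab_p.L[None].astype(_F32))
        ys.append(np.stack([lab_f.a, lab_f.b]).astype(_F32))
    return np.stack(xs), np.stack(ys)


def _d_step(gen, disc, opt_d, L, ab_real, cond):
    fake = gen.forward(L, train=False)
    z_r = disc.forward(cond, ab_real, train=True)
    opt_d.zero_grad()
    disc.backward(((sigmoid(z_r) - 1.0) / z_r.size).astype(_F32))
    loss = _softplus(-z_r).mean()
    z_f = disc.forward(cond, fake, train=True)
    disc.backward((sigmoid(z_f) / z_f.size).astype(_F32))
    loss += _softplus(z_f).mean()
    opt_d.step()
    return float(loss)


def _g_step(gen, disc, opt_g, opt_d, L, ab_real, cond, lam):
    fake = gen.forward(L, train=True)
    z_f = disc.forward(cond, fake, train=True)
    adv = float(_softplus(-z_f).mean())
    d_in = disc.backward(((sigmoid(z_f) - 1.0) / z_f.size).astype(_F32))
    d_ab = d_in[:, -2:]  # chroma part of the discriminator input gradient
    diff = fake - ab_real
    l1 = float(np.abs(diff).mean())
    d_l1 = (lam * np.sign(diff) / diff.size).astype(_F32)
    opt_g.zero_grad()
    opt_d.zero_grad()  # discard spillover grads from the frozen discriminator
    gen.backward(d_ab + d_l1)
    opt_g.step()
    return adv, l1


def _run_epochs(gen, disc, opt_g, opt_d, X, Y, cfg, rng, result, epoch0=0):
    n = X.shape[0]
    for epoch in range(epoch0, epoch0 + cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            L, ab_real = X[idx], Y[idx]
            cond = L if cfg.condition_on_l else None
            d_loss = _d_step(gen, disc, opt_d, L, ab_real, cond)
            result.d_updates += 1
            for _ in range(cfg.gen_updates_per_batch):
                adv, l1 = _g_step(gen, disc, opt_g, opt_d, L, ab_real, cond, cfg.l1_weight)
                result.g_updates += 1
            result.history.append(
                {
                    "epoch": epoch,
                    "step": start // cfg.batch_size,
                    "d_loss": d_loss,
                    "g_adv": adv,
                    "g_l1": l1,
                    "g_total": adv + cfg.l1_weight * l1,
                }
            )


def _build_nets(cfg: TrainingConfig, rng: np.random.Generator):
    gen = UNetGenerator(
        img_size=cfg.img_size,
        base=cfg.gen_base,
        use_cbam=cfg.use_cbam,
        cbam_reduction=cfg.cbam_reduction,
        rng=rng,
    )
    disc = PatchDiscriminator(
        in_ch=3 if cfg.condition_on_l else 2, base=cfg.disc_base, rng=rng
    )
    return gen, disc


def train(dataset: list[PairedSample], cfg: TrainingConfig) -> TrainResult:
    """Train a colorization GAN from scratch on paired images."""
    X, Y = _prepare(dataset)
    if X.shape[-1] != cfg.img_size:
        raise ValueError(
            f"dataset images are {X.shape[-1]}px but config expects {cfg.img_size}px"
        )
    rng = np.random.default_rng(cfg.seed)
    gen, disc = _build_nets(cfg, rng)
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas)
    result = TrainResult(gen, disc, cfg)
    _run_epochs(gen, disc, opt_g, opt_d, X, Y, cfg, rng, result)
    return result


def fine_tune(
    model: TrainResult,
    original_dataset: list[PairedSample],
    new_batch: list[PairedSample],
    fraction: float = 1.0 / 3.0,
    cfg: TrainingConfig | None = None,
) -> tuple[TrainResult, list[str]]:
    """Adapt a trained model to a new differentiation batch.

    Continues training on the original training set mixed with
    ``floor(fraction · |new_batch|)`` images drawn from the new batch; the
    remaining new-batch images stay held out.  Returns the updated model and
    the ids of the new-batch images that entered the training pool.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cfg = cfg or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    k = int(np.floor(fraction * len(new_batch)))
    chosen = list(rng.permutation(len(new_batch))[:k])
    pool = list(original_dataset) + [new_batch[i] for i in chosen]
    X, Y = _prepare(pool)
    gen, disc = model.generator, model.discriminator
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas)
    result = TrainResult(gen, disc, cfg, g_updates=model.g_updates,
                         d_updates=model.d_updates)
    _run_epochs(gen, disc, opt_g, opt_d, X, Y, cfg, rng, result)
    return result, [new_batch[i].id for i in chosen]


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    """Persist generator + discriminator parameters and config (npz + json)."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(result.generator.parameters()):
        arrays[f"g{i}"] = p.value
    for i, p in enumerate(result.discriminator.parameters()):
        arrays[f"d{i}"] = p.value
    cfg = asdict(result.config)
    cfg["betas"] = list(cfg["betas"])
    arrays["config_json"] = np.frombuffer(
        json.dumps({"version": 1, "config": cfg}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["config_json"]).decode())
    cfgd = meta["config"]
    cfgd["betas"] = tuple(cfgd["betas"])
    cfg = TrainingConfig(**cfgd)
    gen, disc = _build_nets(cfg, np.random.default_rng(cfg.seed))
    for i, p in enumerate(gen.parameters()):
        p.value[...] = data[f"g{i}"]
    for i, p in enumerate(disc.parameters()):
        p.value[...] = data[f"d{i}"]
    return TrainResult(gen, disc, cfg)
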