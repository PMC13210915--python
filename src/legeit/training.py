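"""WGAN-GP alternating optimization of critic and generator.

Reference hyperparameters: batch 16, 120 epochs, generator lr 1e-4,
critic lr 4e-4, Adam(0.5, 0.999), n_critic = 5, gradient penalty 10,
gradient clipping at global norm 1, cosine annealing of both learning
rates to 1e-6, Kaiming init for the generator and N(0, 0.02) for the
critic.  Model selection keeps the checkpoint with the best validation
SSIM.  Desk-scale runs shrink the dataset/epochs/channels, never the
update rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import losses, metrics, nn, phantoms
from .autodiff import Tensor, no_grad
from .network import BAM, BAMR2UNet, GeneratorConfig, PatchCritic

__all__ = ["TrainConfig", "Checkpoint", "initialize", "cosine_lr",
           "train_step", "fit", "FitResult"]


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 120
    lr_g: float = 1e-4
    lr_d: float = 4e-4
    adam_betas: tuple = (0.5, 0.999)
    n_critic: int = 5
    lambda_gp: float = 10.0
    base_channels: int = 32
    critic_base_channels: int = 64
    t: int = 2
    grad_clip_norm: float = 1.0
    lr_min: float = 1e-6
    seed: int = 0
    augment: bool = True
    augment_noise_std: float = 0.01

    def __post_init__(self):
        if self.n_critic < 1 or self.epochs < 1:
            raise ValueError("n_critic and epochs must be >= 1")


@dataclass
class Checkpoint:
    epoch: int
    generator_state: dict
    critic_state: dict
    val_rmse: float
    val_ssim: float


@dataclass
class FitResult:
    best: Checkpoint
    history: "object"            # pandas DataFrame of per-epoch records
    step_log: "object"           # pandas DataFrame of per-step loss components
    generator: BAMR2UNet
    critic: PatchCritic


def initialize(generator: BAMR2UNet, critic: PatchCritic, seed: int = 0):
    """Kaiming-normal generator init; N(0, 0.02) critic init.

    BAM fusion scalars stay at 0.5/0.3/0.2 and the edge-branch kernels at
    the Laplacian stencil; biases and norm parameters keep their zeros/ones.
    """
    rng_g = np.random.default_rng(seed)
    rng_d = np.random.default_rng(seed + 1)
    skip = set()
    for m in generator.modules():
        if isinstance(m, BAM):
            skip.add(id(m.alpha))
            skip.add(id(m.beta))
            skip.add(id(m.gamma))
            if m.use_edge:
                skip.add(id(m.e_conv.weight))
    for name, p in generator.named_parameters():
        if id(p) in skip:
            continue
        if p.ndim >= 2 and ("weight" in name.split(".")[-1]):
            nn.kaiming_normal_(p, rng_g, negative_slope=0.2)
    for name, p in critic.named_parameters():
        if p.ndim >= 2 and name.endswith("weight"):
            nn.normal_(p, rng_d, 0.0, 0.02)
    return generator, critic


def cosine_lr(epoch: int, epochs: int, lr0: float, lr_min: float) -> float:
    """Cosine annealing from lr0 (epoch 0) to lr_min (final epoch)."""
    if epochs == 1:
        return lr0
    frac = epoch / (epochs - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + math.cos(math.pi * frac))


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for s in range(0, n - batch_size + 1, batch_size):
        yield idx[s:s + batch_size]


def _prep_batch(htv_in, cond, ids, cfg: TrainConfig, rng):
    xs, ys = [], []
    for i in ids:
        x, y = htv_in[i], cond[i]
        if cfg.augment:
            x, y = phantoms.augment(x, y, int(rng.integers(2 ** 31)),
                                    noise_std=cfg.augment_noise_std)
        xs.append(x)
        ys.append(y)
    xb = np.stack(xs)[:, None].astype(np.float32)
    yb = np.stack(ys)[:, None].astype(np.float32)
    return Tensor(xb), Tensor(yb)


def train_step(generator, critic, opt_g, opt_d, batch_iter, cfg: TrainConfig,
               weights: losses.LossWeights, masks, rng, log: list):
    """n_critic critic updates followed by one generator update."""
    record = {}
    for k in range(cfg.n_critic):
        x, y = next(batch_iter)
        with no_grad():
            fake = Tensor(generator(x).data)
        d_loss, comps = losses.critic_objective(
            critic, x, y, fake, cfg.lambda_gp, seed=int(rng.integers(2 ** 31)))
        if not np.isfinite(d_loss.item()):
            raise FloatingPointError(f"critic loss non-finite: {comps}")
        critic.zero_grad()
        d_loss.backward()
        norm_d = nn.clip_grad_norm_(critic.parameters(), cfg.grad_clip_norm)
        opt_d.step()
        record.update({"d_loss": d_loss.item(), "d_grad_norm": norm_d, **comps})
    x, y = next(batch_iter)
    fake = generator(x)
    g_loss, gcomps = losses.generator_objective(critic, x, fake, y,
                                                weights, masks)
    if not np.isfinite(g_loss.item()):
        raise FloatingPointError(f"generator loss non-finite: {gcomps}")
    generator.zero_grad()
    critic.zero_grad()
    g_loss.backward()
    norm_g = nn.clip_grad_norm_(generator.parameters(), cfg.grad_clip_norm)
    opt_g.step()
    critic.zero_grad()   # drop adversarial-term gradients left on the critic
    record.update({"g_loss": g_loss.item(), "g_grad_norm": norm_g,
                   **{f"g_{k}": v for k, v in gcomps.items()}})
    log.append(record)
    return record


def _validate(generator, htv_in, cond, ids, batch=16):
    generator.eval()
    r, s = [], []
    for start in range(0, len(ids), batch):
        sel = ids[start:start + batch]
        xb = Tensor(np.asarray(htv_in[sel], np.float32)[:, None])
        with no_grad():
            out = generator(xb).data[:, 0]
        for o, t in zip(out, cond[sel]):
            r.append(metrics.rmse(o, t))
            s.append(metrics.ssim(o, t))
    generator.train()
    return float(np.mean(r)), float(np.mean(s))


def fit(dataset, split, cfg: TrainConfig | None = None,
        weights: losses.LossWeights | None = None,
        generator: BAMR2UNet | None = None,
        critic: PatchCritic | None = None,
        verbose: bool = False) -> FitResult:
    """Train on ``split.train``, select the best-validation-SSIM checkpoint."""
    cfg = cfg or TrainConfig()
    weights = weights or losses.LossWeights(lambda_gp=cfg.lambda_gp)
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("empty train or validation split")
    if len(dataset.htv_input) != len(dataset.conductivity):
        raise ValueError("dataset lacks HTV pre-reconstructions")
    g = dataset.grid_size
    masks = losses.layer_masks(g)
    if generator is None:
        generator = BAMR2UNet(GeneratorConfig(base_channels=cfg.base_channels,
                                              t=cfg.t, seed=cfg.seed))
    if critic is None:
        critic = PatchCritic(base_channels=cfg.critic_base_channels)
    initialize(generator, critic, seed=cfg.seed)
    opt_g = nn.Adam(generator.parameters(), cfg.lr_g, cfg.adam_betas)
    opt_d = nn.Adam(critic.parameters(), cfg.lr_d, cfg.adam_betas)
    rng = np.random.default_rng(cfg.seed + 17)

    htv_in = dataset.htv_input
    cond = dataset.conductivity
    train_ids = np.asarray(split.train)
    history = []
    best = None
    step_log: list = []
    for epoch in range(cfg.epochs):
        lr_g = cosine_lr(epoch, cfg.epochs, cfg.lr_g, cfg.lr_min)
        lr_d = cosine_lr(epoch, cfg.epochs, cfg.lr_d, cfg.lr_min)
        opt_g.lr, opt_d.lr = lr_g, lr_d

        def batch_gen():
            while True:
                for ids in _batches(len(train_ids), cfg.batch_size, rng):
                    yield _prep_batch(htv_in, cond, train_ids[ids], cfg, rng)

        it = batch_gen()
        # one generator update per batch-sized chunk of the training set;
        # critic batches are drawn cyclically from the same shuffled stream
        steps = max(len(train_ids) // cfg.batch_size, 1)
        for _ in range(steps):
            rec = train_step(generator, critic, opt_g, opt_d, it, cfg,
                             weights, masks, rng, step_log)
        val_rmse, val_ssim = _validate(generator, htv_in, cond,
                                       np.asarray(split.val))
        history.append({"epoch": epoch, "lr_g": lr_g, "lr_d": lr_d,
                        "val_rmse": val_rmse, "val_ssim": val_ssim,
                        **{k: rec[k] for k in ("d_loss", "g_loss")}})
        if verbose:
            print(f"epoch {epoch:3d} lr_g {lr_g:.2e} val_rmse {val_rmse:.4f} "
                  f"val_ssim {val_ssim:.4f}", flush=True)
        if best is None or val_ssim > best.val_ssim:
            best = Checkpoint(epoch, generator.state_dict(),
                              critic.state_dict(), val_rmse, val_ssim)
    import pandas as pd
    return FitResult(best=best, history=pd.DataFrame(history),
                     step_log=pd.DataFrame(step_log),
                     generator=generator, critic=critic)


def save_checkpoint(ckpt: Checkpoint, path):
    gen = {f"g::{k}": v for k, v in ckpt.generator_state.items()}
    cri = {f"d::{k}": v for k, v in ckpt.critic_state.items()}
    np.savez(path, __epoch=ckpt.epoch, __val_rmse=ckpt.val_rmse,
             __val_ssim=ckpt.val_ssim, **gen, **cri)


def load_checkpoint(path) -> Checkpoint:
    z = np.load(path)
    gen = {k[3:]: z[k] for k in z.files if k.startswith("g::")}
    cri = {k[3:]: z[k] for k in z.files if k.startswith("d::")}
    return Checkpoint(int(z["__epoch"]), gen, cri,
                      float(z["__val_rmse"]), float(z["__val_ssim"]))
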