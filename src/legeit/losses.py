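"""Anatomy-prior composite loss and WGAN-GP objectives.

The generator is trained with a six-term prior loss tailored to the
concentric anatomy of a leg cross-section,

    L_total = l_pix L_pix + l_edge L_edge + l_layer L_layer
            + l_tv L_tv + l_ssim L_ssim + l_hist L_hist

with default weights 100/30/20/5/10/2, plus the Wasserstein adversarial
term.  All paired terms vanish at pred == truth.  Norms are mean-reduced
per image and averaged over the batch by default (keeps the weights
scale-comparable across resolutions); ``reduction="sum"`` recovers the
bare-norm form.

The critic loss is the standard WGAN-GP objective
E[D(x, G(x))] - E[D(x, y)] + l_gp E[(||grad_y D(x, y~)|| - 1)^2] with y~
uniform convex interpolates between real and fake samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, no_grad
from .nn import conv2d
from .phantoms import GRID_SIZE, LEG_RADIUS_PX

__all__ = [
    "LossWeights", "layer_masks", "pixel_loss", "edge_loss", "layer_loss",
    "tv_loss", "ssim_loss", "hist_loss", "total_loss", "critic_objective",
    "generator_objective", "gradient_penalty", "SOBEL_X", "SOBEL_Y",
    "gaussian_window",
]


@dataclass(frozen=True)
class LossWeights:
    """Prior-term weights and the gradient-penalty coefficient."""
    lambda_pix: float = 100.0
    lambda_edge: float = 30.0
    lambda_layer: float = 20.0
    lambda_tv: float = 5.0
    lambda_ssim: float = 10.0
    lambda_hist: float = 2.0
    lambda_gp: float = 10.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
SOBEL_Y = SOBEL_X.T.copy()


def layer_masks(grid_size: int = GRID_SIZE,
                radius: float | None = None) -> dict[str, np.ndarray]:
    """Concentric ring masks (skin/fat/muscle/core) partitioning the disc.

    With leg radius R: skin R-3 <= d < R, fat R-10 <= d < R-3,
    muscle 0.35R <= d < R-10, core d < 0.35R.  Ring widths are in pixels of
    the reference 64x64 grid and scale with grid size.
    """
    R = radius if radius is not None else LEG_RADIUS_PX * grid_size / GRID_SIZE
    s = grid_size / GRID_SIZE
    c = (grid_size - 1) / 2.0
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    d = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    disc = d < R
    skin = (d >= R - 3 * s) & disc
    fat = (d >= R - 10 * s) & (d < R - 3 * s)
    core = d < 0.35 * R
    muscle = (d >= 0.35 * R) & (d < R - 10 * s)
    return {"skin": skin, "fat": fat, "muscle": muscle, "core": core}


def _prep(pred, truth):
    p, t = as_tensor(pred), as_tensor(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim == 2:
        p = p.reshape(1, 1, *p.shape)
        t = t.reshape(1, 1, *t.shape)
    elif p.ndim == 3:
        p = p.reshape(p.shape[0], 1, *p.shape[1:])
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    return p, t


def _reduce(x: Tensor, n_per_image: int, reduction: str) -> Tensor:
    total = x.sum()
    if reduction == "sum":
        return total
    batch = x.shape[0] if x.ndim >= 3 else 1
    return total * (1.0 / (n_per_image * batch))


def pixel_loss(pred, truth, reduction: str = "mean") -> Tensor:
    """L1 + 0.5 L2^2 pixel fidelity."""
    p, t = _prep(pred, truth)
    d = p - t
    n = int(np.prod(p.shape[1:]))
    return _reduce(d.abs(), n, reduction) + 0.5 * _reduce(d * d, n, reduction)


def _sobel_mag(x: Tensor, eps: float = 1e-8) -> Tensor:
    kx = Tensor(SOBEL_X.reshape(1, 1, 3, 3))
    ky = Tensor(SOBEL_Y.reshape(1, 1, 3, 3))
    gx = conv2d(x, kx, padding=1)
    gy = conv2d(x, ky, padding=1)
    return (gx * gx + gy * gy + eps).sqrt()


def edge_loss(pred, truth, reduction: str = "mean") -> Tensor:
    """L1 distance between Sobel gradient-magnitude maps."""
    p, t = _prep(pred, truth)
    d = (_sobel_mag(p) - _sobel_mag(t)).abs()
    return _reduce(d, int(np.prod(p.shape[1:])), reduction)


def layer_loss(pred, truth, masks: dict[str, np.ndarray] | None = None) -> Tensor:
    """Sum over the four rings of |mean(pred*M_k) - mean(truth*M_k)|."""
    p, t = _prep(pred, truth)
    masks = masks or layer_masks(p.shape[-1])
    out = None
    for name, m in masks.items():
        cnt = int(m.sum())
        if cnt == 0:
            import warnings
            warnings.warn(f"empty layer mask {name!r}; ring skipped")
            continue
        mt = Tensor(m.astype(np.float32).reshape(1, 1, *m.shape))
        scale = 1.0 / cnt
        term = (((p * mt).sum(axis=(1, 2, 3)) - (t * mt).sum(axis=(1, 2, 3)))
                * scale).abs().mean()
        out = term if out is None else out + term
    return out if out is not None else Tensor(np.float32(0.0))


def tv_loss(pred, reduction: str = "mean") -> Tensor:
    """Anisotropic total variation with forward differences, no wraparound."""
    p = as_tensor(pred)
    if p.ndim == 2:
        p = p.reshape(1, 1, *p.shape)
    h, w = p.shape[-2], p.shape[-1]
    dh = (p.slice_((Ellipsis, slice(1, None), slice(None)))
          - p.slice_((Ellipsis, slice(None, -1), slice(None)))).abs()
    dw = (p.slice_((Ellipsis, slice(None), slice(1, None)))
          - p.slice_((Ellipsis, slice(None), slice(None, -1)))).abs()
    total = dh.sum() + dw.sum()
    if reduction == "sum":
        return total
    batch = p.shape[0]
    return total * (1.0 / (batch * h * w))


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(np.float32)


def _ssim_map(p: Tensor, t: Tensor, dynamic_range: float,
              window: np.ndarray) -> Tensor:
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    k = Tensor(window.reshape(1, 1, *window.shape))
    mu_p = conv2d(p, k)
    mu_t = conv2d(t, k)
    mu_pp = conv2d(p * p, k)
    mu_tt = conv2d(t * t, k)
    mu_pt = conv2d(p * t, k)
    var_p = mu_pp - mu_p * mu_p
    var_t = mu_tt - mu_t * mu_t
    cov = mu_pt - mu_p * mu_t
    num = (2.0 * mu_p * mu_t + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_t * mu_t + c1) * (var_p + var_t + c2)
    return num / den


def ssim_loss(pred, truth, dynamic_range: float = 2.0,
              window_size: int = 11, sigma: float = 1.5) -> Tensor:
    """1 - mean SSIM over valid Gaussian windows (11 taps, sigma 1.5)."""
    p, t = _prep(pred, truth)
    if p.shape[-1] < window_size or p.shape[-2] < window_size:
        raise ValueError(f"image smaller than the {window_size}-tap SSIM window")
    w = gaussian_window(window_size, sigma)
    return 1.0 - _ssim_map(p, t, dynamic_range, w).mean()


def hist_loss(pred, truth, reduction: str = "mean") -> Tensor:
    """L1 distance between ascending-sorted pixel vectors (per image)."""
    p, t = _prep(pred, truth)
    if p.size != t.size:
        raise ValueError("pixel-count mismatch")
    n_img = int(np.prod(p.shape[1:]))
    batch = p.shape[0]
    out = None
    for b in range(batch):
        pb = p.slice_((b,)).reshape(n_img)
        tb = t.slice_((b,)).reshape(n_img)
        ip = np.argsort(pb.data, kind="stable")
        it = np.argsort(tb.data, kind="stable")
        d = (pb.take(ip) - tb.take(it)).abs().sum()
        out = d if out is None else out + d
    if reduction == "sum":
        return out
    return out * (1.0 / (batch * n_img))


def total_loss(pred, truth, weights: LossWeights | None = None,
               masks: dict[str, np.ndarray] | None = None,
               reduction: str = "mean"):
    """Weighted six-term prior loss; returns (total, components dict).

    ``reduction`` applies to the four norm-valued terms (pixel, edge, TV,
    histogram): "mean" normalizes per pixel, "sum" is the bare-norm form
    used by the training objective; the layer and SSIM terms are O(1) by
    construction either way.
    """
    w = weights or LossWeights()
    comps = {
        "pix": pixel_loss(pred, truth, reduction),
        "edge": edge_loss(pred, truth, reduction),
        "layer": layer_loss(pred, truth, masks),
        "tv": tv_loss(pred, reduction),
        "ssim": ssim_loss(pred, truth),
        "hist": hist_loss(pred, truth, reduction),
    }
    total = (w.lambda_pix * comps["pix"] + w.lambda_edge * comps["edge"]
             + w.lambda_layer * comps["layer"] + w.lambda_tv * comps["tv"]
             + w.lambda_ssim * comps["ssim"] + w.lambda_hist * comps["hist"])
    return total, comps


# ---------------------------------------------------------------------------
# adversarial objectives
# ---------------------------------------------------------------------------

def gradient_penalty(critic, condition: Tensor, real: Tensor, fake: Tensor,
                     seed: int) -> Tensor:
    """E[(||grad_y D(x, y~)||_2 - 1)^2] at uniform convex interpolates y~."""
    rng = np.random.default_rng(seed)
    eps = rng.random((real.shape[0],) + (1,) * (real.ndim - 1))
    interp = Tensor((eps * real.data + (1 - eps) * fake.data)
                    .astype(real.data.dtype), requires_grad=True)
    score = critic(condition, interp)
    score.sum().backward(create_graph=True)
    g = interp.grad
    axes = tuple(range(1, real.ndim))
    norm = ((g * g).sum(axis=axes) + 1e-12).sqrt()
    return ((norm - 1.0) * (norm - 1.0)).mean()


def critic_objective(critic, condition: Tensor, real: Tensor, fake: Tensor,
                     lambda_gp: float = 10.0, seed: int = 0):
    """WGAN-GP critic loss; returns (loss, components dict)."""
    d_fake = critic(condition, fake).mean()
    d_real = critic(condition, real).mean()
    gp = gradient_penalty(critic, condition, real, fake, seed)
    loss = d_fake - d_real + lambda_gp * gp
    return loss, {"d_fake": d_fake.item(), "d_real": d_real.item(),
                  "gp": gp.item()}


def generator_objective(critic, condition: Tensor, fake: Tensor, truth: Tensor,
                        weights: LossWeights | None = None,
                        masks: dict[str, np.ndarray] | None = None,
                        reduction: str = "mean"):
    """-E[D(x, G(x))] + L_total; returns (loss, components dict)."""
    adv = critic(condition, fake).mean() * (-1.0)
    prior, comps = total_loss(fake, truth, weights, masks,
                              reduction=reduction)
    loss = adv + prior
    comps = {k: v.item() for k, v in comps.items()}
    comps["adv"] = adv.item()
    return loss, comps
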