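"""Image-quality metrics (RMSE / SSIM / PSNR) and experiment reporting.

Conventions:

- RMSE is the root of the mean squared pixel difference.
- SSIM uses a Gaussian window (11 taps, sigma 1.5) over valid window
  positions, with stability constants C1 = (0.01 Dr)^2, C2 = (0.03 Dr)^2
  for dynamic range Dr.  Conductivity images in [0, 2] are evaluated at
  Dr = 2 by default; Dr = 255 reproduces the classical 8-bit constants
  6.5025 and 58.5225.
- PSNR is 10 log10(MAX^2 / MSE) with MAX = 2.0 for conductivity maps;
  identical images report a capped sentinel (99 dB) so tables stay numeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .losses import gaussian_window

__all__ = ["rmse", "ssim", "psnr", "relative_change", "MetricReport",
           "evaluate_pairs", "run_experiment", "ablation_grid",
           "PSNR_SENTINEL_DB"]

PSNR_SENTINEL_DB = 99.0


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def ssim(pred: np.ndarray, truth: np.ndarray, dynamic_range: float = 2.0,
         window_size: int = 11, sigma: float = 1.5) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    if min(pred.shape) < window_size:
        raise ValueError("image smaller than the SSIM window")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    w = gaussian_window(window_size, sigma).astype(float)

    def wconv(img):
        # valid-mode Gaussian-weighted local means
        full = convolve(img, w, mode="constant")
        m = (window_size - 1) // 2
        return full[m:img.shape[0] - m, m:img.shape[1] - m]

    mu_p, mu_t = wconv(pred), wconv(truth)
    var_p = wconv(pred * pred) - mu_p ** 2
    var_t = wconv(truth * truth) - mu_t ** 2
    cov = wconv(pred * truth) - mu_p * mu_t
    s = ((2 * mu_p * mu_t + c1) * (2 * cov + c2)
         / ((mu_p ** 2 + mu_t ** 2 + c1) * (var_p + var_t + c2)))
    return float(np.mean(s))


def psnr(pred: np.ndarray, truth: np.ndarray, max_value: float = 2.0,
         sentinel: float = PSNR_SENTINEL_DB) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((pred - truth) ** 2))
    if mse == 0.0:
        return sentinel
    return float(10.0 * np.log10(max_value ** 2 / mse))


def relative_change(before: float, after: float) -> float:
    """Percentage change of ``after`` relative to ``before``.

    Positive return = decrease (improvement conventions for error metrics),
    negative = increase; callers report |value| with the direction stated.
    """
    if before == 0:
        raise ZeroDivisionError("relative change undefined for zero baseline")
    return 100.0 * (before - after) / before


@dataclass
class MetricReport:
    per_sample: pd.DataFrame       # columns: method, condition, sample, rmse, ssim, psnr
    summary: pd.DataFrame          # mean/std aggregates

    def to_csv(self, path):
        self.summary.to_csv(path, index=False)


def evaluate_pairs(preds: np.ndarray, truths: np.ndarray, method: str,
                   condition: str, dynamic_range: float = 2.0) -> pd.DataFrame:
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        rows.append({"method": method, "condition": condition, "sample": i,
                     "rmse": rmse(p, t), "ssim": ssim(p, t, dynamic_range),
                     "psnr": psnr(p, t)})
    return pd.DataFrame(rows)


def summarize(per_sample: pd.DataFrame) -> pd.DataFrame:
    agg = (per_sample.groupby(["method", "condition"])
           .agg(rmse_mean=("rmse", "mean"), rmse_std=("rmse", "std"),
                ssim_mean=("ssim", "mean"), ssim_std=("ssim", "std"),
                psnr_mean=("psnr", "mean"), psnr_std=("psnr", "std"))
           .reset_index())
    return agg


def run_experiment(generator, htv_inputs: np.ndarray, truths: np.ndarray,
                   condition: str = "clean", batch: int = 16) -> MetricReport:
    """Evaluate the HTV input and the generator output against truth.

    ``generator`` may be None to report the pre-reconstruction only.
    """
    frames = [evaluate_pairs(htv_inputs, truths, "htv", condition)]
    if generator is not None:
        from .autodiff import Tensor, no_grad
        generator.eval()
        outs = np.empty_like(np.asarray(htv_inputs, dtype=np.float32))
        for s in range(0, len(htv_inputs), batch):
            xb = np.asarray(htv_inputs[s:s + batch], np.float32)[:, None]
            with no_grad():
                y = generator(Tensor(xb))
            outs[s:s + batch] = y.data[:, 0]
        frames.append(evaluate_pairs(outs, truths, "generator", condition))
    per_sample = pd.concat(frames, ignore_index=True)
    return MetricReport(per_sample=per_sample, summary=summarize(per_sample))


def ablation_grid() -> list[dict]:
    """The 8 on/off combinations of the three BAM branches
    (spatial attention, channel attention, edge enhancement)."""
    # canonical ordering: none, singles, pairs, full
    order = [(False, False, False),
             (True, False, False), (False, True, False), (False, False, True),
             (True, True, False), (True, False, True), (False, True, True),
             (True, True, True)]
    rows = [{"row": k + 1, "spatial": s, "channel": c, "edge": e}
            for k, (s, c, e) in enumerate(order)]
    return rows
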