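"""Reconstruction quality metrics: MSE, PSNR and SSIM.

SSIM uses the standard parameterization C1 = (k1 L)^2, C2 = (k2 L)^2 with
k1 = 0.01, k2 = 0.03 and dynamic range L = 1.0 by default, averaged over
sliding windows (11x11 Gaussian, sigma 1.5, the field-standard choice).  A
uniform-window variant and a single-window ("global") closed-form variant
are available; the Gaussian-window implementation is cross-checked against
scikit-image in the test suite.

PSNR = 10 log10(R^2 / MSE) with R the peak intensity of the reference
image unless overridden.  Identical images report +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["MetricConfig", "mse", "psnr", "ssim", "evaluate_cohort"]


@dataclass
class MetricConfig:
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    window: str = "gaussian"  # gaussian | uniform | global
    win_size: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise ValueError("k1, k2 and data_range must be positive")
        if self.window not in ("gaussian", "uniform", "global"):
            raise ValueError("window must be gaussian, uniform or global")


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images.

    ``data_range`` (R) defaults to the maximum of the reference image ``x``.
    """
    err = mse(x, y)
    r = float(np.max(x)) if data_range is None else float(data_range)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(r * r / err))


def _ssim_map_filtered(x, y, cfg: MetricConfig, filt):
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    return ((2 * ux * uy + c1) * (2 * cov + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MetricConfig | None = None,
    data_range: float | None = None,
    window: str | None = None,
) -> float:
    """Mean structural similarity between two images.

    With ``window='global'`` a single window spanning the image is used,
    which for constant images reduces to the closed form
    (2ab + C1) / (a^2 + b^2 + C1).
    """
    cfg = cfg or MetricConfig()
    if data_range is not None or window is not None:
        cfg = MetricConfig(
            k1=cfg.k1, k2=cfg.k2,
            data_range=cfg.data_range if data_range is None else data_range,
            window=cfg.window if window is None else window,
            win_size=cfg.win_size, sigma=cfg.sigma,
        )
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if cfg.window == "global":
        c1 = (cfg.k1 * cfg.data_range) ** 2
        c2 = (cfg.k2 * cfg.data_range) ** 2
        ux, uy = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - ux) * (y - uy)).mean()
        return float(
            ((2 * ux * uy + c1) * (2 * cov + c2))
            / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
        )
    if min(x.shape) < cfg.win_size:
        raise ValueError(
            f"window of size {cfg.win_size} larger than image {x.shape}"
        )
    if cfg.window == "gaussian":
        # truncate chosen so the kernel radius matches the window size
        truncate = ((cfg.win_size - 1) / 2 - 0.5) / cfg.sigma + 1e-8
        def filt(a):
            return ndimage.gaussian_filter(a, cfg.sigma, truncate=truncate)
        smap = _ssim_map_filtered(x, y, cfg, filt)
    else:
        def filt(a):
            return ndimage.uniform_filter(a, cfg.win_size)
        # sample-covariance correction, matching common practice for
        # uniform windows
        np_pix = cfg.win_size ** 2
        cov_norm = np_pix / (np_pix - 1)
        c1 = (cfg.k1 * cfg.data_range) ** 2
        c2 = (cfg.k2 * cfg.data_range) ** 2
        ux, uy = filt(x), filt(y)
        vx = cov_norm * (filt(x * x) - ux * ux)
        vy = cov_norm * (filt(y * y) - uy * uy)
        cov = cov_norm * (filt(x * y) - ux * uy)
        smap = ((2 * ux * uy + c1) * (2 * cov + c2)) / (
            (ux * ux + uy * uy + c1) * (vx + vy + c2)
        )
    pad = (cfg.win_size - 1) // 2
    core = smap[tuple(slice(pad, s - pad) for s in smap.shape)]
    return float(core.mean())


def evaluate_cohort(
    pairs,
    data_range: float | None = None,
    cfg: MetricConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-stack metrics and a cohort summary in reporting units.

    ``pairs`` is an iterable of (ground_truth, prediction) image pairs (or a
    model + split handled by the caller).  Returns a per-stack DataFrame with
    raw mse/psnr/ssim plus a summary dict whose scaled entries follow the
    conventional table units: MSE in 1e-4, SSIM in 1e-2.
    """
    rows = []
    for i, (gt, pred) in enumerate(pairs):
        r = float(np.max(gt)) if data_range is None else data_range
        r = r or 1.0
        rows.append(
            {
                "stack_id": i,
                "mse": mse(gt, pred),
                "psnr": psnr(gt, pred, data_range=r),
                "ssim": ssim(gt, pred, cfg=cfg, data_range=r),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("evaluate_cohort needs a non-empty split")
    ddof = 0 if len(df) == 1 else 1
    summary = {
        "n": len(df),
        "mse_1e4_mean": float(df["mse"].mean() * 1e4),
        "mse_1e4_sd": float(df["mse"].std(ddof=ddof) * 1e4),
        "psnr_mean": float(df["psnr"][np.isfinite(df["psnr"])].mean()),
        "psnr_sd": float(df["psnr"][np.isfinite(df["psnr"])].std(ddof=ddof)),
        "ssim_1e2_mean": float(df["ssim"].mean() * 1e2),
        "ssim_1e2_sd": float(df["ssim"].std(ddof=ddof) * 1e2),
    }
    return df, summary
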