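"""Image-pair similarity metrics: PSNR, SSIM and the Weighted Patch Histogram.

All three operate on 8-bit RGB images (the evaluation representation; the
CIELAB planes exist only inside training).

PSNR (dB): ``20·log10(255) − 10·log10(MSE)`` with the MSE taken over all
pixels and channels; identical images give +∞.

SSIM: the windowed product of luminance, contrast and structure terms with
the usual stabilizing constants (K1=0.01, K2=0.03, dynamic range 255) under
an 11×11 Gaussian window (σ=1.5), averaged over windows and over the three
channels.  Values lie in [−1, 1].

WPH: both images are partitioned into a regular grid of square patches
(default 32×32 px with 32 histogram bins per channel); corresponding patches
are compared by normalized histogram intersection (Σ min of the probability
histograms, averaged over R, G, B), and the per-patch similarities are
combined as a weighted mean in which patches inside a central region of
interest — where the organoid sits — count 50% extra.  The score lies in
[0, 1], reaching 1 exactly for identical histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["MetricReport", "WphConfig", "psnr", "ssim", "wph", "compare"]


@dataclass
class WphConfig:
    patch_size: int = 32
    bins: int = 32
    roi_weight: float = 1.5
    roi_mask: np.ndarray | None = None  # boolean over the patch grid
    kernel: str = "intersection"  # or "correlation"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least 2 histogram bins")
        if self.roi_weight < 1.0:
            raise ValueError("ROI weight multiplier must be ≥ 1")
        if self.kernel not in ("intersection", "correlation"):
            raise ValueError(f"unknown comparison kernel {self.kernel!r}")


@dataclass
class MetricReport:
    """PSNR / SSIM / WPH for one image pair, plus the per-patch WPH map."""

    psnr: float
    ssim: float
    wph: float
    wph_map: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "psnr": "inf" if math.isinf(self.psnr) else self.psnr,
            "ssim": self.ssim,
            "wph": self.wph,
        }


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def psnr(img: np.ndarray, ref: np.ndarray, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +∞ for identical images."""
    img, ref = _check_pair(img, ref)
    mse = float(np.mean((img.astype(float) - ref.astype(float)) ** 2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(max_val) - 10.0 * math.log10(mse)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_plane(x: np.ndarray, y: np.ndarray, win: np.ndarray, c1: float, c2: float) -> float:
    mx = fftconvolve(x, win, mode="valid")
    my = fftconvolve(y, win, mode="valid")
    mxx = fftconvolve(x * x, win, mode="valid")
    myy = fftconvolve(y * y, win, mode="valid")
    mxy = fftconvolve(x * y, win, mode="valid")
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


def ssim(
    img: np.ndarray,
    ref: np.ndarray,
    max_val: float = 255.0,
    window: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Structural similarity index, averaged over windows and channels."""
    img, ref = _check_pair(img, ref)
    if img.shape[0] < window or img.shape[1] < window:
        raise ValueError(f"image smaller than the {window}×{window} window")
    win = _gaussian_kernel(window, sigma)
    c1 = (k1 * max_val) ** 2
    c2 = (k2 * max_val) ** 2
    x = img.astype(float)
    y = ref.astype(float)
    if x.ndim == 2:
        return _ssim_plane(x, y, win, c1, c2)
    return float(
        np.mean([_ssim_plane(x[..., c], y[..., c], win, c1, c2) for c in range(x.shape[-1])])
    )


def default_roi(grid: int) -> np.ndarray:
    """Centered half-width × half-height block of patches (the organoid ROI)."""
    mask = np.zeros((grid, grid), dtype=bool)
    half = grid // 2
    start = (grid - half) // 2
    mask[start : start + half, start : start + half] = True
    return mask


def _patch_histograms(img: np.ndarray, patch: int, bins: int) -> np.ndarray:
    """Probability histograms per (patch_row, patch_col, channel): g×g×3×bins."""
    h, w, _ = img.shape
    g = h // patch
    idx = np.minimum(img.astype(np.int64) * bins // 256, bins - 1)
    # linear index per (patch, channel, bin) then one bincount
    pr = np.arange(h) // patch
    pc = np.arange(w) // patch
    cell = (pr[:, None] * g + pc[None, :])[:, :, None]  # H×W×1
    chan = np.arange(3)[None, None, :]
    lin = (cell * 3 + chan) * bins + idx
    counts = np.bincount(lin.ravel(), minlength=g * g * 3 * bins)
    hist = counts.reshape(g, g, 3, bins).astype(float)
    return hist / (patch * patch)


def wph(
    img: np.ndarray, ref: np.ndarray, cfg: WphConfig | None = None
) -> tuple[float, np.ndarray]:
    """Weighted patch-histogram similarity: ``(score, per-patch map)``."""
    cfg = cfg or WphConfig()
    img, ref = _check_pair(img, ref)
    h, w = img.shape[:2]
    p = cfg.patch_size
    if h % p or w % p:
        raise ValueError(f"patch size {p} does not divide image size {h}×{w}")
    if h != w:
        raise ValueError("WPH expects square images")
    g = h // p
    h1 = _patch_histograms(img, p, cfg.bins)
    h2 = _patch_histograms(ref, p, cfg.bins)
    if cfg.kernel == "intersection":
        sim = np.minimum(h1, h2).sum(axis=-1)  # g×g×3
    else:  # correlation kernel, affinely mapped from [-1,1] to [0,1]
        a = h1 - h1.mean(axis=-1, keepdims=True)
        b = h2 - h2.mean(axis=-1, keepdims=True)
        denom = np.sqrt((a * a).sum(axis=-1) * (b * b).sum(axis=-1))
        corr = np.where(denom > 0, (a * b).sum(axis=-1) / np.where(denom > 0, denom, 1.0), 1.0)
        sim = (corr + 1.0) / 2.0
    per_patch = sim.mean(axis=-1)  # average over channels
    roi = cfg.roi_mask if cfg.roi_mask is not None else default_roi(g)
    if roi.shape != (g, g):
        raise ValueError(f"ROI mask shape {roi.shape} does not match {g}×{g} grid")
    weights = np.where(roi, cfg.roi_weight, 1.0)
    score = float((weights * per_patch).sum() / weights.sum())
    return score, per_patch


def compare(img: np.ndarray, ref: np.ndarray, cfg: WphConfig | None = None) -> MetricReport:
    """All three metrics for one generated/ground-truth pair."""
    score, patch_map = wph(img, ref, cfg)
    return MetricReport(
        psnr=psnr(img, ref), ssim=ssim(img, ref), wph=score, wph_map=patch_map
    )
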