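"""Procedural paired phase-contrast / fluorescence organoid images.

The generator emulates ring-shaped cardiac organoids grown on circular
micropatterns: a dark background, an annular organoid body carrying a broad
cardiomyocyte (CM) domain rendered green (GFP), and a sparser branching
endothelial (EC) network rendered red (mOrange).  The matching
phase-contrast image is a grayscale rendering in which CM and EC regions
carry distinct, learnable texture statistics — fine grain for the CM body,
brighter coarse ridges along the EC branches — so that cell type is
recoverable from the Lightness channel alone.  That texture→color coding is
what makes colorization learnable from synthetic data, mirroring the premise
that phase contrast carries cell-type information.

What the generator does *not* emulate: optical physics, diffraction halos,
focal drift, or the morphological diversity of real differentiation
batches.  The "new batch" domain-shift knob is a global brightness offset
plus a texture-scale change — a deliberately simple stand-in for
batch-to-batch appearance variation.

Every image pair is a deterministic function of ``(config, seed, index)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .training import PairedSample

__all__ = ["SyntheticConfig", "generate_pair", "generate_pairs", "generate_dataset"]

#: train fraction mirroring a 1374 : 79 train/test split
DEFAULT_SPLIT = 1374 / (1374 + 79)


@dataclass
class SyntheticConfig:
    size: int = 64
    outer_frac: float = 0.45  # ring outer radius / image size
    inner_frac: float = 0.18  # ring inner radius / image size
    cm_fill: float = 0.85  # fraction of the ring body occupied by CMs
    ec_density: float = 0.5  # walkers per ring octant, roughly
    cm_grain: float = 0.8  # phase-texture correlation length (px), CM
    ec_grain: float = 2.0  # phase-texture correlation length (px), EC
    cm_contrast: float = 25.0
    ec_contrast: float = 20.0
    background_noise: float = 2.0
    brightness_shift: float = 0.0  # domain-shift: global phase offset
    texture_shift: float = 0.0  # domain-shift: relative grain-size change
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_frac < self.outer_frac < 1.0):
            raise ValueError("need 0 < inner_frac < outer_frac < 1")
        if not (0.0 <= self.cm_fill <= 1.0 and 0.0 <= self.ec_density <= 1.0):
            raise ValueError("cm_fill and ec_density must lie in [0, 1]")
        if self.size * self.outer_frac - self.size * self.inner_frac < 2:
            raise ValueError("ring thinner than 2 px: degenerate geometry")

    def shifted(self, brightness: float = 25.0, texture: float = 0.6) -> "SyntheticConfig":
        """Config for a domain-shifted "new differentiation batch"."""
        return replace(self, brightness_shift=brightness, texture_shift=texture)


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def _ec_network(
    rng: np.random.Generator, cfg: SyntheticConfig, ring: np.ndarray
) -> np.ndarray:
    """Branching random-walk trees confined to the ring body."""
    s = cfg.size
    c = (s - 1) / 2.0
    rmid = s * (cfg.inner_frac + cfg.outer_frac) / 2.0
    mask = np.zeros((s, s), dtype=bool)
    n_walkers = max(1, int(round(8 * cfg.ec_density)))
    stack = []
    for _ in range(n_walkers):
        theta = rng.uniform(0, 2 * np.pi)
        pos = np.array([c + rmid * np.sin(theta), c + rmid * np.cos(theta)])
        heading = rng.uniform(0, 2 * np.pi)
        stack.append((pos, heading, int(s * 0.6)))
    while stack:
        pos, heading, steps = stack.pop()
        for _ in range(steps):
            i, j = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= i < s and 0 <= j < s) or not ring[i, j]:
                break
            mask[i, j] = True
            heading += rng.normal(0.0, 0.45)
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            if rng.random() < 0.03 and len(stack) < 64:
                stack.append((pos.copy(), heading + rng.choice([-1.2, 1.2]), steps // 2))
    return ndimage.binary_dilation(mask, iterations=1) & ring


def generate_pair(
    cfg: SyntheticConfig, index: int = 0
) -> tuple[PairedSample, dict[str, np.ndarray]]:
    """One phase/fluorescence pair plus its oracle masks.

    Returns ``(PairedSample, {"organoid", "cm", "ec"})``; bitwise identical
    for identical ``(config, index)``.
    """
    rng = np.random.default_rng([cfg.seed, index])
    s = cfg.size
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    ring = (r >= s * cfg.inner_frac) & (r <= s * cfg.outer_frac)

    # CM domain: smooth field thresholded at a quantile so the realized fill
    # fraction tracks cm_fill
    field = _smooth_noise(rng, s, s / 8.0)
    vals = field[ring]
    if cfg.cm_fill >= 1.0:
        cm = ring.copy()
    elif cfg.cm_fill <= 0.0:
        cm = np.zeros_like(ring)
    else:
        cut = np.quantile(vals, 1.0 - cfg.cm_fill)
        cm = ring & (field >= cut)
    ec = _ec_network(rng, cfg, ring)

    # fluorescence: green CMs, red ECs, black elsewhere
    fluor = np.zeros((s, s, 3), dtype=float)
    g_tex = 1.0 + 0.18 * _smooth_noise(rng, s, 2.0)
    r_tex = 1.0 + 0.15 * _smooth_noise(rng, s, 1.5)
    fluor[..., 1] = np.where(cm, np.clip(185.0 * g_tex, 40.0, 255.0), 0.0)
    fluor[..., 0] = np.where(ec, np.clip(205.0 * r_tex, 40.0, 255.0), 0.0)
    fluor_img = np.clip(np.rint(fluor), 0, 255).astype(np.uint8)

    # phase contrast: grayscale with cell-type-coded texture
    grain_scale = 1.0 + cfg.texture_shift
    phase = np.full((s, s), 25.0)
    phase[ring] = 95.0
    cm_tex = _smooth_noise(rng, s, cfg.cm_grain * grain_scale) * cfg.cm_contrast
    ec_tex = _smooth_noise(rng, s, cfg.ec_grain * grain_scale) * cfg.ec_contrast
    phase = np.where(cm & ~ec, phase + cm_tex - 20.0, phase)
    phase = np.where(ec, phase + ec_tex + 70.0, phase)
    phase += rng.normal(0.0, cfg.background_noise, (s, s))
    phase += cfg.brightness_shift
    phase_img = np.clip(np.rint(phase), 0, 255).astype(np.uint8)
    phase_rgb = np.repeat(phase_img[:, :, None], 3, axis=2)

    sample = PairedSample(id=f"synth_{cfg.seed}_{index:05d}", phase=phase_rgb, fluor=fluor_img)
    return sample, {"organoid": ring, "cm": cm, "ec": ec}


def generate_pairs(n: int, cfg: SyntheticConfig, start: int = 0) -> list[PairedSample]:
    """Convenience: ``n`` pairs in memory (masks discarded)."""
    return [generate_pair(cfg, start + i)[0] for i in range(n)]


def generate_dataset(
    n: int,
    cfg: SyntheticConfig,
    out_dir: str | Path,
    split_ratio: float = DEFAULT_SPLIT,
    shift_for_test_batch: bool = False,
) -> Path:
    """Write ``n`` PNG pairs plus a manifest CSV; returns the manifest path.

    Rows carry ``split`` (train/test by ``split_ratio``) and ``batch_tag``
    columns; with ``shift_for_test_batch`` the test images are drawn from
    the domain-shifted config and tagged ``new`` (the fine-tuning scenario).
    """
    from PIL import Image

    if n < 2:
        raise ValueError("need at least 2 pairs for a train/test split")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train = int(round(n * split_ratio))
    n_train = min(max(n_train, 1), n - 1)
    shifted = cfg.shifted() if shift_for_test_batch else cfg
    rows = []
    for i in range(n):
        is_test = i >= n_train
        use_cfg = shifted if (is_test and shift_for_test_batch) else cfg
        sample, _ = generate_pair(use_cfg, i)
        pp = out / f"phase_{i:05d}.png"
        fp = out / f"fluor_{i:05d}.png"
        Image.fromarray(sample.phase).save(pp)
        Image.fromarray(sample.fluor).save(fp)
        rows.append(
            {
                "id": sample.id,
                "phase_path": pp.name,
                "fluor_path": fp.name,
                "split": "test" if is_test else "train",
                "batch_tag": "new" if (is_test and shift_for_test_batch) else "base",
            }
        )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
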