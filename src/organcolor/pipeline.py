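"""Dataset plumbing and end-to-end prediction / evaluation.

``predict`` implements the colorization contract: the Lightness plane of the
phase-contrast input conditions the generator, the generated a*/b* planes
are denormalized and merged back onto that same Lightness plane, and the
merged CIELAB image is converted to 8-bit RGB.  Only chroma is generated —
the output inherits the input's grayscale structure exactly (up to 8-bit
round-trip error).

``evaluate_run`` scores every test pair with PSNR / SSIM / WPH plus the
per-channel fluorescence quantification and difference%, and aggregates the
means, mirroring the usual evaluation tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import LabImage, lab_to_rgb, rgb_to_lab
from .metrics import MetricReport, WphConfig, compare
from .models import UNetGenerator
from .quantify import CHANNEL_ROLES, difference_pct, measure_image
from .training import PairedSample

__all__ = ["Manifest", "load_manifest", "predict", "predict_one", "evaluate_run"]


@dataclass
class Manifest:
    frame: pd.DataFrame
    root: Path

    def samples(self, split: str | None = None, batch_tag: str | None = None) -> list[PairedSample]:
        from PIL import Image

        df = self.frame
        if split is not None:
            df = df[df["split"] == split]
        if batch_tag is not None:
            df = df[df["batch_tag"] == batch_tag]
        out = []
        for row in df.itertuples():
            phase = np.asarray(Image.open(self.root / row.phase_path).convert("RGB"))
            fluor = np.asarray(Image.open(self.root / row.fluor_path).convert("RGB"))
            out.append(PairedSample(id=row.id, phase=phase, fluor=fluor))
        return out


def load_manifest(path: str | Path) -> Manifest:
    """Load and validate a pairing manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "phase_path", "fluor_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "batch_tag" not in df.columns:
        df["batch_tag"] = "base"
    if df["id"].duplicated().any():
        raise ValueError("duplicate ids in manifest")
    root = path.parent
    for col in ("phase_path", "fluor_path"):
        for p in df[col]:
            if not (root / p).exists():
                raise FileNotFoundError(root / p)
    return Manifest(frame=df, root=root)


def predict_one(gen: UNetGenerator, phase: np.ndarray) -> np.ndarray:
    """Colorize one phase-contrast RGB image; returns 8-bit RGB."""
    h, w = phase.shape[:2]
    if h != w or h != gen.img_size:
        raise ValueError(
            f"image is {h}×{w} but the checkpoint expects {gen.img_size}px squares"
        )
    lab = rgb_to_lab(phase)
    l_norm = (lab.L / 50.0 - 1.0).astype(np.float32)
    ab = gen.forward(l_norm[None, None], train=False)[0]
    merged = LabImage(L=lab.L, a=ab[0] * 128.0, b=ab[1] * 128.0)
    return lab_to_rgb(merged)


def predict(gen: UNetGenerator, phases: list[np.ndarray]) -> list[np.ndarray]:
    """Colorize a list of phase-contrast images one at a time."""
    return [predict_one(gen, p) for p in phases]


def evaluate_run(
    samples: list[PairedSample],
    gen: UNetGenerator,
    wph_cfg: WphConfig | None = None,
    quant_threshold: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score generated vs ground-truth fluorescence for every pair.

    Returns ``(per_image, aggregate)``: one row per image with psnr / ssim /
    wph and per-channel difference%, and the column means (PSNR +∞ rows are
    excluded from the PSNR mean only).
    """
    if len(samples) == 0:
        raise ValueError("empty evaluation set")
    rows = []
    for s in samples:
        pred = predict_one(gen, s.phase)
        rep: MetricReport = compare(pred, s.fluor, wph_cfg)
        row: dict = {"id": s.id, "psnr": rep.psnr, "ssim": rep.ssim, "wph": rep.wph}
        gen_m = measure_image(pred, quant_threshold)
        gt_m = measure_image(s.fluor, quant_threshold)
        for ch in ("R", "G"):
            comp = difference_pct(gen_m[ch], gt_m[ch])
            role = CHANNEL_ROLES[ch]
            for name, val in comp.difference_pct.items():
                row[f"{role}:{name}_diff_pct"] = val
        rows.append(row)
    per_image = pd.DataFrame(rows).set_index("id")
    finite = per_image.replace(np.inf, np.nan)
    aggregate = finite.mean(numeric_only=True)
    return per_image, aggregate
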