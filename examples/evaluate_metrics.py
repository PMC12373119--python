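"""Score image pairs with PSNR, SSIM and the weighted patch histogram.

WPH is the color-aware metric: images are cut into a grid of patches, the
per-patch color histograms are compared by intersection, and central patches
(where the organoid sits) count 50% extra.  1 means identical histograms.
"""

import numpy as np

from organcolor import SyntheticConfig, WphConfig, compare, generate_pair

sample, _ = generate_pair(SyntheticConfig(size=64, seed=3), 0)
truth = sample.fluor
cfg = WphConfig(patch_size=16, bins=32, roi_weight=1.5)

rep = compare(truth, truth, cfg)
print(f"truth vs itself:   PSNR {rep.psnr}, SSIM {rep.ssim:.4f}, WPH {rep.wph:.4f}")

noisy = np.clip(truth.astype(int) + np.random.default_rng(0).integers(-20, 21, truth.shape),
                0, 255).astype(np.uint8)
rep = compare(noisy, truth, cfg)
print(f"±20-count noise:   PSNR {rep.psnr:.2f} dB, SSIM {rep.ssim:.4f}, WPH {rep.wph:.4f}")

swapped = truth[:, :, [1, 0, 2]]  # wrong cell-type colors, same structure
rep = compare(swapped, truth, cfg)
print(f"channels swapped:  PSNR {rep.psnr:.2f} dB, SSIM {rep.ssim:.4f}, WPH {rep.wph:.4f}")
print("\nEven with per-pixel structure intact, swapping the cell-type colors")
print("collapses PSNR and keeps WPH well below 1, because CM and EC pixels land")
print("in different color histograms — WPH scores color placement, not structure.")
print("per-patch WPH map (rows × cols):")
print(np.array2string(rep.wph_map, precision=2))
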