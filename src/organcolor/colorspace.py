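"""sRGB ↔ CIELAB conversion chain used throughout the colorization pipeline.

The forward chain is the textbook three-step procedure: undo the sRGB gamma
encoding, project linear RGB onto CIE XYZ with the D65 matrix, then apply the
CIELAB nonlinearity with the standard ``δ = 6/29`` knee.  The network never
sees RGB directly: the Lightness plane (``L*`` in [0, 100]) is the conditional
input and the chroma planes (``a*``, ``b*`` stored in [-128, 127]) are the
prediction target, each affinely normalized to [-1, 1] for training.

All conversions are pixel-wise and vectorized; images are ``H×W×3`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabImage",
    "rgb_to_lab",
    "lab_to_rgb",
    "normalize_lab",
    "SRGB_TO_XYZ",
    "D65_WHITE",
]

#: Row-major sRGB(linear) → XYZ matrix for the D65 white point, to the four
#: decimals conventionally printed.
SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: D65 reference white (X_n, Y_n, Z_n), 2° observer, Y normalized to 1.
D65_WHITE = np.array([0.95047, 1.00000, 1.08883])

_DELTA = 6.0 / 29.0
# α, β chosen so f is C0-continuous at t = δ³ (the CIE standard values).
_ALPHA = 1.0 / (3.0 * _DELTA**2)
_BETA = 4.0 / 29.0


@dataclass
class LabImage:
    """CIELAB image: ``L`` in [0, 100], ``a``/``b`` nominally in [-128, 127].

    ``normalized`` flags the [-1, 1] training representation produced by
    :func:`normalize_lab`; geometry is always ``H×W`` per channel.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L, a, b planes must share one H×W geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """Return the three planes as one ``H×W×3`` array (L, a, b order)."""
        return np.stack([self.L, self.a, self.b], axis=-1)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 RGB image, got shape {arr.shape}")
    return arr


def _srgb_inverse_gamma(v: np.ndarray) -> np.ndarray:
    """Piecewise sRGB decoding: linear toe below 0.04045, 2.4 power above."""
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_forward_gamma(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def _f(t: np.ndarray) -> np.ndarray:
    """CIELAB companding function: cube root above δ³, affine below."""
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), _ALPHA * t + _BETA)


def _f_inv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, (u - _BETA) / _ALPHA)


def rgb_to_lab(img: np.ndarray) -> LabImage:
    """Convert an 8-bit ``H×W×3`` sRGB image to CIELAB.

    Chroma values are left unclamped (the sRGB gamut stays well inside the
    nominal [-128, 127] byte range); clipping happens only at normalization
    or 8-bit serialization so round trips do not compound error.
    """
    arr = _check_rgb(img).astype(float) / 255.0
    linear = _srgb_inverse_gamma(arr)
    xyz = linear @ SRGB_TO_XYZ.T
    fxyz = _f(xyz / D65_WHITE)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return LabImage(L=L, a=a, b=b, normalized=False)


def lab_to_rgb(lab: LabImage) -> np.ndarray:
    """Invert :func:`rgb_to_lab`; out-of-gamut values clip to [0, 255].

    Returns a ``uint8`` image, rounded half-even.
    """
    if lab.normalized:
        raise ValueError("denormalize first: lab_to_rgb expects L in [0,100]")
    fy = (lab.L + 16.0) / 116.0
    fx = fy + lab.a / 500.0
    fz = fy - lab.b / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * D65_WHITE
    linear = xyz @ np.linalg.inv(SRGB_TO_XYZ).T
    srgb = _srgb_forward_gamma(linear)
    return np.clip(np.rint(srgb * 255.0), 0, 255).astype(np.uint8)


def normalize_lab(lab: LabImage, direction: str = "forward") -> LabImage:
    """Map CIELAB planes to the [-1, 1] training range, or back.

    Forward: ``L → L/50 - 1`` and ``a, b → clip(v, -128, 127)/128``; inverse
    is the exact algebraic inverse.  Applying the same direction twice is a
    state error (guarded by the ``normalized`` flag).
    """
    if direction == "forward":
        if lab.normalized:
            raise ValueError("image is already normalized")
        return LabImage(
            L=lab.L / 50.0 - 1.0,
            a=np.clip(lab.a, -128.0, 127.0) / 128.0,
            b=np.clip(lab.b, -128.0, 127.0) / 128.0,
            normalized=True,
        )
    if direction == "inverse":
        if not lab.normalized:
            raise ValueError("image is not normalized")
        return LabImage(
            L=(lab.L + 1.0) * 50.0,
            a=lab.a * 128.0,
            b=lab.b * 128.0,
            normalized=False,
        )
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
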