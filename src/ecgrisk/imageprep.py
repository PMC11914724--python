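"""Image-side preprocessing for the 2D model.

Pages are converted to greyscale, cropped to the 4x3 panel, resized down a
ladder of resolutions (1x1 up to 310x868), and normalized so ink is bright
on a dark background before being fed to the 2D network.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .render import RenderedECG

#: Best-performing full resolution (height, width) and the low-resolution knee.
FULL_RESOLUTION = (310, 868)
KNEE_RESOLUTION = (27, 76)


def to_blackwhite(image: RenderedECG) -> RenderedECG:
    """Luminance conversion of a colour page; greyscale input is unchanged.

    The red grid maps to a light grey while the black trace stays darkest,
    so trace/background contrast survives the conversion.
    """
    if not image.is_color:
        return image
    lum = image.pixels.astype(float) @ np.array([0.299, 0.587, 0.114])
    return RenderedECG(np.clip(np.round(lum), 0, 255).astype(np.uint8), image.truth)


def resize_image(image: RenderedECG | np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Anti-aliased area resize to exactly (height, width) pixels."""
    h, w = target
    if h < 1 or w < 1:
        raise ValueError(f"target dimensions must be >= 1, got {target}")
    arr = image.pixels if isinstance(image, RenderedECG) else np.asarray(image)
    if arr.shape[:2] == (h, w):
        return arr.copy()
    out = Image.fromarray(arr).resize((w, h), resample=Image.Resampling.BOX)
    return np.asarray(out).copy()


def resolution_ladder(n: int = 11,
                      low: tuple[int, int] = (1, 1),
                      knee: tuple[int, int] = KNEE_RESOLUTION,
                      high: tuple[int, int] = FULL_RESOLUTION) -> list[tuple[int, int]]:
    """The resolution ablation ladder: ``n`` sizes from ``low`` to ``high``.

    Anchored at the three named resolutions with geometric interpolation of
    each dimension between anchors; the default enumerates 11 entries from
    1x1 through 27x76 up to 310x868, strictly increasing in pixel count.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError("ladder needs an odd length >= 3 to centre the knee")
    half = n // 2

    def geo(a: int, b: int, steps: int) -> list[int]:
        return [int(round(a * (b / a) ** (i / steps))) for i in range(steps)]

    heights = geo(low[0], knee[0], half) + geo(knee[0], high[0], half) + [high[0]]
    widths = geo(low[1], knee[1], half) + geo(knee[1], high[1], half) + [high[1]]
    ladder = list(zip(heights, widths))
    counts = [h * w for h, w in ladder]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError(f"ladder pixel counts not strictly increasing: {ladder}")
    return ladder


def normalize_for_model(grey: np.ndarray) -> np.ndarray:
    """Invert and scale a greyscale raster to [0, 1] with ink ~ 1."""
    arr = np.asarray(grey, dtype=float)
    out = (255.0 - arr) / 255.0
    return np.clip(out, 0.0, 1.0)


def prepare_image_input(image: RenderedECG, target: tuple[int, int]) -> np.ndarray:
    """Greyscale → resize → normalized (height, width) float array in [0,1]."""
    grey = to_blackwhite(image)
    return normalize_for_model(resize_image(grey, target))
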