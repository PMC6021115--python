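"""Image conditioning for the shape-classification CNN.

The network sees crops that went through two steps:

1. **Contrast stretch** — intensities are mapped to the full 8-bit range so
   that the bottom 1 % and top 1 % of pixel values saturate, equalizing
   contrast across illumination conditions.
2. **Tukey windowing** — every row is weighted by a cosine-tapered window
   (taper fraction ``alpha = 0.25``) along the cross-channel axis, fading
   the image out towards the top and bottom edges where the channel walls
   refract light irregularly:

   .. math::

       w(y) = \\begin{cases}
         \\tfrac12\\left[1+\\cos\\left(\\tfrac{2\\pi}{\\alpha}
           (y-\\tfrac{\\alpha}{2})\\right)\\right], & 0 \\le y < \\alpha/2,\\\\
         1, & \\alpha/2 \\le y < 1-\\alpha/2,\\\\
         \\tfrac12\\left[1+\\cos\\left(\\tfrac{2\\pi}{\\alpha}
           (y-1+\\tfrac{\\alpha}{2})\\right)\\right], & 1-\\alpha/2 \\le y \\le 1,
       \\end{cases}

   with :math:`y \\in [0, 1]` the relative row position.

Training data are additionally doubled by mirroring every crop across the
horizontal centerline (the centerline in flow direction); the slipper /
croissant distinction is invariant under that reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import CellImage, LabeledDataset

__all__ = [
    "WindowSpec",
    "tukey_window",
    "apply_window",
    "contrast_stretch",
    "mirror_augment",
    "preprocess_images",
]


@dataclass(frozen=True)
class WindowSpec:
    """Tukey-window configuration: taper fraction and tapered length/axis."""

    alpha: float = 0.25
    length: int = 90
    axis: int = 0   # the vertical (cross-channel) image axis

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 (rows) or 1 (columns)")


def tukey_window(length: int, alpha: float = 0.25) -> np.ndarray:
    """Cosine-tapered (Tukey) window sampled at y_i = i/(length-1).

    ``alpha = 0`` gives the all-ones (rectangular) window, ``alpha = 1`` the
    Hann window.  Endpoints are included, so the extreme samples get weight
    zero whenever ``alpha > 0``.  Weights are symmetric, ``w(y) = w(1-y)``,
    and lie in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if length < 2:
        raise ValueError("length must be >= 2")
    y = np.arange(length) / (length - 1)
    w = np.ones(length)
    if alpha / 2 > 0:               # subnormal alpha: taper has zero width
        lo = y < alpha / 2
        hi = y >= 1 - alpha / 2
        # argument written as 2*pi*(y/alpha - 1/2) so that tiny alpha stays
        # finite (the taper then only contains the exact endpoints)
        w[lo] = 0.5 * (1 + np.cos(2 * np.pi * (y[lo] / alpha - 0.5)))
        w[hi] = 0.5 * (1 + np.cos(2 * np.pi * ((y[hi] - 1) / alpha + 0.5)))
    return w


def _pixels(img: CellImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, CellImage) else np.asarray(img)


def apply_window(img: CellImage | np.ndarray,
                 spec: WindowSpec | None = None) -> np.ndarray:
    """Weight each row (or column) of the image by the Tukey window.

    Returns a real-valued array; the orthogonal axis is untouched.
    """
    px = _pixels(img).astype(float)
    if spec is None:
        spec = WindowSpec(length=px.shape[0])
    if px.shape[spec.axis] != spec.length:
        raise ValueError(
            f"image has {px.shape[spec.axis]} samples along axis {spec.axis}, "
            f"window expects {spec.length}")
    w = tukey_window(spec.length, spec.alpha)
    shape = [1, 1]
    shape[spec.axis] = spec.length
    return px * w.reshape(shape)


def contrast_stretch(img: CellImage | np.ndarray,
                     sat_frac: float = 0.01) -> np.ndarray:
    """Map intensities to the full 8-bit range with tail saturation.

    The ``sat_frac`` lower and upper quantiles (linear-interpolation
    convention) map to 0 and 255; values in between are rescaled linearly
    and everything is clipped and re-quantized to uint8.  The output is
    invariant under any affine shift of the input.  A constant image has no
    contrast to stretch and is returned as mid-grey 128 with a warning.
    """
    if not 0 <= sat_frac < 0.5:
        raise ValueError("sat_frac must lie in [0, 0.5)")
    px = _pixels(img).astype(float)
    lo, hi = np.quantile(px, [sat_frac, 1.0 - sat_frac])
    if hi <= lo:
        warnings.warn("constant image: contrast stretch returns mid-grey",
                      RuntimeWarning, stacklevel=2)
        return np.full(px.shape, 128, np.uint8)
    out = (px - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def mirror_augment(ds: LabeledDataset) -> LabeledDataset:
    """Double a dataset by reflecting every crop across the horizontal centerline.

    The output holds all originals first, then the mirrors in the same
    order, with labels and pressures copied — 4,000 crops become 8,000.
    """
    if len(ds) == 0:
        return LabeledDataset(ds.images.copy(), [], None
                              if ds.pressures_mbar is None
                              else ds.pressures_mbar.copy())
    flipped = ds.images[:, ::-1, :]
    images = np.concatenate([ds.images, flipped], axis=0)
    labels = list(ds.labels) + list(ds.labels)
    press = (None if ds.pressures_mbar is None
             else np.concatenate([ds.pressures_mbar, ds.pressures_mbar]))
    return LabeledDataset(images, labels, press)


def preprocess_images(images: np.ndarray, alpha: float = 0.25,
                      sat_frac: float = 0.01) -> np.ndarray:
    """Contrast-stretch then Tukey-window a stack of crops.

    This is the exact conditioning the network input expects: stretch on the
    8-bit crop first, windowing second, feeding the real-valued result to
    the input layer.  Returns an ``(N, H, W)`` float array.
    """
    images = np.asarray(images)
    n = images.shape[1]
    w = tukey_window(n, alpha)
    out = np.empty(images.shape, float)
    for i, img in enumerate(images):
        out[i] = contrast_stretch(img, sat_frac).astype(float) * w[:, None]
    return out
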