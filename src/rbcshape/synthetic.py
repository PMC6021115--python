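"""Synthetic bright-field crops of red blood cells in microcapillary flow.

Red blood cells in narrow rectangular microchannels adopt two stable
morphologies: the axisymmetric *croissant* at low flow velocities and the
non-axisymmetric, off-center *slipper* (with its characteristic tail) at
high velocities.  An auxiliary *sheared croissant* — most likely a slipper
rotated 90 degrees about the flow axis — sits between them, and a sizeable
fraction of cells show indefinite shapes (*other*).

This module renders labeled 90 x 90 px 8-bit grayscale crops with the gross
geometry of those classes plus the photometric nuisances of the recordings:
varying lamp power, defocus blur, sensor noise, translation jitter and dark
bands where the channel walls refract the light.  It exists so that the
whole pipeline (preprocessing, CNN training, score calibration, phase
diagrams) is testable end to end without any experimental data.

Silhouettes are parametric: a croissant is the difference of two offset
ellipses (a crescent opening against the flow), a slipper is a sheared
ellipse displaced from the centerline with a tail lobe, a sheared croissant
is a croissant with deliberately broken top-bottom symmetry, and ``other``
is a random morph between the class templates with additional lobed
deformation.  Only class-distinctive gross geometry is modeled — no
membrane mechanics, no hydrodynamics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ShapeClass",
    "RenderParams",
    "CellImage",
    "LabeledDataset",
    "PRESSURE_LEVELS_MBAR",
    "CLASS_PRESSURE_RANGES",
    "render_cell",
    "generate_dataset",
    "generate_phase_sweep",
]

#: Discrete pressure drops (mbar) at which cells are recorded.
PRESSURE_LEVELS_MBAR: tuple[int, ...] = (
    20, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
)


class ShapeClass(enum.Enum):
    """The cell-shape classes and their regression targets.

    Targets live on an 8-bit-inspired scale: perfect slippers at -127,
    perfect croissants at +127 and sheared croissants biased to +64.
    ``other`` is the open-set outlier class and carries no training target.
    """

    SLIPPER = "slipper"
    CROISSANT = "croissant"
    SHEARED_CROISSANT = "sheared_croissant"
    OTHER = "other"

    @property
    def target_value(self) -> int:
        """Regression target of the class; raises for ``other``."""
        targets = {
            ShapeClass.SLIPPER: -127,
            ShapeClass.CROISSANT: 127,
            ShapeClass.SHEARED_CROISSANT: 64,
        }
        if self not in targets:
            raise ValueError(f"class {self.value!r} has no training target")
        return targets[self]

    @classmethod
    def from_name(cls, name: str) -> "ShapeClass":
        try:
            return cls(name)
        except ValueError:
            raise ValueError(f"unknown shape class {name!r}") from None


#: Pressure ranges (mbar) at which each trained class is typically recorded:
#: slippers at high, croissants at low and sheared croissants at mid pressure.
CLASS_PRESSURE_RANGES: Mapping[ShapeClass, tuple[int, ...]] = {
    ShapeClass.SLIPPER: (700, 800, 900, 1000),
    ShapeClass.CROISSANT: (100, 200),
    ShapeClass.SHEARED_CROISSANT: (300, 400, 500),
    ShapeClass.OTHER: PRESSURE_LEVELS_MBAR,
}


@dataclass(frozen=True)
class RenderParams:
    """Photometric and geometric rendering knobs.

    Parameters
    ----------
    canvas_px
        Side length of the square crop; fixed at 90 px by the recording
        pipeline.
    bit_depth
        Output bit depth (8: values quantized into [0, 255]).
    illumination_scale
        Lamp-power fraction.  A ``(lo, hi)`` pair draws a fresh uniform
        value per image, emulating the 50-80 % random lamp variation of the
        recordings; a scalar pins it.
    defocus_sigma_px
        Std of the Gaussian defocus blur, px.
    translation_jitter_px
        Max absolute shift of the cell from the crop center, px, per axis.
    noise_sd
        Std of additive Gaussian sensor noise, grey levels.
    edge_artifact_amplitude
        Peak darkening fraction of the channel-wall bands at the top and
        bottom rows (0 disables them).
    edge_band_px
        Thickness of each wall band, rows.
    rng_seed
        Seed used when no explicit generator is passed.
    """

    canvas_px: int = 90
    bit_depth: int = 8
    illumination_scale: float | tuple[float, float] = (0.5, 0.8)
    defocus_sigma_px: float = 1.2
    translation_jitter_px: float = 3.0
    noise_sd: float = 4.0
    edge_artifact_amplitude: float = 0.35
    edge_band_px: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_px < 48:
            raise ValueError("canvas too small to contain a cell silhouette")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")
        for name in ("defocus_sigma_px", "translation_jitter_px", "noise_sd",
                     "edge_artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def noiseless(self) -> "RenderParams":
        """Copy with all stochastic photometric effects switched off."""
        return replace(self, illumination_scale=0.65, defocus_sigma_px=0.0,
                       translation_jitter_px=0.0, noise_sd=0.0)

    def draw_illumination(self, rng: np.random.Generator) -> float:
        s = self.illumination_scale
        if np.isscalar(s):
            return float(s)
        lo, hi = s
        return float(rng.uniform(lo, hi))


@dataclass
class CellImage:
    """One 90 x 90 crop with optional label and flow-condition metadata."""

    pixels: np.ndarray
    label: ShapeClass | None = None
    pressure_mbar: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("cell image must be a square 2-D grid")


@dataclass
class LabeledDataset:
    """A stack of crops with per-image labels and optional pressures.

    ``images`` is an ``(N, H, W)`` array (uint8 straight from the renderer,
    float after preprocessing); ``labels`` holds one ``ShapeClass`` or
    ``None`` per image.
    """

    images: np.ndarray
    labels: list[ShapeClass | None]
    pressures_mbar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N, H, W) stack")
        if len(self.labels) != len(self.images):
            raise ValueError("images and labels must have equal length")
        if self.pressures_mbar is not None:
            self.pressures_mbar = np.asarray(self.pressures_mbar)
            if len(self.pressures_mbar) != len(self.images):
                raise ValueError("pressures and images must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> CellImage:
        p = None if self.pressures_mbar is None else int(self.pressures_mbar[i])
        return CellImage(self.images[i], self.labels[i], p)

    def targets(self) -> np.ndarray:
        """Regression targets per image; raises if any label is other/None."""
        return np.array([lab.target_value if lab is not None else
                         self._no_target() for lab in self.labels], float)

    @staticmethod
    def _no_target():
        raise ValueError("dataset contains unlabeled images")

    def subset(self, idx: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx, int)
        pr = None if self.pressures_mbar is None else self.pressures_mbar[idx]
        return LabeledDataset(self.images[idx],
                              [self.labels[i] for i in idx], pr)


# ---------------------------------------------------------------------------
# silhouette rasterization

def _grid(n: int, dy: float = 0.0, dx: float = 0.0):
    """Pixel-center coordinates relative to the (shifted) canvas center."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return yy - c - dy, xx - c - dx


def _soft(field_: np.ndarray, edge: float = 1.2) -> np.ndarray:
    """Anti-aliased indicator of ``field_ <= 0`` (smooth over ~edge px)."""
    return 1.0 / (1.0 + np.exp(np.clip(field_ / edge, -40, 40)))


def _ellipse(yy, xx, cy, cx, ry, rx, theta=0.0):
    """Signed implicit field of a rotated ellipse (negative inside)."""
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return np.sqrt((u / rx) ** 2 + (v / ry) ** 2) * min(rx, ry) - min(rx, ry)


def _croissant_mask(n, rng, dy=0.0, dx=0.0, asym=0.0):
    """Crescent opening against the flow (concave trailing face).

    Difference of two ellipses offset along the flow (x) axis; ``asym``
    shears the cutter off the centerline to break top-bottom symmetry
    (used by the sheared-croissant class).
    """
    yy, xx = _grid(n, dy, dx)
    r = rng.uniform(26, 31)
    thick = rng.uniform(0.55, 0.70)
    body = _ellipse(yy, xx, 0.0, 0.0, r, r * rng.uniform(0.82, 0.95))
    cut = _ellipse(yy, xx, asym * r, -r * thick, r * 0.92, r * 0.85)
    inside = np.minimum(_soft(body), 1.0 - _soft(cut))
    return inside


def _slipper_mask(n, rng, dy=0.0, dx=0.0):
    """Elongated sheared body off the centerline with a trailing tail lobe."""
    yy, xx = _grid(n, dy, dx)
    off = rng.uniform(8, 12)           # offset from the channel centerline
    shear = rng.uniform(0.25, 0.4)
    ry = rng.uniform(11, 14)
    rx = rng.uniform(26, 31)
    ys = yy - off + shear * xx         # sheared frame
    body = _ellipse(ys, xx, 0.0, 0.0, ry, rx)
    tail = _ellipse(yy, xx, off * 0.1, -rx * 0.85, ry * 0.75, rx * 0.45,
                    theta=rng.uniform(0.25, 0.45))
    return np.maximum(_soft(body), _soft(tail))


def _other_mask(n, rng, dy=0.0, dx=0.0):
    """Indefinite shape: random morph of the templates plus lobed warping."""
    w = rng.uniform(0.25, 0.75)
    a = _croissant_mask(n, rng, dy, dx, asym=rng.uniform(-0.5, 0.5))
    b = _slipper_mask(n, rng, dy, dx)
    mix = w * a + (1 - w) * b
    # random angular lobes carve/extend the outline beyond either template
    yy, xx = _grid(n, dy, dx)
    ang = np.arctan2(yy, xx)
    warp = np.zeros_like(mix)
    for _ in range(rng.integers(2, 5)):
        k = rng.integers(2, 6)
        warp += rng.uniform(0.25, 0.6) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
    bump = _soft(np.abs(mix - 0.5) * 12 - 3)   # ring around the outline
    mix = np.clip(mix + 0.8 * warp * bump, 0, 1)
    return (mix > 0.5).astype(float) * mix + (mix <= 0.5) * mix * 0.3


_MASKS = {
    ShapeClass.CROISSANT: lambda n, rng, dy, dx: _croissant_mask(n, rng, dy, dx),
    ShapeClass.SLIPPER: _slipper_mask,
    ShapeClass.SHEARED_CROISSANT: lambda n, rng, dy, dx: _croissant_mask(
        n, rng, dy, dx, asym=rng.uniform(0.35, 0.6) * rng.choice([-1.0, 1.0])),
    ShapeClass.OTHER: _other_mask,
}


def render_cell(shape: ShapeClass | str, params: RenderParams | None = None,
                rng: np.random.Generator | int | None = None) -> CellImage:
    """Render one synthetic bright-field crop of the given shape class.

    The silhouette is rasterized with anti-aliasing, then the photometric
    chain is applied in order: illumination scaling, Gaussian defocus blur,
    additive sensor noise, translation jitter, channel-wall darkening at the
    top/bottom rows, and finally 8-bit quantization.

    Parameters
    ----------
    shape
        One of ``slipper``, ``croissant``, ``sheared_croissant``, ``other``.
    params
        Rendering parameters; defaults emulate the recordings.
    rng
        A :class:`numpy.random.Generator`, a seed, or ``None`` (uses
        ``params.rng_seed``).  Identical seed and params give bitwise
        identical images.
    """
    if isinstance(shape, str):
        shape = ShapeClass.from_name(shape)
    if params is None:
        params = RenderParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.rng_seed if rng is None else rng)
    n = params.canvas_px

    # geometric translation jitter (integer px keeps the raster exact)
    j = params.translation_jitter_px
    dy = dx = 0.0
    if j > 0:
        dy = float(rng.integers(-int(round(j)), int(round(j)) + 1))
        dx = float(rng.integers(-int(round(j)), int(round(j)) + 1))

    mask = _MASKS[shape](n, rng, dy, dx)

    illum = params.draw_illumination(rng)
    background = 255.0 * illum
    depth = background * 0.75          # cells absorb most of the light
    img = background - depth * mask
    # faint bright halo just outside the membrane, as in defocused bright field
    halo = _soft(np.abs(mask - 0.5) * 10 - 2.2) * (mask < 0.5)
    img = img + 0.12 * background * halo

    if params.defocus_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.defocus_sigma_px,
                                      mode="nearest")
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    if params.edge_artifact_amplitude > 0 and params.edge_band_px > 0:
        img = img * _edge_profile(n, params.edge_band_px,
                                  params.edge_artifact_amplitude)[:, None]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CellImage(img, label=shape)


def _edge_profile(n: int, band: int, amp: float) -> np.ndarray:
    """Per-row brightness factor: cosine-ramped darkening at both walls."""
    prof = np.ones(n)
    ramp = 1.0 - amp * 0.5 * (1 + np.cos(np.pi * np.arange(band) / band))
    prof[:band] = ramp
    prof[-band:] = ramp[::-1]
    return prof


def _assign_pressure(shape: ShapeClass, rng: np.random.Generator) -> int:
    return int(rng.choice(CLASS_PRESSURE_RANGES[shape]))


def generate_dataset(counts: Mapping[ShapeClass | str, int],
                     params: RenderParams | None = None,
                     assign_pressures: bool = True,
                     seed: int = 0) -> LabeledDataset:
    """Generate a labeled dataset with exact per-class counts.

    Each image is rendered from a fresh child stream of ``seed`` so the
    dataset is bitwise reproducible.  When ``assign_pressures`` is set, each
    image gets a pressure drop from its class's typical recording range
    (slippers 700-1000 mbar, croissants 100-200, sheared 300-500).

    The training mix of the study is
    ``{slipper: 1500, croissant: 1500, sheared_croissant: 1000}`` (4,000
    manually classified cells before augmentation).
    """
    if params is None:
        params = RenderParams()
    norm: list[tuple[ShapeClass, int]] = []
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for class {k}")
        norm.append((ShapeClass.from_name(k) if isinstance(k, str) else k, v))

    ss = np.random.SeedSequence(seed)
    n_total = sum(v for _, v in norm)
    images = np.empty((n_total, params.canvas_px, params.canvas_px), np.uint8)
    labels: list[ShapeClass | None] = []
    pressures = np.zeros(n_total, int) if assign_pressures else None
    i = 0
    for shape, count in norm:
        for child in ss.spawn(count):
            rng = np.random.default_rng(child)
            images[i] = render_cell(shape, params, rng).pixels
            labels.append(shape)
            if pressures is not None:
                pressures[i] = _assign_pressure(shape, rng)
            i += 1
    return LabeledDataset(images[:i], labels, pressures)


def generate_phase_sweep(n_per_condition: int = 60,
                         transition_mbar: float = 400.0,
                         transition_width_mbar: float = 180.0,
                         other_fraction: float = 0.15,
                         sheared_peak_fraction: float = 0.2,
                         sheared_width_mbar: float = 250.0,
                         conditions: Sequence[int] = PRESSURE_LEVELS_MBAR,
                         params: RenderParams | None = None,
                         seed: int = 0) -> LabeledDataset:
    """Generate a pressure sweep with a planted croissant-to-slipper transition.

    At each pressure drop the class mixture is croissant-rich below and
    slipper-rich above ``transition_mbar``; a constant ``other_fraction`` of
    indefinite shapes occurs everywhere, and sheared croissants peak around
    the transition region (fraction ``sheared_peak_fraction`` with a
    Gaussian pressure profile of width ``sheared_width_mbar``), as they do
    in real recordings.  Slipper and croissant take complementary shares of
    the remainder, so their fraction curves cross exactly at
    ``transition_mbar`` — the planted phase-transition point a downstream
    phase diagram should recover.
    """
    if params is None:
        params = RenderParams()
    if not 0 <= other_fraction < 1 or not 0 <= sheared_peak_fraction < 1:
        raise ValueError("class fractions must lie in [0, 1)")
    ss = np.random.SeedSequence([seed, 2**16 + 1])
    rng = np.random.default_rng(ss)
    classes = [ShapeClass.SLIPPER, ShapeClass.CROISSANT,
               ShapeClass.SHEARED_CROISSANT, ShapeClass.OTHER]
    chunks, labels, press = [], [], []
    for p in conditions:
        f_slip = 1.0 / (1.0 + np.exp(-(p - transition_mbar) / transition_width_mbar))
        f_sheared = sheared_peak_fraction * np.exp(
            -0.5 * ((p - transition_mbar) / sheared_width_mbar) ** 2)
        stable = 1.0 - other_fraction - f_sheared
        probs = [stable * f_slip, stable * (1 - f_slip), f_sheared,
                 other_fraction]
        draws = rng.choice(4, size=n_per_condition, p=probs)
        for d in draws:
            shape = classes[d]
            chunks.append(render_cell(shape, params, rng).pixels)
            labels.append(shape)
            press.append(p)
    return LabeledDataset(np.stack(chunks), labels, np.array(press))
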