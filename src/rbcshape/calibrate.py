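"""Calibration of the network's score spectrum into class intervals.

The trained network maps every cell to one scalar score.  Across a whole
recording the score histogram shows three populations — slippers near the
negative target, sheared croissants in between, croissants near the
positive target — on top of a broad background of indefinite shapes.  The
spectrum is fitted by the sum of four Gaussians (one per population plus
one wide background component); class intervals on the score axis are then
derived either as ``k * sigma`` confidence intervals around the fitted
slipper and croissant centers, or as *adapted* intervals found by scanning
center and half-width per class to minimize false positives plus false
negatives against reference labels.  Any score falling in neither interval
is classified ``other`` — this interval logic is what makes the regression
network an outlier-tolerant classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .synthetic import ShapeClass

__all__ = [
    "GaussianComponent", "MixtureFit", "ThresholdSet", "SearchGrid",
    "score_histogram", "fit_four_gaussians", "thresholds_from_sigma",
    "default_search_grid", "adapt_thresholds",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted population: center, width, amplitude and its role."""

    center: float
    width: float
    amplitude: float
    role: str   # slipper | sheared_croissant | croissant | background

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")


@dataclass
class MixtureFit:
    """Four-Gaussian decomposition of the score spectrum."""

    components: list[GaussianComponent]
    fit_domain: tuple[float, float]
    fit_residual: float

    def __post_init__(self) -> None:
        roles = sorted(c.role for c in self.components)
        if roles != ["background", "croissant", "sheared_croissant", "slipper"]:
            raise ValueError("fit must carry exactly the four roles")
        s, m, c = (self[r].center for r in
                   ("slipper", "sheared_croissant", "croissant"))
        if not s < m < c:
            raise ValueError("class centers must be ordered "
                             "slipper < sheared_croissant < croissant")

    def __getitem__(self, role: str) -> GaussianComponent:
        for comp in self.components:
            if comp.role == role:
                return comp
        raise KeyError(role)

    def to_dict(self) -> dict:
        return {c.role: {"center": c.center, "width": c.width,
                         "amplitude": c.amplitude} for c in self.components}


@dataclass(frozen=True)
class ThresholdSet:
    """Class intervals on the score axis: (center, half_width) per class.

    Only slippers and croissants get intervals — the sheared croissant is an
    auxiliary training class never reported on its own.  A score inside
    neither interval is ``other``.
    """

    slipper: tuple[float, float]
    croissant: tuple[float, float]
    provenance: str = "adapted"   # e.g. "sigma_1", "sigma_2", "adapted"

    def __post_init__(self) -> None:
        if self.slipper[1] <= 0 or self.croissant[1] <= 0:
            raise ValueError("half-widths must be positive")

    def to_dict(self) -> dict:
        return {"slipper": {"center": self.slipper[0],
                            "half_width": self.slipper[1]},
                "croissant": {"center": self.croissant[0],
                              "half_width": self.croissant[1]},
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls((d["slipper"]["center"], d["slipper"]["half_width"]),
                   (d["croissant"]["center"], d["croissant"]["half_width"]),
                   d.get("provenance", "adapted"))


def score_histogram(scores, bin_width: float = 5.0):
    """Regular binning of scores; returns ``(bin_centers, counts)``.

    Bins cover ``[min, max]`` of the scores; counts sum to the number of
    scores.
    """
    s = np.asarray(scores, float)
    if s.size == 0:
        raise ValueError("cannot histogram an empty score list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(s.min()), float(s.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)     # closed last edge keeps the max in
    counts, edges = np.histogram(s, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _gauss4(x, *p):
    out = np.zeros_like(x, float)
    for mu, sig, amp in zip(p[0::3], p[1::3], p[2::3]):
        out = out + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_four_gaussians(hist: tuple[np.ndarray, np.ndarray]) -> MixtureFit:
    """Least-squares fit of four Gaussians to a binned score spectrum.

    Initialization seeds the three class centers at the three largest local
    maxima of the smoothed histogram and the background as a wide component
    (sigma = half the score range) at the overall mean.  After fitting, the
    component with the largest width is labeled ``background``; the rest are
    assigned slipper / sheared_croissant / croissant by center order.

    Requires at least 12 occupied bins; raises on degenerate input or
    non-convergence (the error carries the initialization used).
    """
    centers, counts = np.asarray(hist[0], float), np.asarray(hist[1], float)
    if np.count_nonzero(counts) < 12:
        raise ValueError(
            f"spectrum has only {np.count_nonzero(counts)} occupied bins; "
            "need >= 12 for a four-component fit")
    lo, hi = centers.min(), centers.max()
    span = hi - lo
    smooth = gaussian_filter1d(counts, 2.0)
    peaks, props = find_peaks(smooth, height=0)
    if len(peaks) >= 3:
        top = peaks[np.argsort(props["peak_heights"])[-3:]]
        seeds = np.sort(centers[top])
    else:   # flat spectrum: spread seeds over the domain
        seeds = lo + span * np.array([0.2, 0.5, 0.8])
    p0, lb, ub = [], [], []
    for mu in seeds:
        p0 += [mu, span / 12, max(smooth.max(), 1.0)]
        lb += [lo - span, 1e-3, 1e-9]
        ub += [hi + span, span, np.inf]
    mean = float(np.average(centers, weights=np.maximum(counts, 1e-9)))
    p0 += [mean, span / 2, max(counts.mean(), 1e-3)]
    lb += [lo - span, 1e-3, 1e-9]
    ub += [hi + span, 4 * span, np.inf]
    try:
        popt, _ = curve_fit(_gauss4, centers, counts, p0=p0,
                            bounds=(lb, ub), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"four-Gaussian fit did not converge (init {p0})") from err
    comps = [(popt[3 * i], popt[3 * i + 1], popt[3 * i + 2]) for i in range(4)]
    bg = max(range(4), key=lambda i: comps[i][1])
    rest = sorted((comps[i] for i in range(4) if i != bg), key=lambda c: c[0])
    roles = ["slipper", "sheared_croissant", "croissant"]
    fitted = [GaussianComponent(mu, sig, max(amp, 1e-9), role)
              for (mu, sig, amp), role in zip(rest, roles)]
    mu, sig, amp = comps[bg]
    fitted.append(GaussianComponent(mu, sig, max(amp, 1e-9), "background"))
    resid = float(np.sqrt(np.mean((_gauss4(centers, *popt) - counts) ** 2)))
    return MixtureFit(fitted, (float(lo), float(hi)), resid)


def thresholds_from_sigma(fit: MixtureFit, k: float) -> ThresholdSet:
    """``k * sigma`` confidence intervals around the slipper and croissant
    fit centers (the sheared croissant gets no interval of its own)."""
    if k <= 0:
        raise ValueError("k must be positive")
    s, c = fit["slipper"], fit["croissant"]
    return ThresholdSet((s.center, k * s.width), (c.center, k * c.width),
                        provenance=f"sigma_{k:g}")


@dataclass(frozen=True)
class SearchGrid:
    """Per-class scan grid for the adapted thresholds: candidate centers and
    half-widths for each of the two reported classes."""

    slipper_centers: np.ndarray
    slipper_half_widths: np.ndarray
    croissant_centers: np.ndarray
    croissant_half_widths: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.slipper_centers, self.slipper_half_widths,
                  self.croissant_centers, self.croissant_half_widths):
            if np.asarray(a).size == 0:
                raise ValueError("empty search grid")


def default_search_grid(fit: MixtureFit, center_step: float = 0.5,
                        width_step: float = 0.5) -> SearchGrid:
    """Grid centered on the fit: centers within +/- 1 sigma of each fitted
    class center, half-widths from 0.5 to 4 fitted sigma."""
    def axis(comp):
        cs = np.arange(comp.center - comp.width,
                       comp.center + comp.width + 1e-9, center_step)
        hw = np.arange(0.5 * comp.width, 4 * comp.width + 1e-9, width_step)
        return cs, hw
    sc, sh = axis(fit["slipper"])
    cc, ch = axis(fit["croissant"])
    return SearchGrid(sc, sh, cc, ch)


def _scan_class(scores: np.ndarray, is_member: np.ndarray,
                centers: np.ndarray, half_widths: np.ndarray
                ) -> tuple[float, float, int]:
    """Minimize FP + FN over the (center, half_width) grid for one class.

    FP: non-members inside the interval; FN: members outside.  Ties break
    towards the narrowest interval, then the lowest center.  Vectorized over
    the grid; equivalent to exhaustive enumeration.
    """
    # membership matrix: (n_centers, n_widths, n_scores) would be large;
    # loop widths (few) and vectorize centers x scores.
    centers = np.sort(centers)         # ascending order makes the
    half_widths = np.sort(half_widths)  # tie-breaks deterministic
    best = (np.inf, np.inf, np.inf)    # (cost, half_width, center)
    for hw in half_widths:
        inside = np.abs(scores[None, :] - centers[:, None]) <= hw
        fp = (inside & ~is_member[None, :]).sum(axis=1)
        fn = (~inside & is_member[None, :]).sum(axis=1)
        cost = fp + fn
        i = int(np.argmin(cost))       # argmin takes the lowest center first
        cand = (float(cost[i]), float(hw), float(centers[i]))
        if cand < best:
            best = cand
    return best[2], best[1], int(best[0])


def adapt_thresholds(scores, ref_labels, grid: SearchGrid
                     ) -> tuple[ThresholdSet, dict]:
    """Cost-optimized ("adapted") class intervals.

    For slippers and croissants independently, scan the (center,
    half-width) grid and keep the pair minimizing false positives plus
    false negatives against the reference labels.  Reference
    ``sheared_croissant`` cells count as non-members of both intervals.

    Returns the threshold set and a dict with the achieved cost per class.
    """
    s = np.asarray(scores, float)
    labels = [ShapeClass.from_name(l) if isinstance(l, str) else l
              for l in ref_labels]
    if len(labels) != s.size:
        raise ValueError("scores and labels must be congruent")
    is_slip = np.array([l is ShapeClass.SLIPPER for l in labels])
    is_croi = np.array([l is ShapeClass.CROISSANT for l in labels])
    if not is_slip.any() or not is_croi.any():
        raise ValueError("reference must contain at least one slipper "
                         "and one croissant")
    sc, sw, s_cost = _scan_class(s, is_slip, np.asarray(grid.slipper_centers, float),
                                 np.asarray(grid.slipper_half_widths, float))
    cc, cw, c_cost = _scan_class(s, is_croi, np.asarray(grid.croissant_centers, float),
                                 np.asarray(grid.croissant_half_widths, float))
    th = ThresholdSet((sc, sw), (cc, cw), provenance="adapted")
    return th, {"slipper_cost": s_cost, "croissant_cost": c_cost}
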