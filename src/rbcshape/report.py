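"""Outlier-tolerant classification, phase diagrams and confusion matrices.

Applying a :class:`~rbcshape.calibrate.ThresholdSet` to the scalar network
scores yields a three-way decision per cell: *slipper*, *croissant*, or
*other* for any score falling in neither interval.  Aggregating those
decisions per flow condition (pressure drop, or measured velocity when
available) gives the shape *phase diagram* — the fraction of each stable
morphology versus flow strength — whose slipper/croissant crossing is the
phase-transition point.  Against reference labels the decisions are
summarized in a confusion matrix with per-row percentages plus the
false-positive / false-negative id lists per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import ThresholdSet
from .synthetic import ShapeClass

__all__ = ["ClassifiedCell", "PhaseDiagram", "ConfusionMatrix",
           "classify", "classify_all", "phase_diagram", "confusion_matrix"]

PREDICTED_CATEGORIES = ("slipper", "croissant", "other")


@dataclass
class ClassifiedCell:
    """One scored cell with its predicted category and optional metadata."""

    cell_id: str
    score: float
    predicted: str
    reference: ShapeClass | None = None
    pressure_mbar: int | None = None
    velocity_mm_s: float | None = None

    @property
    def condition(self) -> float | None:
        """Flow-condition axis value: velocity when known, else pressure."""
        if self.velocity_mm_s is not None:
            return float(self.velocity_mm_s)
        if self.pressure_mbar is not None:
            return float(self.pressure_mbar)
        return None


def classify(score: float, th: ThresholdSet) -> str:
    """Assign one score to slipper / croissant / other.

    A score belongs to a class when it lies within that class's interval
    (inclusive boundaries).  If the intervals overlap and the score is in
    both, the nearer center *in units of half-widths* wins.  Everything
    else — including the sheared-croissant peak region — is ``other``.
    """
    if not np.isfinite(score):
        raise ValueError(f"non-finite score {score!r}")
    (sc, sw), (cc, cw) = th.slipper, th.croissant
    d_s = abs(score - sc) / sw
    d_c = abs(score - cc) / cw
    in_s, in_c = d_s <= 1.0, d_c <= 1.0
    if in_s and in_c:
        return "slipper" if d_s <= d_c else "croissant"
    if in_s:
        return "slipper"
    if in_c:
        return "croissant"
    return "other"


def classify_all(scores, th: ThresholdSet, ids=None, references=None,
                 pressures=None, velocities=None) -> list[ClassifiedCell]:
    """Vector version of :func:`classify` building ClassifiedCell records."""
    s = np.asarray(scores, float)
    n = s.size
    ids = [f"cell_{i:05d}" for i in range(n)] if ids is None else list(ids)
    refs = [None] * n if references is None else list(references)
    pres = [None] * n if pressures is None else list(pressures)
    vels = [None] * n if velocities is None else list(velocities)
    return [ClassifiedCell(ids[i], float(s[i]), classify(float(s[i]), th),
                           refs[i],
                           None if pres[i] is None else int(pres[i]),
                           None if vels[i] is None else float(vels[i]))
            for i in range(n)]


@dataclass
class PhaseDiagram:
    """Per-condition class fractions and the interpolated transition point."""

    table: pd.DataFrame          # condition, n, slipper_frac, croissant_frac, other_frac
    transition: float | None     # crossing of the slipper & croissant curves

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.attrs = {}
        df.to_csv(path, index=False)


def phase_diagram(cells: Sequence[ClassifiedCell]) -> PhaseDiagram:
    """Build the shape phase diagram from classified cells.

    Fractions of each predicted category are computed per distinct flow
    condition (sorted ascending); the transition point is the abscissa of
    the first crossing of the piecewise-linear slipper and croissant
    fraction curves (``None`` if the difference never changes sign).
    """
    rows = [(c.condition, c.predicted) for c in cells if c.condition is not None]
    if not rows:
        raise ValueError("no cells carry a flow-condition value")
    df = pd.DataFrame(rows, columns=["condition", "predicted"])
    tab = (df.groupby("condition")["predicted"]
             .value_counts().unstack(fill_value=0)
             .reindex(columns=PREDICTED_CATEGORIES, fill_value=0))
    n = tab.sum(axis=1)
    frac = tab.div(n, axis=0)
    out = pd.DataFrame({
        "condition": tab.index.to_numpy(float),
        "n": n.to_numpy(int),
        "slipper_frac": frac["slipper"].to_numpy(),
        "croissant_frac": frac["croissant"].to_numpy(),
        "other_frac": frac["other"].to_numpy(),
    }).sort_values("condition", ignore_index=True)
    return PhaseDiagram(out, _first_crossing(
        out["condition"].to_numpy(),
        out["slipper_frac"].to_numpy() - out["croissant_frac"].to_numpy()))


def _first_crossing(x: np.ndarray, d: np.ndarray) -> float | None:
    """Abscissa where the piecewise-linear curve d(x) first crosses zero."""
    for i in range(len(x)):
        if d[i] == 0.0:
            return float(x[i])
        if i and (d[i - 1] < 0) != (d[i] < 0):
            f = d[i - 1] / (d[i - 1] - d[i])
            return float(x[i - 1] + f * (x[i] - x[i - 1]))
    return None


@dataclass
class ConfusionMatrix:
    """Reference (rows) vs predicted (columns) cross-tabulation.

    ``counts`` and ``percentages`` (row-normalized) are DataFrames; the
    diagonal holds correctly classified cells.  ``false_positives`` /
    ``false_negatives`` list the offending cell ids per predicted class,
    mirroring the error montages one would inspect by eye.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    false_positives: dict[str, list[str]]
    false_negatives: dict[str, list[str]]

    def diagonal_accuracy(self) -> dict[str, float]:
        """Row percentage on the diagonal, per reference class present."""
        out = {}
        for ref in self.counts.index:
            if ref in self.counts.columns:
                out[ref] = float(self.percentages.loc[ref, ref])
        return out


def confusion_matrix(cells: Sequence[ClassifiedCell]) -> ConfusionMatrix:
    """Cross-tabulate reference labels against predicted categories.

    Cells without a reference label are ignored; raises if none remain.
    Reference classes keep their own rows (a 4th ``sheared_croissant`` row
    appears when such references exist), columns are the three predicted
    categories.
    """
    labeled = [c for c in cells if c.reference is not None]
    if not labeled:
        raise ValueError("no cells carry reference labels")
    ref = [c.reference.value for c in labeled]
    pred = [c.predicted for c in labeled]
    counts = pd.crosstab(pd.Series(ref, name="reference"),
                         pd.Series(pred, name="predicted"))
    counts = counts.reindex(columns=PREDICTED_CATEGORIES, fill_value=0)
    row_order = [r for r in ("slipper", "croissant", "sheared_croissant",
                             "other") if r in counts.index]
    counts = counts.loc[row_order]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    fps: dict[str, list[str]] = {k: [] for k in ("slipper", "croissant")}
    fns: dict[str, list[str]] = {k: [] for k in ("slipper", "croissant")}
    for c in labeled:
        for cls in ("slipper", "croissant"):
            if c.predicted == cls and c.reference.value != cls:
                fps[cls].append(c.cell_id)
            if c.reference.value == cls and c.predicted != cls:
                fns[cls].append(c.cell_id)
    return ConfusionMatrix(counts, pct, fps, fns)
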