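"""Dataset and manifest I/O.

Datasets on disk are a directory of 8-bit grayscale PNG (or TIFF) crops
plus a CSV manifest with columns ``filename, class, pressure_mbar, seed``.
An empty ``class`` cell marks an unlabeled image (usable for scoring but
not training).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import LabeledDataset, ShapeClass

__all__ = ["write_image", "read_image", "write_manifest", "read_manifest"]

MANIFEST_NAME = "manifest.csv"


def write_image(path: Path | str, pixels: np.ndarray) -> None:
    """Write one 8-bit grayscale crop as PNG or TIFF (by extension)."""
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def read_image(path: Path | str) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return np.asarray(arr, np.uint8)


def write_manifest(ds: LabeledDataset, out_dir: Path | str,
                   image_format: str = "png", seed: int | None = None) -> Path:
    """Write all images plus the CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(ds)):
        fname = f"cell_{i:05d}.{image_format}"
        write_image(out_dir / fname, ds.images[i])
        lab = ds.labels[i]
        rows.append({
            "filename": fname,
            "class": "" if lab is None else lab.value,
            "pressure_mbar": ("" if ds.pressures_mbar is None
                              else int(ds.pressures_mbar[i])),
            "seed": "" if seed is None else seed,
        })
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows, columns=["filename", "class", "pressure_mbar",
                                "seed"]).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: Path | str, expect_px: int = 90) -> LabeledDataset:
    """Load a dataset from a manifest CSV (paths relative to the CSV).

    Raises with the offending row number on missing columns, unknown class
    names, unreadable files, or images that are not ``expect_px`` square.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"class": "string"})
    missing = {"filename", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks required columns: {sorted(missing)}")
    images, labels, pressures = [], [], []
    has_pressure = "pressure_mbar" in df.columns
    for i, row in df.iterrows():
        try:
            img = read_image(path.parent / str(row["filename"]))
        except Exception as err:
            raise ValueError(f"manifest row {i}: cannot read "
                             f"{row['filename']!r}: {err}") from err
        if img.shape != (expect_px, expect_px):
            raise ValueError(f"manifest row {i}: image {row['filename']!r} "
                             f"is {img.shape}, expected ({expect_px}, {expect_px})")
        cls = row["class"]
        if pd.isna(cls) or str(cls).strip() == "":
            labels.append(None)
        else:
            try:
                labels.append(ShapeClass.from_name(str(cls).strip()))
            except ValueError as err:
                raise ValueError(f"manifest row {i}: {err}") from err
        images.append(img)
        if has_pressure:
            p = row["pressure_mbar"]
            pressures.append(0 if pd.isna(p) or str(p).strip() == "" else int(p))
    press = np.array(pressures) if has_pressure else None
    return LabeledDataset(np.stack(images), labels, press)
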