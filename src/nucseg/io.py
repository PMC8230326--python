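"""TIFF and manifest I/O for scenes, masks and normalized images."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .synthetic import SyntheticScene, dataset_manifest

__all__ = ["write_image", "read_image", "write_dataset", "read_dataset"]


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a grayscale image: integer masks/images as uint8/16,
    normalized images as 32-bit float."""
    x = np.asarray(img)
    if np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    tifffile.imwrite(str(path), x)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_dataset(scenes: Sequence[SyntheticScene], out_dir: str | Path) -> Path:
    """Write image_{i}.tif / labels_{i}.tif pairs plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(scenes):
        write_image(out / f"image_{i}.tif", s.image)
        write_image(out / f"labels_{i}.tif", s.labels)
    manifest = dataset_manifest(scenes)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_dataset(manifest_csv: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read (image, labels) pairs listed in a manifest CSV."""
    import pandas as pd

    manifest = pd.read_csv(manifest_csv)
    base = Path(manifest_csv).parent
    return [
        (read_image(base / row.filename), read_image(base / row.labels))
        for row in manifest.itertuples()
    ]
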