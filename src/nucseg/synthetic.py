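"""Synthetic 16-bit fluorescence nuclei scenes with exact instance labels.

Emulates the statistical structure of a DAPI-style nuclei crop collection:
512x512 single-channel 16-bit fields of view, a magnification-dependent
expected nuclei count, touching nuclei, and rare saturated hot-spot
artefacts on the background.  Every scene carries its ground-truth label
mask, so the whole segmentation/evaluation stack is testable without any
real acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MagnificationPreset",
    "SyntheticScene",
    "PRESETS",
    "generate_scene",
    "generate_dataset",
]

FULL_RANGE = 65535  # max value of a 16-bit pixel

# Background floor: dark-field DAPI background, ~2% of full range.
_BG_MEAN = 0.02 * FULL_RANGE
_BG_SIGMA = 0.006 * FULL_RANGE
# Per-nucleus peak intensity, as a fraction of full range.
_PEAK_LO, _PEAK_HI = 0.35, 0.80
# Radial intensity profile: peak * (RIM + (1-RIM) * (1 - r^2)^0.25).
# Chromatin fills the nucleus, so fluorescence looks like a bright plateau
# with a steep PSF-limited shoulder; the rim fraction keeps the boundary
# dim yet clearly above the background floor.
_RIM = 0.15
_SHOULDER_POWER = 0.25
_NUCLEUS_NOISE = 0.005 * FULL_RANGE


@dataclass(frozen=True)
class MagnificationPreset:
    """Scene statistics for one acquisition objective.

    mean_count is the expected number of nuclei per field of view;
    radius_range bounds the nucleus semi-axes in pixels; touch_fraction is
    the fraction of nuclei deliberately placed against a neighbour;
    hotspot_rate is the expected number of saturated artefact spots.
    """

    name: str
    mean_count: float
    radius_range: tuple[float, float]
    touch_fraction: float = 0.25
    hotspot_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValueError("mean_count must be non-negative")
        lo, hi = self.radius_range
        if lo > hi or lo <= 0:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if not 0.0 <= self.touch_fraction <= 1.0:
            raise ValueError("touch_fraction must lie in [0, 1]")
        if self.hotspot_rate < 0:
            raise ValueError("hotspot_rate must be >= 0")


#: Default presets for the four objectives; mean counts follow the source
#: dataset's per-magnification averages.
PRESETS: dict[str, MagnificationPreset] = {
    "20x_air": MagnificationPreset("20x_air", 145.5, (4.0, 8.0)),
    "40x_air": MagnificationPreset("40x_air", 47.2, (7.0, 12.0)),
    "40x_oil": MagnificationPreset("40x_oil", 38.1, (8.0, 13.0)),
    "63x_oil": MagnificationPreset("63x_oil", 19.4, (12.0, 20.0)),
}


@dataclass
class SyntheticScene:
    image: np.ndarray  # uint16, HxW
    labels: np.ndarray  # uint16 instance labels, 0 = background
    seed: int
    preset: MagnificationPreset
    true_count: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share a shape")
        n = int(np.count_nonzero(np.unique(self.labels)))
        if self.true_count < 0:
            self.true_count = n
        elif self.true_count != n:
            raise ValueError("true_count disagrees with the label mask")


def easy_preset(base: MagnificationPreset) -> MagnificationPreset:
    """High-contrast variant: no touching nuclei, no saturated artefacts."""
    return replace(base, touch_fraction=0.0, hotspot_rate=0.0)


def _place_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    preset: MagnificationPreset,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample nucleus centres; a touch_fraction of them abut a neighbour.

    Non-touching nuclei are rejection-sampled to keep their boundaries
    separated; after 80 failed draws the last candidate is accepted so dense
    scenes still fill up.
    """
    h, w = shape
    r_lo, r_hi = preset.radius_range
    margin = min(r_hi, min(h, w) / 2 - 1)
    centres = np.empty((n, 2))
    # mildly eccentric nuclei: minor/major axis ratio in [0.75, 1]
    major = rng.uniform(r_lo, r_hi, size=n)
    minor = np.maximum(major * rng.uniform(0.75, 1.0, size=n), r_lo)
    radii = np.column_stack([major, minor])
    r_eff = radii.mean(axis=1)
    for i in range(n):
        touching = i > 0 and rng.random() < preset.touch_fraction
        if touching:
            j = int(rng.integers(i))
            gap = (r_eff[i] + r_eff[j]) * rng.uniform(0.85, 0.95)
            phi = rng.uniform(0, 2 * np.pi)
            c = centres[j] + gap * np.array([np.cos(phi), np.sin(phi)])
            centres[i] = np.clip(c, margin, [h - 1 - margin, w - 1 - margin])
            continue
        best = None
        for _ in range(80):
            c = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
            best = c
            if i == 0:
                break
            sep = np.linalg.norm(centres[:i] - c, axis=1)
            if np.all(sep > r_eff[:i] + r_eff[i] + 2.0):
                break
        centres[i] = best
    return centres, radii


def generate_scene(
    preset: MagnificationPreset | str,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> SyntheticScene:
    """Render one seeded scene: rotated-ellipse nuclei with smooth radial
    falloff over a noisy dark background, plus saturated hot-spots.

    The same (preset, shape, seed) triple always yields a bitwise-identical
    scene.  Later nuclei overwrite earlier ones at shared pixels, so the
    label mask partitions the foreground.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise KeyError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    h, w = int(shape[0]), int(shape[1])
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64x64")

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(preset.mean_count)) if preset.mean_count > 0 else 0

    img = rng.normal(_BG_MEAN, _BG_SIGMA, size=(h, w))
    np.clip(img, 0, None, out=img)
    labels = np.zeros((h, w), dtype=np.uint16)

    if n > 0:
        centres, radii = _place_centres(rng, n, (h, w), preset)
        thetas = rng.uniform(0, np.pi, size=n)
        peaks = rng.uniform(_PEAK_LO, _PEAK_HI, size=n) * FULL_RANGE
        for k in range(n):
            (cy, cx), (a, b) = centres[k], radii[k]
            r_max = max(a, b)
            y0, y1 = int(max(0, cy - r_max - 1)), int(min(h, cy + r_max + 2))
            x0, x1 = int(max(0, cx - r_max - 1)), int(min(w, cx + r_max + 2))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            ct, st = np.cos(thetas[k]), np.sin(thetas[k])
            u = ct * (yy - cy) + st * (xx - cx)
            v = -st * (yy - cy) + ct * (xx - cx)
            r2 = (u / a) ** 2 + (v / b) ** 2
            inside = r2 <= 1.0
            profile = _RIM + (1.0 - _RIM) * np.clip(1.0 - r2, 0, None) ** _SHOULDER_POWER
            vals = peaks[k] * profile
            vals = vals + rng.normal(0, _NUCLEUS_NOISE, size=vals.shape)
            patch_img = img[y0:y1, x0:x1]
            patch_img[inside] = np.maximum(patch_img[inside], vals[inside])
            labels[y0:y1, x0:x1][inside] = k + 1

    # saturated acquisition artefacts: tiny full-scale spots on background
    n_spots = int(rng.poisson(preset.hotspot_rate)) if preset.hotspot_rate > 0 else 0
    for _ in range(n_spots):
        for _ in range(100):
            sy, sx = int(rng.integers(1, h - 1)), int(rng.integers(1, w - 1))
            if labels[sy, sx] == 0:
                break
        else:
            continue
        img[sy, sx] = FULL_RANGE
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if rng.random() < 0.5 and labels[sy + dy, sx + dx] == 0:
                img[sy + dy, sx + dx] = FULL_RANGE

    img = np.clip(np.rint(img), 0, FULL_RANGE).astype(np.uint16)
    # relabel compactly in case any nucleus was fully overwritten
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=np.uint16)
    lut[present] = np.arange(1, present.size + 1, dtype=np.uint16)
    labels = lut[labels]
    return SyntheticScene(image=img, labels=labels, seed=seed, preset=preset)


def generate_dataset(
    preset: MagnificationPreset | str,
    n: int,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> list[SyntheticScene]:
    """n scenes with per-scene seeds derived deterministically from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_scene(preset, shape, int(s)) for s in child_seeds]


def dataset_manifest(scenes: Sequence[SyntheticScene]):
    """Manifest rows (filename, preset, seed, true_count) for saved scenes."""
    import pandas as pd

    return pd.DataFrame(
        {
            "filename": [f"image_{i}.tif" for i in range(len(scenes))],
            "labels": [f"labels_{i}.tif" for i in range(len(scenes))],
            "preset": [s.preset.name for s in scenes],
            "seed": [s.seed for s in scenes],
            "true_count": [s.true_count for s in scenes],
        }
    )
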