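"""Intensity pre-processing and bit-depth requantization.

Four normalization variants are supported, mirroring the sub-dataset design
of the bit-depth study:

* D1 — divide every pixel by the full range of the bit depth (65535 for
  16-bit, 255 for 8-bit, ...);
* D2 — D1 followed by 99th-percentile outlier clipping, rescaled back into
  [0, 1];
* D3 — per-image min/max normalization, (x - min) / (max - min);
* D4 — 99th-percentile clipping on the raw image, then min/max
  normalization.

Bit-depth reduction maps a 16-bit image to b bits by round(x / 2^(16-b))
with clamping into [0, 2^b - 1]; b = 16 is the identity.  Percentiles use
the lower nearest-rank estimator, which is exact and portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "PreprocessSpec",
    "DegenerateImageError",
    "VARIANTS",
    "quantize_to_bits",
    "divide_by_full_range",
    "clip_outliers",
    "minmax_normalize",
    "make_variant",
    "resize_to_reference",
]

ALLOWED_BITS = (2, 4, 6, 8, 10, 12, 14, 16)
VARIANTS = ("D1", "D2", "D3", "D4")


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on a constant image."""


@dataclass(frozen=True)
class PreprocessSpec:
    """Which normalization variant to apply, and its clipping percentile."""

    variant: str = "D4"
    clip_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 < self.clip_percentile < 100.0:
            raise ValueError("clip_percentile must lie in (0, 100)")


def quantize_to_bits(img: np.ndarray, bits: int, *, source_bits: int = 16) -> np.ndarray:
    """Requantize a 16-bit image to ``bits`` bits.

    Each pixel maps by round(x / 2^(16-b)) — round half away from zero —
    then clamps into [0, 2^b - 1], so 65535 at b=8 yields 255, not an
    overflowed 256.  The mapping is monotone non-decreasing and b=16 is the
    identity.
    """
    if bits not in ALLOWED_BITS:
        raise ValueError(f"bits must be one of {ALLOWED_BITS}")
    if source_bits != 16:
        raise ValueError("only 16-bit sources are supported")
    x = np.asarray(img)
    if x.size == 0:
        raise ValueError("empty image")
    if bits == 16:
        return x.astype(np.uint16, copy=True)
    step = 2 ** (16 - bits)
    q = np.floor(x / step + 0.5)  # half away from zero (values are >= 0)
    return np.clip(q, 0, 2**bits - 1).astype(np.uint16)


def divide_by_full_range(img: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Variant D1: divide by 2^b - 1 so the output lies in [0, 1]."""
    if bit_depth not in ALLOWED_BITS:
        raise ValueError(f"bit_depth must be one of {ALLOWED_BITS}")
    return np.asarray(img, dtype=np.float64) / (2**bit_depth - 1)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Lower nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    flat = np.asarray(values).ravel()
    if flat.size == 0:
        raise ValueError("empty image")
    k = int(np.ceil(percentile / 100.0 * flat.size))
    k = min(max(k, 1), flat.size)
    return float(np.partition(flat, k - 1)[k - 1])


def clip_outliers(img: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Replace values above the per-image percentile threshold by it.

    Saturated hot-spots (rare, near-full-scale pixels) are the motivating
    case: after clipping, the image maximum equals the threshold.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    x = np.asarray(img)
    thr = nearest_rank_percentile(x, percentile)
    # thr is an actual pixel value, so clipping preserves the input dtype
    return np.minimum(x, x.dtype.type(thr))


def minmax_normalize(img: np.ndarray) -> np.ndarray:
    """Variant D3: (x - min) / (max - min); constant images are degenerate."""
    x = np.asarray(img, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty image")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateImageError("min/max normalization undefined on a constant image")
    return (x - lo) / (hi - lo)


def make_variant(
    img: np.ndarray,
    spec: PreprocessSpec | str = "D4",
    bit_depth: int = 16,
) -> np.ndarray:
    """Apply one of the four normalization variants; output lies in [0, 1].

    D2 clips the already-normalized image and rescales by the new maximum;
    D4 clips the raw image first and min/max-normalizes the result.
    """
    if isinstance(spec, str):
        spec = PreprocessSpec(variant=spec)
    p = spec.clip_percentile
    if spec.variant == "D1":
        return divide_by_full_range(img, bit_depth)
    if spec.variant == "D2":
        out = clip_outliers(divide_by_full_range(img, bit_depth), p)
        m = out.max()
        return out / m if m > 0 else out
    if spec.variant == "D3":
        return minmax_normalize(img)
    # D4
    return minmax_normalize(clip_outliers(np.asarray(img, dtype=np.float64), p))


def resize_to_reference(img: np.ndarray, scale: float, *, is_labels: bool = False) -> np.ndarray:
    """Resample by ``scale`` — bilinear for images, nearest for label masks.

    Used by the merged-magnification experiment to bring different
    objectives into one resolution space (e.g. 512 -> 1612 at 20x).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    x = np.asarray(img)
    out_shape = tuple(int(round(s * scale)) for s in x.shape[:2])
    if min(out_shape) < 1:
        raise ValueError("resized image would be empty")
    if is_labels:
        out = resize(x, out_shape, order=0, preserve_range=True, anti_aliasing=False)
        return out.astype(x.dtype)
    out = resize(x.astype(np.float64), out_shape, order=1, preserve_range=True, anti_aliasing=scale < 1)
    return out if np.issubdtype(x.dtype, np.floating) else np.clip(np.rint(out), 0, None).astype(x.dtype)
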