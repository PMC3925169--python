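"""Pearson mode skewness of reflected-light intensity from disc photographs.

A veneer disc photographed on a dark background yields a pixel-intensity
distribution dominated by the wood's early/latewood banding: earlywood is
pale, latewood dark. The statistic of interest is the first Pearson
skewness coefficient of the foreground intensities,

    mode_skewness = (mean - mode) / sd,

computed on the 8-bit histogram after discarding background pixels below
an intensity cutoff (default 60). Pale-dominated discs give a negative
value because the modal (earlywood) intensity sits above the mean.

Conventions (fixed, recorded in output metadata):

* images with 16-bit depth are rescaled to 8-bit; colour is collapsed
  with the Rec. 601 luminance weights (0.299 R + 0.587 G + 0.114 B);
* the mode is the intensity of the maximal histogram bin (bin width 1),
  ties broken toward the lowest intensity;
* the standard deviation is the population (divide-by-n) form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import (
    EmptyForegroundError,
    ImageIOError,
    ParameterError,
    UndefinedSkewnessError,
)

#: Rec. 601 luma weights for collapsing RGB to gray.
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_CUTOFF = 60


@dataclass
class IntensityDistribution:
    """Histogram of 8-bit pixel intensities, optionally background-cut.

    ``counts`` has 256 bins; ``cutoff`` is the background threshold
    already applied (0 = none); ``n_pixels`` is the retained pixel count.
    """

    counts: np.ndarray
    cutoff: int = 0
    n_pixels: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ParameterError("counts must be a 256-bin histogram")
        if np.any(self.counts < 0):
            raise ParameterError("histogram counts must be non-negative")
        self.n_pixels = int(self.counts.sum())

    @classmethod
    def from_gray8(cls, gray: np.ndarray) -> "IntensityDistribution":
        gray = np.asarray(gray)
        if gray.dtype != np.uint8:
            raise ParameterError("expected an 8-bit grayscale array")
        counts = np.bincount(gray.ravel(), minlength=256)
        return cls(counts=counts)


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG into an ndarray (8- or 16-bit, gray or colour)."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageIOError(f"image {path} has no pixels")
    return arr


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Collapse an image to single-channel 8-bit grayscale.

    8-bit gray input passes through unchanged; 16-bit values are rescaled
    by 255/65535; colour is collapsed with Rec. 601 luminance weights
    before requantisation. Alpha channels are ignored.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ImageIOError("image has no pixels")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ImageIOError(f"unsupported channel count {arr.shape[2]}")
        chans = arr[..., :3].astype(float)
        gray = chans @ _LUMA
    elif arr.ndim == 2:
        if arr.dtype == np.uint8:
            return arr.copy()
        gray = arr.astype(float)
    else:
        raise ImageIOError(f"unsupported image dimensionality {arr.ndim}")
    if arr.dtype == np.uint16:
        gray = gray * (255.0 / 65535.0)
    elif arr.dtype not in (np.uint8, np.dtype(float)):
        gray = np.clip(gray, 0, 255)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def background_cutoff(
    dist: IntensityDistribution, threshold: int = DEFAULT_CUTOFF
) -> IntensityDistribution:
    """Zero all histogram bins below ``threshold`` (black background removal)."""
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold must be in [0, 255], got {threshold}")
    counts = dist.counts.copy()
    counts[:threshold] = 0
    if counts.sum() == 0:
        raise EmptyForegroundError(
            f"cutoff {threshold} removed every pixel ({dist.n_pixels} total)"
        )
    return replace(dist, counts=counts, cutoff=max(dist.cutoff, threshold))


def mode_skewness(dist: IntensityDistribution) -> float:
    """First Pearson skewness coefficient, (mean - mode) / sd.

    The mode is the intensity of the maximal bin (lowest intensity on
    ties); the standard deviation is the population form. Raises
    :class:`UndefinedSkewnessError` when the distribution has no spread.
    """
    n = dist.n_pixels
    if n == 0:
        raise EmptyForegroundError("empty intensity distribution")
    if n < 2:
        raise UndefinedSkewnessError("need at least 2 pixels")
    levels = np.arange(256, dtype=float)
    mean = float(np.dot(dist.counts, levels)) / n
    mode = int(np.argmax(dist.counts))  # argmax returns the lowest tied bin
    var = float(np.dot(dist.counts, (levels - mean) ** 2)) / n
    if var == 0:
        raise UndefinedSkewnessError("zero-variance intensity distribution")
    return (mean - mode) / np.sqrt(var)


def mode_skewness_from_file(path: str | Path, cutoff: int = DEFAULT_CUTOFF) -> dict:
    """Full per-image record: read, gray-convert, cut background, summarise.

    Returns a dict with ``n_pixels``, ``mean``, ``mode``, ``sd``,
    ``mode_skewness``, ``cutoff`` and ``sd_convention``.
    """
    gray = to_gray8(read_image(path))
    dist = background_cutoff(IntensityDistribution.from_gray8(gray), cutoff)
    levels = np.arange(256, dtype=float)
    mean = float(np.dot(dist.counts, levels)) / dist.n_pixels
    mode = int(np.argmax(dist.counts))
    sd = float(
        np.sqrt(np.dot(dist.counts, (levels - mean) ** 2) / dist.n_pixels)
    )
    return {
        "path": str(path),
        "n_pixels": dist.n_pixels,
        "mean": mean,
        "mode": mode,
        "sd": sd,
        "mode_skewness": mode_skewness(dist),
        "cutoff": cutoff,
        "sd_convention": "population",
    }


def summarize_images(paths, cutoff: int = DEFAULT_CUTOFF):
    """Per-image brightness records for a batch of photographs.

    Returns a pandas DataFrame (one row per image) ready to be written
    to CSV and joined onto a specimen table.
    """
    import pandas as pd

    return pd.DataFrame([mode_skewness_from_file(p, cutoff=cutoff) for p in paths])
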