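"""Tissue-fraction morphometry: binarize, sample regions, aggregate.

Mirrors the classic ImageJ workflow: the grayscale section is converted to
a binary image with dark pixels as tissue plus infiltrating cells and light
pixels as airspace; square regions are sampled from each animal's images
(at least 15 per animal) and the tissue fraction of a region is the ratio
of tissue pixels to total pixels.  Per-animal statistics are the mean and
sample SD of the pooled region fractions, reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_mean, threshold_otsu

from .histology import HistologyImage

__all__ = [
    "MorphometryError",
    "Region",
    "TFResult",
    "binarize",
    "sample_regions",
    "tissue_fraction",
    "measure_animal",
]


class MorphometryError(ValueError):
    pass


class Region(NamedTuple):
    row: int
    col: int
    size: int


@dataclass(frozen=True)
class TFResult:
    """Per-animal tissue-fraction statistics over sampled regions."""

    animal_id: str
    region_tfs: tuple                # fractions in [0, 1]
    tf_mean: float                   # percent
    tf_sd: float                     # percent, sample SD (ddof=1)
    n_regions: int
    threshold_used: float
    region_size_px: int


def _as_array(image) -> np.ndarray:
    if isinstance(image, HistologyImage):
        return image.pixels
    return np.asarray(image)


def binarize(image, method: str = "otsu", tissue_is_dark: bool = True):
    """Global threshold; returns (mask, threshold) with True = tissue.

    ``method`` is "otsu" (default) or "mean".  ``tissue_is_dark=False``
    handles inverted-polarity inputs (light tissue on dark background).
    """
    arr = _as_array(image)
    if arr.ndim != 2:
        raise MorphometryError("expected a 2D grayscale image")
    if np.ptp(arr) == 0:
        raise MorphometryError("constant image: no separable threshold")
    if method == "otsu":
        thr = float(threshold_otsu(arr))
    elif method == "mean":
        thr = float(threshold_mean(arr))
    else:
        raise MorphometryError(f"unknown threshold method {method!r}")
    # threshold-level pixels go to the dark class (Otsu returns the lower
    # class level for a two-valued image), so inverting the image and the
    # polarity flag yields the identical mask
    mask = arr <= thr if tissue_is_dark else arr > thr
    return mask, thr


def sample_regions(
    image, n: int = 15, size_px: int = 256, rng: "np.random.Generator | int | None" = None
) -> list:
    """Sample n axis-aligned square regions uniformly at random.

    Overlap between regions is allowed; placement is deterministic given
    the rng state.
    """
    arr = _as_array(image)
    h, w = arr.shape
    if n < 1:
        raise MorphometryError("need at least one region")
    if size_px > min(h, w):
        raise MorphometryError(f"region size {size_px} exceeds image {arr.shape}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = rng.integers(0, h - size_px + 1, size=n)
    cols = rng.integers(0, w - size_px + 1, size=n)
    return [Region(int(r), int(c), size_px) for r, c in zip(rows, cols)]


def region_fractions(mask: np.ndarray, regions: Sequence[Region]) -> np.ndarray:
    if len(regions) == 0:
        raise MorphometryError("empty region list")
    return np.array(
        [mask[r.row : r.row + r.size, r.col : r.col + r.size].mean() for r in regions]
    )


def tissue_fraction(
    mask: np.ndarray,
    regions: Sequence[Region],
    animal_id: str = "",
    threshold_used: float = float("nan"),
) -> TFResult:
    """Aggregate per-region tissue fractions into per-animal statistics."""
    if mask.dtype != bool:
        raise MorphometryError("mask must be boolean")
    tfs = region_fractions(mask, regions)
    sd = float(np.std(tfs, ddof=1)) if len(tfs) > 1 else float("nan")
    return TFResult(
        animal_id=animal_id,
        region_tfs=tuple(float(v) for v in tfs),
        tf_mean=float(np.mean(tfs)) * 100.0,
        tf_sd=sd * 100.0,
        n_regions=len(tfs),
        threshold_used=threshold_used,
        region_size_px=regions[0].size,
    )


def measure_animal(
    images: Sequence,
    animal_id: str = "",
    n_regions_per_image: int = 15,
    region_size_px: int = 256,
    rng: "np.random.Generator | int | None" = None,
    method: str = "otsu",
) -> TFResult:
    """Binarize and region-sample all of one animal's images, pooling regions."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    all_tfs: list = []
    thresholds: list = []
    size = region_size_px
    for image in images:
        mask, thr = binarize(image, method=method)
        regions = sample_regions(image, n=n_regions_per_image, size_px=size, rng=rng)
        all_tfs.extend(region_fractions(mask, regions))
        thresholds.append(thr)
    tfs = np.asarray(all_tfs)
    sd = float(np.std(tfs, ddof=1)) if len(tfs) > 1 else float("nan")
    return TFResult(
        animal_id=animal_id,
        region_tfs=tuple(float(v) for v in tfs),
        tf_mean=float(np.mean(tfs)) * 100.0,
        tf_sd=sd * 100.0,
        n_regions=len(tfs),
        threshold_used=float(np.mean(thresholds)),
        region_size_px=size,
    )


def tf_frame(results: Sequence[TFResult], groups: "dict | None" = None) -> pd.DataFrame:
    """Tidy per-animal TF table."""
    rows = []
    for r in results:
        row = {
            "animal_id": r.animal_id,
            "tf_mean": r.tf_mean,
            "tf_sd": r.tf_sd,
            "n_regions": r.n_regions,
            "threshold": r.threshold_used,
        }
        if groups and r.animal_id in groups:
            row["group"] = groups[r.animal_id]
        rows.append(row)
    return pd.DataFrame(rows)
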