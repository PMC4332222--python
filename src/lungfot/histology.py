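"""Synthetic lung micrographs with known tissue fraction.

The generator is a morphological cartoon of a hematoxylin-eosin section:
dark tissue on a light airspace background.  It renders

* an alveolar wall network — the edge skeleton of a Voronoi tessellation of
  random seed points, with walls of controllable thickness;
* vessels/bronchioles — ring walls around circular lumina;
* perivascular infiltrate blobs whose count and size grow with rejection
  grade, plus (severe grade) free consolidation foci emulating septal and
  airspace involvement.

All structures are expressed as one signed distance-like field D(x); tissue
is ``D < t`` and a bisection on the scale ``t`` calibrates the rendered
tissue fraction to the requested per-animal target within +/-0.005 before
blur and pixel noise are applied.  The realised pre-noise fraction is
recorded as ``tf_truth``.

Only tissue fraction, its spatial dispersion, and the grade ordering of
infiltrate burden are contracted properties; the images are not meant to be
histologically realistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .presets import GradePreset, HistologyPreset, PresetLibrary, load_presets

__all__ = [
    "HistologyImage",
    "CalibrationError",
    "generate_histology",
    "write_image",
    "read_image",
]

TISSUE_GRAY = 40.0
AIR_GRAY = 220.0


class CalibrationError(RuntimeError):
    """Tissue-fraction calibration failed to converge."""

    def __init__(self, message: str, last_fraction: float):
        super().__init__(message)
        self.last_fraction = last_fraction


@dataclass(frozen=True)
class HistologyImage:
    """8-bit grayscale synthetic micrograph with known ground truth."""

    pixels: np.ndarray                  # uint8, 2D
    pixel_size_um: float = 0.5
    tf_truth: float | None = None       # realised pre-noise tissue fraction
    grade_label: str = ""
    seed: int | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.tf_truth is not None and not 0.0 < self.tf_truth < 1.0:
            raise ValueError("tf_truth must lie strictly in (0, 1)")


def _rint(rng: np.random.Generator, lohi) -> int:
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)


def _periodic_dist(yy, xx, c, size) -> np.ndarray:
    """Euclidean distance to a point on the size-periodic torus."""
    dy = np.abs(yy - c[0])
    dx = np.abs(xx - c[1])
    dy = np.minimum(dy, size - dy)
    dx = np.minimum(dx, size - dx)
    return np.hypot(dy, dx)


def _distance_field(
    hist: HistologyPreset, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Combined structure field; tissue at scale t is {D < t}.

    All geometry is periodic (toroidal), so the rendered texture is
    statistically stationary: uniformly placed sampling regions see the
    same tissue statistics anywhere in the field of view.  Structure sizes
    are physical (pixels at the nominal magnification) and stay fixed;
    structure counts scale with the field area so smaller renderings are
    smaller fields of the same tissue, not shrunken cartoons.
    """
    area_scale = (size / 1024.0) ** 2
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    pts = np.column_stack([yy.ravel(), xx.ravel()])

    # alveolar wall network: distance to the Voronoi edges of random seeds,
    # computed as half the gap between the two nearest seeds
    n_cells = max(4, round(hist.n_cells * area_scale))
    seeds = rng.uniform(0, size, size=(n_cells, 2))
    d2, _ = cKDTree(seeds, boxsize=size).query(pts, k=2)
    d_wall = ((d2[:, 1] - d2[:, 0]) / 2.0).reshape(size, size)

    fields = [d_wall]

    # vessels: ring walls |r - R| around circular lumina, slightly thicker
    # than the alveolar septa
    n_vessels = round(_rint(rng, hist.n_vessels) * area_scale)
    centers = []
    radii = []
    for _ in range(n_vessels):
        c = rng.uniform(0, size, size=2)
        r = rng.uniform(*hist.vessel_r)
        centers.append(c)
        radii.append(r)
        fields.append(np.abs(_periodic_dist(yy, xx, c, size) - r) / 1.3)

    # perivascular infiltrates: blobs seeded just outside vessel walls
    n_inf = round(_rint(rng, hist.n_infiltrates) * area_scale)
    for _ in range(n_inf):
        if centers:
            v = int(rng.integers(len(centers)))
            theta = rng.uniform(0, 2 * np.pi)
            rad = radii[v] + rng.uniform(0.0, 0.8 * radii[v])
            c = (centers[v] + rad * np.array([np.sin(theta), np.cos(theta)])) % size
        else:
            c = rng.uniform(0, size, size=2)
        r0 = rng.uniform(*hist.infiltrate_r0)
        soft = rng.uniform(1.0, 2.5)
        fields.append((_periodic_dist(yy, xx, c, size) - r0) / soft)

    # free consolidation foci (severe grade): interstitial/airspace filling
    n_con = round(_rint(rng, hist.n_consolidations) * area_scale)
    for _ in range(n_con):
        c = rng.uniform(0, size, size=2)
        r0 = rng.uniform(*hist.consolidation_r0)
        soft = rng.uniform(1.5, 3.0)
        fields.append((_periodic_dist(yy, xx, c, size) - r0) / soft)

    return np.min(np.stack(fields), axis=0)


def _calibrate_threshold(
    d_field: np.ndarray, target: float, tol: float, max_iter: int
) -> tuple:
    """Bisection on the scale t so that fraction(D < t) hits the target."""
    lo, hi = 0.0, 4.0
    frac = float(np.mean(d_field < hi))
    expand = 0
    while frac < target and expand < 12:
        hi *= 2.0
        frac = float(np.mean(d_field < hi))
        expand += 1
    if frac < target:
        raise CalibrationError(
            f"cannot reach tissue fraction {target}: maximum achievable {frac:.3f}",
            frac,
        )
    t, last = hi, frac
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        last = float(np.mean(d_field < t))
        if abs(last - target) <= tol:
            return t, last
        if last < target:
            lo = t
        else:
            hi = t
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(last fraction {last:.4f}, target {target:.4f})",
        last,
    )


def generate_histology(
    grade_preset: GradePreset,
    rng: "np.random.Generator | int",
    tf_target: float | None = None,
    size_px: int = 1024,
    pixel_size_um: float = 0.5,
    blur_sigma: float = 1.0,
    noise_sd: float = 8.0,
    tf_tol: float = 0.005,
    max_iter: int = 50,
) -> HistologyImage:
    """Render one synthetic micrograph for a grade preset.

    ``tf_target`` defaults to a draw from the grade's per-animal TF
    distribution (normal, truncated to (0.05, 0.95)).  The pre-noise binary
    rendering is calibrated to the target within ``tf_tol``; the achieved
    fraction is stored as ``tf_truth``.  Identical seeds yield identical
    image bytes.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    if tf_target is None:
        from .simulate import _tnorm

        tf_target = float(_tnorm(rng, grade_preset.tf_mean, grade_preset.tf_sd, 0.05, 0.95))
    if not 0.0 < tf_target < 1.0:
        raise ValueError("tissue-fraction target must lie strictly in (0, 1)")

    d_field = _distance_field(grade_preset.histology, rng, size_px)
    t, achieved = _calibrate_threshold(d_field, tf_target, tf_tol, max_iter)
    tissue = d_field < t

    gray = np.where(tissue, TISSUE_GRAY, AIR_GRAY).astype(float)
    if blur_sigma > 0:
        gray = gaussian_filter(gray, blur_sigma, mode="wrap")
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)

    return HistologyImage(
        pixels=pixels,
        pixel_size_um=pixel_size_um,
        tf_truth=achieved,
        grade_label=grade_preset.label,
        seed=seed,
        meta={"tf_target": tf_target, "threshold_scale": t},
    )


# ---------------------------------------------------------------------------
# lossless I/O with a JSON sidecar for the ground truth

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_image(image: HistologyImage, path) -> None:
    """Write a losslessly encoded image (PNG or TIFF) plus JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        Image.fromarray(image.pixels).save(path, format="PNG")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        raise ValueError(f"refusing lossy/unknown format {suffix!r}; use .png or .tif")
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "tf_truth": image.tf_truth,
        "grade_label": image.grade_label,
        "seed": image.seed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_image(path) -> HistologyImage:
    """Read an image and its sidecar; without a sidecar tf_truth is unknown."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        arr = np.asarray(Image.open(path))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported format {suffix!r}")
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint16:
        warnings.warn("16-bit input rescaled to 8-bit", stacklevel=2)
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return HistologyImage(
            pixels=arr,
            pixel_size_um=float(meta.get("pixel_size_um", 0.5)),
            tf_truth=meta.get("tf_truth"),
            grade_label=meta.get("grade_label", ""),
            seed=meta.get("seed"),
        )
    return HistologyImage(pixels=arr, tf_truth=None)
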