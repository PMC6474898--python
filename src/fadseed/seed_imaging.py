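"""Seed photograph segmentation and morphometrics.

Re-implementation of the "Sid" style seed image tool: a single seed is
photographed against a contrasting background and decomposed into three
binary layers — the seed body, the dark pigmentation spots on the seed
coat, and the pale elaiosome appendage at one pole.  The central phenotype
is *percent spot cover*: the spot-layer area divided by the seed-body area.

Algorithmic choices (the original tool's algorithm is not published):

* foreground/background separation by grayscale Otsu threshold, followed by
  morphological opening and closing (configurable structuring-element
  radius, default 2 px) and largest-connected-component selection;
* spot layer by a second Otsu threshold computed over seed-body pixels
  only, guarded by a minimum dark/light contrast so an unspotted seed coat
  is not split in half by its own noise;
* elaiosome by a hue + brightness gate (pale, yellow-shifted pixels) on the
  region outside the seed body, keeping the largest component adjacent to
  the seed boundary.

Conventions: 8-connected components; row-major coordinates, origin top-left,
0-based; bounding boxes half-open.  The seed "total area" excludes the
elaiosome — spot cover is a property of the seed coat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.measure import label

logger = logging.getLogger(__name__)

#: 8-connectivity structure for component labelling.
_CONN8 = np.ones((3, 3), dtype=bool)


class SegmentationError(ValueError):
    """Raised when an image cannot be decomposed into the expected layers."""


@dataclass
class SeedImage:
    """An RGB seed photograph with optional physical scale.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    scale
        Physical length per pixel (e.g. mm/px); areas are converted by
        ``scale**2`` when given.
    source
        Identifier of the image origin (file name, generator tag).
    """

    pixels: np.ndarray
    scale: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("SeedImage requires a non-empty (H, W, 3) array")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MaskSet:
    """The three binary layers of a segmented seed photograph.

    Invariants enforced at construction: all masks share one shape, the
    spot mask is a subset of the seed-body mask, and the elaiosome mask is
    disjoint from the seed body.
    """

    seed: np.ndarray
    spot: np.ndarray
    elaiosome: np.ndarray

    def __post_init__(self) -> None:
        self.seed = np.asarray(self.seed, dtype=bool)
        self.spot = np.asarray(self.spot, dtype=bool)
        self.elaiosome = np.asarray(self.elaiosome, dtype=bool)
        if not (self.seed.shape == self.spot.shape == self.elaiosome.shape):
            raise ValueError("mask shapes differ")
        if np.any(self.spot & ~self.seed):
            raise ValueError("spot mask must be a subset of the seed-body mask")
        if np.any(self.elaiosome & self.seed):
            raise ValueError("elaiosome mask must be disjoint from the seed body")

    @property
    def shape(self) -> tuple[int, int]:
        return self.seed.shape


@dataclass
class SeedMorphometrics:
    """Per-seed area measurements and the percent-spot-cover statistic.

    Areas are in pixels unless a physical scale was supplied, in which case
    they are in ``scale**2`` units.  ``bbox`` is half-open
    ``(min_row, min_col, max_row, max_col)`` over the seed body.
    """

    seed_area: float
    spot_area: float
    spot_cover_pct: float
    elaiosome_area: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.spot_cover_pct <= 100.0):
            raise ValueError("spot cover must be within [0, 100]")
        if self.spot_area > self.seed_area:
            raise ValueError("spot area cannot exceed seed area")
        if min(self.seed_area, self.spot_area, self.elaiosome_area) < 0:
            raise ValueError("areas must be non-negative")


@dataclass
class SegmentationConfig:
    """Tunable thresholds of the segmentation pipeline.

    morph_radius
        Structuring-element radius (px) for opening/closing of the
        foreground mask; rejects speckle and smooths the outline.
    min_component_frac
        Minimum seed candidate size as a fraction of image area (rejects
        dust).
    min_spot_contrast
        Minimum gray-level separation (0-255 scale) between the dark and
        light classes inside the seed body for the spot threshold to be
        accepted; below it the seed is declared spotless.
    elaiosome_yellowness / elaiosome_brightness
        Gates for elaiosome pixels: ``(R+G)/2 - B`` must exceed the former
        and grayscale brightness the latter.
    """

    morph_radius: int = 2
    min_component_frac: float = 0.005
    min_spot_contrast: float = 25.0
    elaiosome_yellowness: float = 35.0
    elaiosome_brightness: float = 175.0


def _grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luma grayscale on the 0-255 scale."""
    px = pixels.astype(np.float64)
    return 0.2125 * px[..., 0] + 0.7154 * px[..., 1] + 0.0721 * px[..., 2]


def segment_seed(
    image: SeedImage, config: SegmentationConfig | None = None
) -> MaskSet:
    """Segment a single-seed photograph into seed / spot / elaiosome layers.

    Parameters
    ----------
    image
        Photograph containing at most one seed against a lighter background.
    config
        Threshold settings; defaults are tuned for microscope images with a
        neutral pale background.

    Returns
    -------
    MaskSet
        Binary layers satisfying the :class:`MaskSet` invariants.

    Raises
    ------
    SegmentationError
        If no foreground component exceeds the minimum size ("no seed
        detected") or several candidate seeds do (ambiguous scene).
    """
    cfg = config or SegmentationConfig()
    gray = _grayscale(image.pixels)

    fg = gray < threshold_otsu(gray)
    selem = disk(cfg.morph_radius)
    fg = ndi.binary_opening(fg, structure=selem)
    fg = ndi.binary_closing(fg, structure=selem)

    labels, n = label(fg, connectivity=2, return_num=True)
    min_px = cfg.min_component_frac * gray.size
    sizes = np.bincount(labels.ravel())[1:] if n else np.array([])
    candidates = [i + 1 for i, s in enumerate(sizes) if s >= min_px]
    if not candidates:
        raise SegmentationError("no seed detected (no component above minimum size)")
    if len(candidates) > 1:
        listing = ", ".join(
            f"component {c}: {sizes[c - 1]} px" for c in candidates
        )
        raise SegmentationError(f"multiple candidate seeds detected ({listing})")
    seed_mask = ndi.binary_fill_holes(labels == candidates[0])

    spot_mask = _segment_spots(gray, seed_mask, cfg)
    elaiosome_mask = _segment_elaiosome(image.pixels, gray, seed_mask, cfg)
    return MaskSet(seed=seed_mask, spot=spot_mask, elaiosome=elaiosome_mask)


def _segment_spots(
    gray: np.ndarray, seed_mask: np.ndarray, cfg: SegmentationConfig
) -> np.ndarray:
    """Per-seed Otsu on body pixels, accepted only above a contrast floor."""
    vals = gray[seed_mask]
    if vals.size < 2 or np.ptp(vals) == 0:
        return np.zeros_like(seed_mask)
    thr = threshold_otsu(vals)
    dark, light = vals[vals < thr], vals[vals >= thr]
    if dark.size == 0 or light.size == 0:
        return np.zeros_like(seed_mask)
    if light.mean() - dark.mean() < cfg.min_spot_contrast:
        return np.zeros_like(seed_mask)  # unimodal coat: spotless seed
    return seed_mask & (gray < thr)


def _segment_elaiosome(
    pixels: np.ndarray, gray: np.ndarray, seed_mask: np.ndarray, cfg: SegmentationConfig
) -> np.ndarray:
    """Pale yellow-shifted component adjacent to the seed-body boundary."""
    px = pixels.astype(np.float64)
    yellowness = (px[..., 0] + px[..., 1]) / 2.0 - px[..., 2]
    cand = (
        (yellowness > cfg.elaiosome_yellowness)
        & (gray > cfg.elaiosome_brightness)
        & ~seed_mask
    )
    cand = ndi.binary_opening(cand, structure=disk(1))
    if not cand.any():
        return np.zeros_like(seed_mask)
    near_seed = ndi.binary_dilation(seed_mask, structure=_CONN8, iterations=3)
    labels, n = label(cand, connectivity=2, return_num=True)
    best, best_size = 0, 0
    for i in range(1, n + 1):
        comp = labels == i
        if not np.any(comp & near_seed):
            continue
        size = int(comp.sum())
        if size > best_size:
            best, best_size = i, size
    if best == 0:
        return np.zeros_like(seed_mask)
    return labels == best


def measure_seed(
    masks: MaskSet, scale: Optional[float] = None
) -> SeedMorphometrics:
    """Compute areas, percent spot cover, centroid and bounding box.

    ``spot_cover_pct = 100 * spot_pixels / seed_body_pixels``; the seed-body
    denominator excludes the elaiosome by construction.  Pixel areas are
    multiplied by ``scale**2`` when a physical scale is given.

    Raises
    ------
    ValueError
        If the seed-body mask is empty.
    """
    seed_px = int(masks.seed.sum())
    if seed_px == 0:
        raise ValueError("empty seed-body mask: nothing to measure")
    spot_px = int(masks.spot.sum())
    ela_px = int(masks.elaiosome.sum())
    cover = 100.0 * spot_px / seed_px

    rows, cols = np.nonzero(masks.seed)
    centroid = (float(rows.mean()), float(cols.mean()))
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)

    factor = scale**2 if scale is not None else 1.0
    return SeedMorphometrics(
        seed_area=seed_px * factor,
        spot_area=spot_px * factor,
        spot_cover_pct=cover,
        elaiosome_area=ela_px * factor,
        centroid=centroid,
        bbox=bbox,
    )


#: Overlay colors: spots green, elaiosome red.
_SPOT_RGB = np.array([0, 255, 0], dtype=np.uint8)
_ELA_RGB = np.array([255, 0, 0], dtype=np.uint8)


def render_layers(image: SeedImage, masks: MaskSet) -> np.ndarray:
    """Four-panel composite: original, spot overlay, elaiosome overlay, both.

    The output is a 2x2 tiling of the input (top row: original | spots in
    green; bottom row: elaiosome in red | combined overlay).  Overlays
    replace masked pixels with the layer color and leave others untouched,
    so empty masks reproduce the original exactly.
    """
    if masks.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    spot_panel = image.pixels.copy()
    spot_panel[masks.spot] = _SPOT_RGB
    ela_panel = image.pixels.copy()
    ela_panel[masks.elaiosome] = _ELA_RGB
    both_panel = image.pixels.copy()
    both_panel[masks.spot] = _SPOT_RGB
    both_panel[masks.elaiosome] = _ELA_RGB

    out = np.empty((2 * h, 2 * w, 3), dtype=np.uint8)
    out[:h, :w] = image.pixels
    out[:h, w:] = spot_panel
    out[h:, :w] = ela_panel
    out[h:, w:] = both_panel
    return out


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def batch_measure(
    image_dir: str | Path,
    config: SegmentationConfig | None = None,
    scale: Optional[float] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Segment and measure every PNG/TIFF image in a directory.

    Returns a table with one row per successfully processed image (sorted
    by file name, so reruns are reproducible) and a list of
    ``(file name, error message)`` pairs for failures, which are also
    logged — never silently dropped.

    Raises
    ------
    ValueError
        If the directory contains no image files.
    """
    image_dir = Path(image_dir)
    files = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"no PNG/TIFF images found in {image_dir}")

    rows = []
    failures: list[tuple[str, str]] = []
    for path in files:
        try:
            arr = np.asarray(Image.open(path).convert("RGB"))
            img = SeedImage(pixels=arr, scale=scale, source=path.name)
            masks = segment_seed(img, config)
            m = measure_seed(masks, scale=scale)
        except Exception as exc:  # noqa: BLE001 - contract: log and continue
            logger.warning("failed to process %s: %s", path.name, exc)
            failures.append((path.name, str(exc)))
            continue
        rows.append(
            {
                "source": path.name,
                "seed_area_px": m.seed_area,
                "spot_area_px": m.spot_area,
                "spot_cover_pct": m.spot_cover_pct,
                "elaiosome_area_px": m.elaiosome_area,
                "centroid_row": m.centroid[0],
                "centroid_col": m.centroid[1],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "source",
            "seed_area_px",
            "spot_area_px",
            "spot_cover_pct",
            "elaiosome_area_px",
            "centroid_row",
            "centroid_col",
        ],
    )
    return table, failures
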