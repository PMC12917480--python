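"""Raster preprocessing: tissue masking, tessellation, and polygon labeling.

Turns a stained-tissue raster plus optional expert polygon annotations into a
feature bag: a multilevel-Otsu tissue mask separates tissue from the bright
glass background, the image is tessellated into non-overlapping square tiles
(default 224 px), tiles with less than 5% tissue coverage are discarded, and
each retained tile is labeled positive iff it overlaps an annotation polygon
with strictly positive area. Polygon buffering simulates coarser annotations.

The module is magnification-agnostic: images and polygons must share one
coordinate frame, and any cross-magnification scaling (e.g. annotation pixels
drawn at twice the tiling resolution) is a factor the caller applies before
calling in. Coordinates are 0-based and tiles are half-open
``[x0, x0 + patch_size)``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu

from .bags import Bag

__all__ = [
    "PolygonAnnotation",
    "TileGrid",
    "tissue_mask",
    "tessellate_and_filter",
    "label_patches",
    "pad_annotation",
    "build_bag_from_image",
    "load_annotation",
]


@dataclass
class PolygonAnnotation:
    """Expert lesion annotation: a list of polygon vertex lists (pixel coords)."""

    slide_id: str
    polygons: list
    class_tag: str = "lesion"

    def __post_init__(self) -> None:
        for poly in self.polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
                raise ValueError("each polygon needs >= 3 (x, y) vertices")
            if (arr < 0).any():
                raise ValueError("polygon coordinates must be non-negative")

    def to_geometry(self):
        """Union of all polygons as one (multi)polygon; invalid rings repaired."""
        geoms = [Polygon(p).buffer(0) for p in self.polygons]
        return shapely.union_all(geoms)


def load_annotation(path: str | os.PathLike) -> PolygonAnnotation:
    """Read a GeoJSON-like annotation file: {slide_id, polygons, class}."""
    with open(path) as f:
        data = json.load(f)
    return PolygonAnnotation(
        slide_id=data["slide_id"],
        polygons=data["polygons"],
        class_tag=data.get("class", "lesion"),
    )


@dataclass
class TileGrid:
    """Retained tiles of a tessellation: (row, col, x0, y0) per tile, row-major."""

    patch_size: int = 224
    stride: int | None = None
    tiles: list = None  # list of (row, col, x0, y0)

    def __post_init__(self) -> None:
        if self.stride is None:
            self.stride = self.patch_size
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.tiles is None:
            self.tiles = []

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def coords(self) -> np.ndarray:
        return np.array([(r, c) for r, c, _, _ in self.tiles], dtype=np.int64).reshape(-1, 2)


def _binary_between_class_variance(image: np.ndarray, t: float) -> float:
    lo = image < t
    w0 = lo.mean()
    if w0 == 0.0 or w0 == 1.0:
        return 0.0
    return w0 * (1.0 - w0) * (image[lo].mean() - image[~lo].mean()) ** 2


def tissue_mask(image: np.ndarray, levels: int = 3) -> np.ndarray:
    """Binary tissue mask from a multilevel Otsu threshold.

    RGB input is converted to grayscale first. Multilevel Otsu with
    ``levels`` classes yields ``levels - 1`` candidate cuts; the
    tissue/background cut is the candidate with maximal *binary*
    between-class variance, and tissue (foreground) is everything below it —
    on stained-tissue rasters the bright glass background sits above the
    best cut. On a bimodal image this reduces exactly to the 2-class Otsu
    threshold (picking the top cut blindly would split whichever mode the
    extra class subdivides). A degenerate image (too few distinct gray
    values to separate classes) yields an empty mask with a warning rather
    than an exception.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb2gray(image)
    for classes in range(levels, 1, -1):
        # images with too few distinct gray values cannot support `levels`
        # classes; degrade to fewer classes before giving up
        try:
            thresholds = threshold_multiotsu(image, classes=classes)
        except ValueError:
            continue
        best = max(thresholds, key=lambda t: _binary_between_class_variance(image, t))
        return image < best
    warnings.warn("degenerate image (no separable background class); empty tissue mask")
    return np.zeros(image.shape, dtype=bool)


def tessellate_and_filter(
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 224,
    stride: int | None = None,
    min_tissue_fraction: float = 0.05,
) -> TileGrid:
    """Tile the image and keep tiles with mask coverage >= min_tissue_fraction.

    Tiles lie fully inside the image and are enumerated row-major. The
    boundary is inclusive: a tile with coverage exactly at the threshold is
    kept ("less than 5% tissue" is discarded).
    """
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    if stride is None:
        stride = patch_size
    h, w = mask.shape[:2]
    if patch_size > h or patch_size > w:
        warnings.warn(f"patch_size {patch_size} exceeds image extent ({h}x{w}); zero tiles")
        return TileGrid(patch_size, stride, [])
    tiles = []
    area = float(patch_size * patch_size)
    for row, y0 in enumerate(range(0, h - patch_size + 1, stride)):
        for col, x0 in enumerate(range(0, w - patch_size + 1, stride)):
            coverage = mask[y0 : y0 + patch_size, x0 : x0 + patch_size].sum() / area
            if coverage >= min_tissue_fraction:
                tiles.append((row, col, x0, y0))
    return TileGrid(patch_size, stride, tiles)


def label_patches(
    grid: TileGrid,
    annotation: PolygonAnnotation | None,
    image_shape: tuple | None = None,
    min_overlap_fraction: float = 0.0,
) -> np.ndarray:
    """Binary patch labels: y_k = 1 iff tile k overlaps the annotation union.

    Overlap means strictly positive intersection area (a shared edge does not
    count); ``min_overlap_fraction`` > 0 requires that fraction of the tile
    area instead. Warns when the annotation lies entirely outside the image
    (likely a coordinate-frame mismatch).
    """
    y = np.zeros(len(grid), dtype=np.int8)
    if annotation is None or not annotation.polygons:
        return y
    geom = annotation.to_geometry()
    if image_shape is not None:
        h, w = image_shape[:2]
        minx, miny, maxx, maxy = geom.bounds
        if maxx <= 0 or maxy <= 0 or minx >= w or miny >= h:
            warnings.warn(
                f"{annotation.slide_id}: annotation bounding box lies outside the image; "
                "possible coordinate-frame mismatch"
            )
    p = grid.patch_size
    cutoff = min_overlap_fraction * p * p
    for k, (_, _, x0, y0) in enumerate(grid.tiles):
        area = box(x0, y0, x0 + p, y0 + p).intersection(geom).area
        y[k] = 1 if (area > cutoff if min_overlap_fraction > 0 else area > 0) else 0
    return y


def pad_annotation(annotation: PolygonAnnotation, padding_px: float) -> PolygonAnnotation:
    """Dilate every polygon outward by ``padding_px`` (Minkowski buffer).

    Simulates coarse expert annotations; padding 0 is the identity. Buffered
    polygons that merge stay merged (the result may have fewer, larger parts).
    """
    if padding_px < 0:
        raise ValueError("padding must be >= 0")
    if padding_px == 0:
        return replace(annotation, polygons=[list(map(list, p)) for p in annotation.polygons])
    buffered = annotation.to_geometry().buffer(padding_px)
    parts = getattr(buffered, "geoms", [buffered])
    polygons = [np.asarray(part.exterior.coords)[:-1].clip(min=0.0).tolist() for part in parts]
    return replace(annotation, polygons=polygons)


def build_bag_from_image(
    image: np.ndarray,
    annotation: PolygonAnnotation | None,
    feature_fn,
    slide_id: str = "slide",
    slide_label: int | None = None,
    patch_size: int = 224,
    min_tissue_fraction: float = 0.05,
    otsu_levels: int = 3,
) -> Bag:
    """Full preprocessing pipeline: mask -> tessellate -> label -> featurize.

    ``feature_fn(tile_pixels) -> 1-d vector`` supplies the patch embedding
    (any fixed dimension). The slide label defaults to 1 iff any patch label
    is positive. Raises when no tile survives filtering ("empty bag").
    """
    image = np.asarray(image)
    mask = tissue_mask(image, levels=otsu_levels)
    grid = tessellate_and_filter(image, mask, patch_size=patch_size, min_tissue_fraction=min_tissue_fraction)
    if len(grid) == 0:
        raise ValueError(f"{slide_id}: empty bag (no tiles passed the tissue filter)")
    y = label_patches(grid, annotation, image_shape=image.shape) if annotation is not None else None
    features = []
    for _, _, x0, y0 in grid.tiles:
        vec = np.asarray(feature_fn(image[y0 : y0 + patch_size, x0 : x0 + patch_size]), dtype=float)
        if vec.ndim != 1 or not np.all(np.isfinite(vec)):
            raise ValueError("feature_fn must return a finite 1-d vector")
        features.append(vec)
    if slide_label is None:
        slide_label = int(y.any()) if y is not None else 0
    if y is not None and slide_label == 0 and y.any():
        raise ValueError(f"{slide_id}: slide labeled negative but annotation marks patches")
    return Bag(
        slide_id=slide_id,
        features=np.stack(features),
        slide_label=slide_label,
        patch_labels=y,
        patch_coords=grid.coords,
        annotated=y is not None,
    )
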