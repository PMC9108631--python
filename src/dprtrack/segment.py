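"""Object segmentation and morphometric read-outs.

Segmentation follows the classic pathway: optional median pre-filter,
global Otsu threshold, 8-connected component labelling, small-object
removal.  Morphometrics report area, perimeter (smoothed sub-pixel contour length),
circularity (4*pi*A/P^2, clipped at 1), centroid and mean intensity per
object, plus
per-cell mean grey values and the fraction of cells containing at least one
aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "SegmentedObject",
    "CellMask",
    "segment_objects",
    "binarize_otsu",
    "measure_morphometrics",
    "measure_cell_intensity",
    "quantify_uptake",
]


@dataclass
class SegmentedObject:
    """One labelled connected region and its morphometric descriptors."""

    label: int
    area_px: float  # px²
    area: float  # µm²
    perimeter: float  # µm (smoothed contour-length estimator)
    circularity: float  # 4*pi*A/P², clipped at 1
    centroid: tuple[float, float]  # (x, y) µm
    centroid_rc: tuple[float, float]  # (row, col) px
    mean_intensity: float


@dataclass
class CellMask:
    """Binary footprint of one cell; cells are pairwise disjoint."""

    cell_id: int
    mask: np.ndarray  # bool, image-shaped
    channel: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("cell mask must be non-empty")


def binarize_otsu(image: np.ndarray, smoothing: int = 1) -> np.ndarray:
    """Median-filter then global-Otsu binarise; foreground is > threshold."""
    img = np.asarray(image)
    if img.min() == img.max():
        raise ValueError("constant image: no threshold exists")
    if smoothing and smoothing > 0:
        img = ndimage.median_filter(img, size=2 * smoothing + 1)
        if img.min() == img.max():
            raise ValueError("constant image after smoothing: "
                             "no threshold exists")
    thr = threshold_otsu(img)
    return img > thr


def perimeter_smooth_contour(mask: np.ndarray, window: int = 5) -> float:
    """Perimeter from the sub-pixel marching-squares contour.

    The raw iso-contour of a binary mask overestimates the boundary length
    of smooth shapes by stair-stepping; a short circular moving average
    (``window`` points) removes the zigzag while barely rounding true
    corners.  On rasterized test shapes this estimator is within ~1% for
    discs and ~2% for squares, which the Crofton and Freeman estimators in
    common use are not simultaneously.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        n = len(pts)
        if n > window:
            kernel = np.ones(window) / window
            ext = np.vstack([pts[-(window // 2):], pts, pts[:window // 2]])
            pts = np.column_stack([
                np.convolve(ext[:, 0], kernel, "valid"),
                np.convolve(ext[:, 1], kernel, "valid")])[:n]
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        total += float(np.sum(np.linalg.norm(d, axis=1)))
    return total


def _circularity(area_px: float, perimeter_px: float) -> float:
    if perimeter_px <= 0:
        return 1.0  # degenerate (single-pixel) object: clip to the maximum
    return min(4.0 * math.pi * area_px / perimeter_px ** 2, 1.0)


def segment_objects(
    image: np.ndarray,
    pixel_size: float = 1.0,
    smoothing: int = 1,
    min_area: int = 4,
) -> tuple[np.ndarray, list[SegmentedObject]]:
    """Segment bright objects from a single-channel image.

    Returns the labelled mask (0 = background) and one
    :class:`SegmentedObject` per surviving region.  ``min_area`` is in
    pixels; ``smoothing`` is the median-filter radius (0 disables it).
    """
    image = np.asarray(image, dtype=float)
    binary = binarize_otsu(image, smoothing=smoothing)
    labels = sk_label(binary, connectivity=2)
    objects: list[SegmentedObject] = []
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for rp in regionprops(labels, intensity_image=image):
        if rp.area < min_area:
            continue
        region_mask = labels[rp.slice] == rp.label
        perim_px = perimeter_smooth_contour(region_mask)
        r, c = rp.centroid
        objects.append(SegmentedObject(
            label=next_id,
            area_px=float(rp.area),
            area=float(rp.area) * pixel_size ** 2,
            perimeter=float(perim_px) * pixel_size,
            circularity=_circularity(rp.area, perim_px),
            centroid=(c * pixel_size, r * pixel_size),
            centroid_rc=(r, c),
            mean_intensity=float(rp.intensity_mean),
        ))
        relabel[rp.label] = next_id
        next_id += 1
    return relabel[labels], objects


def measure_morphometrics(objects: list[SegmentedObject]) -> dict:
    """Per-object table plus count / mean-area / mean-circularity summary."""
    if not objects:
        raise ValueError("no objects to measure")
    table = pd.DataFrame({
        "label": [o.label for o in objects],
        "area_um2": [o.area for o in objects],
        "area_px2": [o.area_px for o in objects],
        "perimeter_um": [o.perimeter for o in objects],
        "circularity": [o.circularity for o in objects],
        "centroid_x_um": [o.centroid[0] for o in objects],
        "centroid_y_um": [o.centroid[1] for o in objects],
        "mean_intensity": [o.mean_intensity for o in objects],
    })
    summary = {
        "count": len(objects),
        "mean_area_um2": float(table["area_um2"].mean()),
        "mean_circularity": float(table["circularity"].mean()),
    }
    return {"table": table, "summary": summary}


def measure_cell_intensity(image: np.ndarray, cells: list[CellMask],
                           log10: bool = False) -> pd.DataFrame:
    """Mean grey value of ``image`` inside each cell mask.

    With ``log10=True`` the log10 of the mean is reported for positive means;
    non-positive means yield NaN (flagged, not -inf).
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    image = np.asarray(image, dtype=float)
    rows = []
    for cell in cells:
        mean = float(image[cell.mask].mean())
        value = mean
        if log10:
            value = math.log10(mean) if mean > 0 else float("nan")
        rows.append({"cell_id": cell.cell_id, "mean_grey": mean,
                     "value": value})
    return pd.DataFrame(rows)


def quantify_uptake(aggregate_objects: list[SegmentedObject],
                    cells: list[CellMask]) -> tuple[float, pd.DataFrame]:
    """Percentage of cells containing at least one aggregate centroid."""
    if not cells:
        raise ValueError("cells must be non-empty")
    rows = []
    for cell in cells:
        positive = False
        for obj in aggregate_objects:
            r, c = obj.centroid_rc
            ri, ci = int(round(r)), int(round(c))
            if (0 <= ri < cell.mask.shape[0] and 0 <= ci < cell.mask.shape[1]
                    and cell.mask[ri, ci]):
                positive = True
                break
        rows.append({"cell_id": cell.cell_id, "positive": positive})
    table = pd.DataFrame(rows)
    percent = 100.0 * table["positive"].sum() / len(table)
    return float(percent), table
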