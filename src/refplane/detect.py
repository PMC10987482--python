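"""Bead detection: percentile thresholding, acceptance filters, tile cropping.

Candidate beads are the 8-connected clusters of the darkest one percent of
pixels in a field-of-view image.  Each cluster (after hole filling -- the
bright bead center punches a hole in the dark mask near focus) must pass,
in order:

1. size: filled area >= 180 px,
2. circularity: (4*pi*area)/perimeter**2 >= 0.9,
3. contrast: std/mean of a sub-image with extra background > 0.1,

Before measuring, each cluster mask is regularized: holes are filled and a
morphological closing followed by an opening (disk footprint, radius 2 px)
removes the single-pixel raggedness that sensor noise imprints on the mask
boundary.  Circularity then uses a polygon perimeter measured on the
simplified marching-squares contour of the mask (tolerance 0.5 px).  A
naive boundary-pixel count overestimates the perimeter of rasterized disks
enough to push genuine beads below the 0.9 threshold, while the
regularized contour keeps digitized disks of radius >= 8 px above 0.9 and
digitized squares well below it.

Coordinates are 0-based with (x, y) = (col, row) and pixel centers at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import closing, disk, opening

EIGHT = np.ones((3, 3), dtype=int)
_FOOTPRINT = disk(2)


def _regularize(mask: np.ndarray) -> np.ndarray:
    """Fill holes and smooth the boundary of a cluster mask."""
    padded = np.pad(mask, 4)
    filled = ndi.binary_fill_holes(padded)
    return opening(closing(filled, _FOOTPRINT), _FOOTPRINT)


@dataclass
class BeadDetection:
    """One candidate bead with its filter outcome."""

    label: int
    area: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1)
    contrast: float = np.nan
    rejected_by: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejected_by is None


@dataclass
class BeadTile:
    """A square crop around one detected bead."""

    pixels: np.ndarray
    nominal_center: tuple[float, float]  # bead center in tile (x, y) coords
    origin: tuple[int, int]  # (x0, y0) of the tile in the source image
    saturated_count: int = 0
    source_key: tuple | None = None


def threshold_percentile(image: np.ndarray, pct: float = 1.0) -> np.ndarray:
    """Label 8-connected clusters of pixels at or below the ``pct`` percentile.

    Returns an integer label image (0 = background).
    """
    image = np.asarray(image)
    if image.size == 0 or image.ndim != 2:
        raise ValueError("image must be a non-empty 2-D array")
    thr = np.percentile(image, pct)
    mask = image <= thr
    labels, _ = ndi.label(mask, structure=EIGHT)
    return labels


def contour_perimeter(mask: np.ndarray, tolerance: float = 0.5) -> float:
    """Perimeter of a binary mask from its simplified marching-squares contour."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    contour = max(contours, key=len)
    poly = measure.approximate_polygon(contour, tolerance)
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def filter_clusters(
    labels: np.ndarray,
    image: np.ndarray,
    min_area: float = 180.0,
    circularity_threshold: float = 0.9,
    contrast_threshold: float = 0.1,
    bead_diameter_px: float = 19.0,
) -> list[BeadDetection]:
    """Apply the size, circularity, and contrast filters to labeled clusters.

    Filters are conjunctive; each rejected cluster records the first filter
    it failed.  Returns one :class:`BeadDetection` per cluster.
    """
    image = np.asarray(image, dtype=float)
    out: list[BeadDetection] = []
    pad = int(round(bead_diameter_px))
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        mask = _regularize(region.image)
        area = float(mask.sum())
        if area == 0:
            continue
        # centroid of the regularized mask, (x, y) in image coordinates;
        # the mask was padded by 4 px on each side during regularization
        rr, cc = np.nonzero(mask)
        centroid = (float(cc.mean() - 4 + c0), float(rr.mean() - 4 + r0))
        perim = contour_perimeter(mask)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        det = BeadDetection(
            label=region.label, area=area, perimeter=perim, circularity=circ,
            centroid=centroid, bbox=(r0, c0, r1, c1),
        )
        if area < min_area:
            det.rejected_by = "size"
        elif circ < circularity_threshold:
            det.rejected_by = "circularity"
        else:
            # sub-image with extra background around the cluster
            rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
            rr1, cc1 = min(r1 + pad, image.shape[0]), min(c1 + pad, image.shape[1])
            sub = image[rr0:rr1, cc0:cc1]
            mean = sub.mean()
            det.contrast = float(sub.std() / mean) if mean > 0 else np.inf
            if det.contrast <= contrast_threshold:
                det.rejected_by = "contrast"
        out.append(det)
    return out


def detect_beads(
    image: np.ndarray,
    pct: float = 1.0,
    presmooth_sigma: float = 1.0,
    **filter_kwargs,
) -> tuple[list[BeadDetection], list[BeadDetection]]:
    """Segment and filter an image; returns (accepted, rejected) detections.

    Segmentation runs on a lightly Gaussian-smoothed copy of the image
    (``presmooth_sigma`` px) so that the percentile threshold cuts a clean
    boundary instead of a noise-ragged one; the filters and all downstream
    intensity measurements use the raw pixels.
    """
    seg = ndi.gaussian_filter(np.asarray(image, dtype=float), presmooth_sigma) \
        if presmooth_sigma > 0 else image
    labels = threshold_percentile(seg, pct)
    detections = filter_clusters(labels, image, **filter_kwargs)
    accepted = [d for d in detections if d.accepted]
    rejected = [d for d in detections if not d.accepted]
    return accepted, rejected


def crop_tile(
    image: np.ndarray,
    centroid: tuple[float, float],
    tile_size: int = 64,
    source_key: tuple | None = None,
) -> BeadTile:
    """Crop a ``tile_size`` square around ``centroid`` (x, y).

    The window is centered on the rounded centroid and shifted inward when
    it would exceed the image boundary, so a bead near the field edge sits
    off-center in its tile.  ``nominal_center`` is the bead centroid in tile
    coordinates (the tile midpoint whenever no shift was needed).
    """
    h, w = image.shape
    if tile_size > h or tile_size > w:
        raise ValueError("tile_size larger than image")
    x, y = centroid
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("centroid outside image")
    half = tile_size // 2
    x0 = int(np.clip(int(round(x)) - half, 0, w - tile_size))
    y0 = int(np.clip(int(round(y)) - half, 0, h - tile_size))
    pixels = np.ascontiguousarray(image[y0 : y0 + tile_size, x0 : x0 + tile_size])
    return BeadTile(
        pixels=pixels,
        nominal_center=(x - x0, y - y0),
        origin=(x0, y0),
        saturated_count=int(np.count_nonzero(pixels == 255)),
        source_key=source_key,
    )


def detections_table(detections: list[BeadDetection]):
    """Detections as a DataFrame (x, y, area, perimeter, circularity, ...)."""
    import pandas as pd

    rows = [
        {
            "x": d.centroid[0], "y": d.centroid[1], "area": d.area,
            "perimeter": d.perimeter, "circularity": d.circularity,
            "contrast": d.contrast, "accepted": d.accepted,
            "reject_reason": d.rejected_by or "",
        }
        for d in detections
    ]
    return pd.DataFrame(rows)
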