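"""Region selection and morphological post-processing of the segmented mask.

The level-set mask may contain several components or a pore fused to
neighbouring structures (guard cells, epidermal texture). This module
picks the component nearest the ROI centre, decides whether it is an
*independent* pore region via its solidity (area / convex-hull area, with
threshold 0.85 — concave, branched regions fall below it), and if not,
disconnects it by erosion / central reselection / dilation, then fills
interior holes and extracts the sub-pixel outer boundary for ellipse
fitting.

Connectivity is 8-connected for foreground and 4-connected for background
throughout (standard duality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.morphology import dilation, disk, erosion

from .errors import (
    DisconnectFailedError,
    EmptySegmentationError,
    InvalidArgumentError,
    TooSmallRegionError,
)

__all__ = [
    "ShapeReport",
    "select_central_region",
    "solidity",
    "disconnect_region",
    "fill_holes",
    "extract_boundary",
]

SOLIDITY_THRESHOLD = 0.85
MIN_BOUNDARY_PX = 9


@dataclass(frozen=True)
class ShapeReport:
    """Solidity-based shape analysis of a single region.

    ``independent`` is True when solidity >= the threshold (0.85 by
    default; a region exactly at the threshold counts as independent).
    """

    area_px: int
    convex_area_px: int
    solidity: float
    independent: bool
    centroid: tuple[float, float]
    touches_border: bool
    threshold: float = SOLIDITY_THRESHOLD


def _as_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidArgumentError("mask must be 2-D")
    return arr.astype(bool)


def select_central_region(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Keep the 8-connected component containing (or nearest to) ``center``.

    If no component covers the centre pixel, the component whose centroid
    is nearest wins; ties go to the larger area, then the smaller label.
    """
    m = _as_mask(mask)
    if not m.any():
        raise EmptySegmentationError("empty mask: nothing to select")
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    r0, c0 = center
    ri, ci = int(round(r0)), int(round(c0))
    if 0 <= ri < m.shape[0] and 0 <= ci < m.shape[1] and labels[ri, ci] > 0:
        return labels == labels[ri, ci]
    centroids = ndimage.center_of_mass(m, labels, index=range(1, n + 1))
    areas = ndimage.sum_labels(m, labels, index=range(1, n + 1))
    best = min(
        range(n),
        key=lambda i: (np.hypot(centroids[i][0] - r0, centroids[i][1] - c0), -areas[i], i),
    )
    return labels == best + 1


def fill_holes(region: np.ndarray) -> np.ndarray:
    """Fill background components not 4-connected to the grid border."""
    return ndimage.binary_fill_holes(_as_mask(region))


def solidity(region: np.ndarray, threshold: float = SOLIDITY_THRESHOLD) -> ShapeReport:
    """Area / convex-hull-area analysis of a single-component region.

    Holes are filled before measuring, since a pore region is conceptually
    solid and an interior hole would spuriously depress solidity. Solidity
    is capped at 1 (discretization can push the raw ratio slightly over).
    """
    m = _as_mask(region)
    if not m.any():
        raise EmptySegmentationError("empty region")
    _, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n != 1:
        raise InvalidArgumentError(f"expected a single component, found {n}")
    filled = fill_holes(m)
    props = skmeasure.regionprops(filled.astype(np.uint8))[0]
    area = int(props.area)
    convex_area = int(props.area_convex)
    sol = min(1.0, area / convex_area)
    touches = bool(
        filled[0, :].any() or filled[-1, :].any() or filled[:, 0].any() or filled[:, -1].any()
    )
    return ShapeReport(
        area_px=area,
        convex_area_px=convex_area,
        solidity=sol,
        independent=sol >= threshold,
        centroid=(float(props.centroid[0]), float(props.centroid[1])),
        touches_border=touches,
        threshold=threshold,
    )


def disconnect_region(
    region: np.ndarray,
    center: tuple[float, float],
    se_radius: int = 2,
    max_rounds: int = 3,
    threshold: float = SOLIDITY_THRESHOLD,
) -> tuple[np.ndarray, ShapeReport, int]:
    """Detach a non-independent pore region from its neighbours.

    An already-independent region is returned unchanged (0 rounds).
    Otherwise, up to ``max_rounds`` times: erode with a disk (radius
    grows by 1 each round), reselect the central component, dilate with
    the same disk and restrict to the original footprint; stop as soon as
    the recomputed solidity clears the threshold. Returns the final
    region, its report, and the number of rounds used — the last round's
    result is returned even if still non-independent.

    Raises :class:`DisconnectFailedError` if erosion removes all
    foreground.
    """
    m = _as_mask(region)
    report = solidity(m, threshold)
    if report.independent:
        return m, report, 0
    footprint = m
    current = m
    rounds = 0
    for round_idx in range(max_rounds):
        se = disk(se_radius + round_idx)
        eroded = erosion(current, se)
        if not eroded.any():
            raise DisconnectFailedError(
                f"erosion with radius {se_radius + round_idx} removed all foreground"
            )
        core = select_central_region(eroded, center)
        current = dilation(core, se) & footprint
        current = select_central_region(current, center)
        report = solidity(current, threshold)
        rounds = round_idx + 1
        if report.independent:
            break
    return current, report, rounds


def extract_boundary(region: np.ndarray) -> np.ndarray:
    """Closed outer contour of a filled region at mask iso-level 0.5.

    Returns an (N, 2) array of sub-pixel (row, col) points without a
    duplicated endpoint, traversed counter-clockwise as displayed (row
    down), starting from the topmost-then-leftmost point. Sub-pixel
    interpolation means ellipse fitting sees a smooth boundary rather
    than a pixel staircase.
    """
    m = _as_mask(region)
    n = int(m.sum())
    if n < MIN_BOUNDARY_PX:
        raise TooSmallRegionError(f"region has {n} px; need >= {MIN_BOUNDARY_PX}")
    padded = np.pad(m.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5, fully_connected="high")
    if not contours:
        raise TooSmallRegionError("no contour found")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # enforce display-CCW orientation: negative shoelace in (x=col, y=row)
    x, y = contour[:, 1], contour[:, 0]
    signed2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if signed2 > 0:
        contour = contour[::-1]
    # start at topmost-then-leftmost point
    start = np.lexsort((contour[:, 1], contour[:, 0]))[0]
    return np.roll(contour, -start, axis=0)
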