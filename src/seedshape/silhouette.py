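"""Turn seed images into measured silhouettes.

The pipeline mirrors standard particle analysis: binarize (automatic
between-class-variance threshold), label connected components, fill
holes, trace each outline at sub-pixel precision with marching squares,
and measure the geometric primitives every shape index needs: area,
perimeter, convex perimeter, moment-matched (fitted) ellipse axes, and
the minimum-area rotated bounding rectangle's length L and width W.

Image coordinates are 0-based with the origin at the top-left corner
and y growing downward; outlines are converted to y-up mathematical
coordinates (``y = (H − 1) − row``) before they are returned, so that
silhouettes and model curves share one chirality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateRegionError, EmptyResultError, SegmentationError
from .geometry import Polygon

DEFAULT_MIN_AREA_PX = 50

#: circular moving-average window on traced contours, as a fraction of
#: the vertex count; suppresses the fixed pixel-scale waviness left by
#: iso-contouring, so perimeter estimates converge with resolution
CONTOUR_SMOOTH_FRAC = 0.01


def _smooth_closed_contour(points: np.ndarray, frac: float = CONTOUR_SMOOTH_FRAC
                           ) -> np.ndarray:
    win = max(3, int(round(len(points) * frac)))
    kernel = np.ones(win) / win
    out = np.empty_like(points)
    for i in range(points.shape[1]):
        wrapped = np.r_[points[-win:, i], points[:, i], points[:win, i]]
        out[:, i] = np.convolve(wrapped, kernel, "same")[win:-win]
    return out


@dataclass(frozen=True)
class BinaryImage:
    """A segmented image: boolean foreground mask plus the physical
    length of one pixel (1 when uncalibrated)."""

    mask: np.ndarray
    pixel_size: float = 1.0


@dataclass(frozen=True)
class FittedEllipse:
    """Moment-matched ellipse of a region.

    ``major_axis`` and ``minor_axis`` are full lengths (diameters), the
    particle-analysis convention; ``orientation`` is the CCW angle of
    the major axis from +x in y-up coordinates, in (−π/2, π/2].
    """

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float


@dataclass(frozen=True)
class Silhouette:
    """One seed's outline and derived scalar measurements.

    All lengths are in physical units (pixels × pixel_size).  ``L`` and
    ``W`` (``bbox_length``/``bbox_width``) come from the minimum-area
    rotated bounding rectangle; ``major_axis``/``minor_axis`` from the
    moment-matched ellipse.
    """

    outline: Polygon
    area: float
    perimeter: float
    convex_perimeter: float
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float
    bbox_length: float
    bbox_width: float
    pixel_size: float = 1.0


def binarize(
    image: np.ndarray,
    threshold: float | None = None,
    dark_foreground: bool = True,
    pixel_size: float = 1.0,
) -> BinaryImage:
    """Segment seeds from the background.

    By default the foreground is the darker-than-threshold region (dark
    seeds on a light background); pass ``dark_foreground=False`` for the
    opposite convention.  Without an explicit ``threshold`` Otsu's
    between-class-variance criterion is used.  Boolean input is taken
    as an already-segmented mask.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise SegmentationError(f"expected a 2-D intensity grid, got ndim={image.ndim}")
    if image.dtype == bool:
        return BinaryImage(image.copy(), pixel_size)
    if threshold is None:
        if np.unique(image).size < 2:
            raise SegmentationError(
                "constant image: cannot choose an automatic threshold"
            )
        threshold = float(threshold_otsu(image))
    # inclusive on the dark side: Otsu returns the lower class bound for
    # a two-valued image, so strict `<` would lose the foreground
    mask = image <= threshold if dark_foreground else image > threshold
    return BinaryImage(mask, pixel_size)


def polygon_second_moments(p: Polygon) -> tuple[float, tuple[float, float], np.ndarray]:
    """Exact area, centroid, and 2x2 central second-moment (covariance)
    matrix of the region enclosed by a simple polygon, by the standard
    Green's-theorem edge sums."""
    x, y = p.vertices[:, 0], p.vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    iyy = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    ixy = (cross * (2 * x * y + x * yn + xn * y + 2 * xn * yn)).sum() / 24.0
    cov = np.array(
        [[ixx / a - cx * cx, ixy / a - cx * cy], [ixy / a - cx * cy, iyy / a - cy * cy]]
    )
    return float(a), (float(cx), float(cy)), cov


def principal_axis_angle(p: Polygon) -> float:
    """CCW angle in (−π/2, π/2] of the region's principal (major) axis
    from +x; 0 for rotationally degenerate regions (e.g. circles)."""
    _, _, cov = polygon_second_moments(p)
    evals, evecs = np.linalg.eigh(cov)
    if math.isclose(evals[0], evals[1], rel_tol=1e-9, abs_tol=1e-15):
        return 0.0
    vx, vy = evecs[:, np.argmax(evals)]
    ang = math.atan2(vy, vx)
    if ang <= -math.pi / 2:
        ang += math.pi
    elif ang > math.pi / 2:
        ang -= math.pi
    return ang


def fit_ellipse(s: Silhouette | Polygon) -> FittedEllipse:
    """Moment-matched ellipse: same area-normalized second-order central
    moments as the silhouette region.  For a solid ellipse the variance
    along an axis is (semi-axis)²/4, hence full axis = 4·sqrt(eigenvalue).
    """
    poly = s.outline if isinstance(s, Silhouette) else s
    _, centroid, cov = polygon_second_moments(poly)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise DegenerateRegionError("region is degenerate (collinear); no ellipse fit")
    major = 4.0 * math.sqrt(float(evals[1]))
    minor = 4.0 * math.sqrt(float(evals[0]))
    vx, vy = evecs[:, 1]
    ang = math.atan2(vy, vx)
    if ang <= -math.pi / 2:
        ang += math.pi
    elif ang > math.pi / 2:
        ang -= math.pi
    return FittedEllipse(centroid, major, minor, ang)


def convex_hull(p: Polygon) -> Polygon:
    """Convex hull of a polygon's vertices; output vertices are a
    subset of the input vertices, CCW."""
    try:
        hull = ConvexHull(p.vertices)
    except QhullError as exc:
        raise DegenerateRegionError(f"convex hull failed: {exc}") from exc
    return Polygon(p.vertices[hull.vertices])


def _min_area_rect_sides(p: Polygon) -> tuple[float, float]:
    rect = p.to_shapely().minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)
    e1 = float(np.hypot(*(coords[1] - coords[0])))
    e2 = float(np.hypot(*(coords[2] - coords[1])))
    return max(e1, e2), min(e1, e2)


def _measure_outline(outline: Polygon, pixel_size: float) -> Silhouette:
    if pixel_size != 1.0:
        outline = Polygon(outline.vertices * pixel_size)
    hull = convex_hull(outline)
    ell = fit_ellipse(outline)
    length, width = _min_area_rect_sides(outline)
    return Silhouette(
        outline=outline,
        area=outline.area,
        perimeter=outline.perimeter,
        convex_perimeter=hull.perimeter,
        centroid=outline.centroid,
        major_axis=ell.major_axis,
        minor_axis=ell.minor_axis,
        orientation=ell.orientation,
        bbox_length=length,
        bbox_width=width,
        pixel_size=pixel_size,
    )


def extract_silhouettes(
    b: BinaryImage, min_area_px: int = DEFAULT_MIN_AREA_PX
) -> list[Silhouette]:
    """One measured silhouette per connected foreground component.

    Holes are filled before measurement (seed silhouettes are solid);
    outlines are traced with marching squares at the 0.5 iso-level for
    sub-pixel precision, and results are sorted left-to-right then
    top-to-bottom by centroid.  Components smaller than ``min_area_px``
    pixels are discarded as specks.
    """
    mask = np.asarray(b.mask, dtype=bool)
    height = mask.shape[0]
    labels = measure.label(mask, connectivity=2)
    out: list[Silhouette] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        filled = binary_fill_holes(region.image)
        # pad so the 0.5 iso-contour closes around border-touching pixels;
        # a light Gaussian blur turns the 0/1 staircase into a sub-pixel
        # iso-line (a raw binary contour overestimates a disk's perimeter
        # by ~5%, inflating rugosity and deflating circularity)
        pad = 4
        padded = gaussian_filter(np.pad(filled, pad).astype(float), sigma=1.0)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        contour = _smooth_closed_contour(contour)
        r0, c0 = region.bbox[0], region.bbox[1]
        rows = contour[:, 0] - pad + r0
        cols = contour[:, 1] - pad + c0
        outline = Polygon(np.column_stack([cols, (height - 1.0) - rows]))
        out.append(_measure_outline(outline, b.pixel_size))
    if not out:
        raise EmptyResultError(
            f"no foreground component of at least {min_area_px} px found"
        )
    out.sort(key=lambda s: (s.centroid[0], -s.centroid[1]))
    return out
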