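"""Ground-truthed synthetic seed images and the pixel-count J oracle.

Real seed scans are not redistributable, so the test suite and the
worked examples run on synthetic seeds: a model curve (usually a
cardioid) whose radius is perturbed by smooth low-frequency Fourier
noise — real seed outlines are smooth, so white vertex noise would be
the wrong roughness model — then posed, rasterized with anti-aliasing
onto a light background, and returned together with the exact
perturbed polygon as ground truth.

:func:`raster_j_oracle` re-evaluates J by brute-force pixel counting
(matplotlib point-in-polygon tests on a grid, no polygon booleans), an
implementation deliberately independent of :func:`seedshape.jindex.
compute_j` so the two can cross-check each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError
from .geometry import InvalidParameterError, Polygon, make_model

#: Fourier harmonics of the radial perturbation (low order keeps the
#: outline smooth and simple)
NOISE_HARMONICS = range(2, 9)

BACKGROUND_LEVEL = 230
FOREGROUND_LEVEL = 25


def rasterize_grid(polygon: Polygon, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Boolean inside-mask of a polygon on a rectangular grid of pixel
    centers, by even-odd scanline parity counting.

    Each edge toggles every pixel whose center lies right of its
    crossing with the pixel row's scanline, under the half-open rule
    ``min(y1, y2) <= y < max(y1, y2)`` so shared vertices are counted
    exactly once.  Runs in O(vertices + boundary crossings), with no
    polygon-clipping library involved — this is the brute-force
    counterpart that cross-checks the exact boolean-geometry route.

    ``xs`` and ``ys`` must be ascending; the result has shape
    ``(len(ys), len(xs))`` with row i at height ``ys[i]``.
    """
    v = polygon.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    ylo, yhi = np.minimum(y1, y2), np.maximum(y1, y2)
    i0 = np.searchsorted(ys, ylo, side="left")
    i1 = np.searchsorted(ys, yhi, side="left")
    counts = i1 - i0
    total = int(counts.sum())
    toggles = np.zeros((len(ys), len(xs) + 1), dtype=np.int32)
    if total:
        edge = np.repeat(np.arange(len(v)), counts)
        start = np.concatenate([[0], np.cumsum(counts)[:-1]])
        rows = i0[edge] + (np.arange(total) - np.repeat(start, counts))
        yv = ys[rows]
        t = (yv - y1[edge]) / (y2[edge] - y1[edge])
        xc = x1[edge] + t * (x2[edge] - x1[edge])
        cols = np.searchsorted(xs, xc, side="left")
        np.add.at(toggles, (rows, cols), 1)
    return (np.cumsum(toggles[:, :-1], axis=1) % 2).astype(bool)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic seed image; identical specs produce
    bit-identical images."""

    kind: str = "cardioid"
    scale: float = 1.0
    model_params: dict = field(default_factory=dict)
    radial_noise_sigma: float = 0.02
    resolution: int = 500
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (dx, dy, rotation)
    rng_seed: int = 0
    n_vertices: int = 720

    def __post_init__(self) -> None:
        if self.resolution < 64:
            raise InvalidParameterError("resolution must be >= 64")
        if self.radial_noise_sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")


def perturb_radially(
    polygon: Polygon, sigma: float, rng: np.random.Generator, max_attempts: int = 10
) -> Polygon:
    """Multiply each vertex radius (about the centroid) by ``1 + δ(θ)``
    where δ is a random low-order Fourier series with std ``sigma``.

    Multiplicative noise leaves cusps in place and cannot drive the
    radius negative.  If the perturbed outline self-intersects the
    harmonics are redrawn, up to ``max_attempts`` times.
    """
    if sigma == 0.0:
        return polygon
    cx, cy = polygon.centroid
    v = polygon.vertices - [cx, cy]
    theta = np.arctan2(v[:, 1], v[:, 0])
    n_harm = len(NOISE_HARMONICS)
    for _ in range(max_attempts):
        # per-harmonic amplitude: total field variance sums to sigma²
        amp = rng.normal(0.0, sigma / math.sqrt(n_harm), size=n_harm)
        phase = rng.uniform(0.0, 2.0 * math.pi, size=n_harm)
        delta = np.zeros(len(theta))
        for a, k, ph in zip(amp, NOISE_HARMONICS, phase):
            delta += a * np.cos(k * theta + ph)
        candidate = Polygon(v * (1.0 + delta)[:, None] + [cx, cy])
        if candidate.is_simple():
            return candidate
    raise InvalidGeometryError(
        f"radial noise sigma={sigma} kept self-intersecting the outline"
    )


def _rasterize(polygon: Polygon, resolution: int, supersample: int = 4
               ) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Anti-aliased 8-bit render: dark seed on light background.

    Returns (image, pixel_size_in_model_units, origin) where ``origin``
    is the model-frame point mapped to the outer corner of pixel (0, 0)
    top-left, with y up within the image flipped to row order.
    """
    xmin, ymin, xmax, ymax = polygon.bounds
    margin = 0.05 * max(xmax - xmin, ymax - ymin)
    xmin, xmax = xmin - margin, xmax + margin
    ymin, ymax = ymin - margin, ymax + margin
    px = max(xmax - xmin, ymax - ymin) / resolution  # long axis = resolution
    width = max(int(math.ceil((xmax - xmin) / px)), 1)
    height = max(int(math.ceil((ymax - ymin) / px)), 1)

    fine = supersample
    xs = xmin + (np.arange(width * fine) + 0.5) * px / fine
    ys = ymax - (np.arange(height * fine) + 0.5) * px / fine  # top row first
    inside = rasterize_grid(polygon, xs, ys[::-1])[::-1]
    # box-filter the supersampled coverage down to the target grid
    cover = inside.reshape(height, fine, width, fine).mean(axis=(1, 3))
    image = BACKGROUND_LEVEL + (FOREGROUND_LEVEL - BACKGROUND_LEVEL) * cover
    return np.round(image).astype(np.uint8), px, (xmin, ymax)


def generate_seed_image(spec: FixtureSpec) -> tuple[np.ndarray, Polygon]:
    """Synthesize one seed image plus its exact ground-truth outline.

    The ground-truth polygon is returned in image coordinates (pixels,
    y up, matching what :func:`seedshape.silhouette.extract_silhouettes`
    reports for the rendered image at pixel_size 1).
    """
    rng = np.random.default_rng(spec.rng_seed)
    model = make_model(spec.kind, spec.scale, spec.n_vertices, **spec.model_params)
    seed_poly = perturb_radially(model.polygon, spec.radial_noise_sigma, rng)
    dx, dy, rot = spec.pose
    if rot:
        seed_poly = seed_poly.rotated(rot)
    seed_poly = seed_poly.translated(dx, dy)
    image, px, (x0, y_top) = _rasterize(seed_poly, spec.resolution)
    height = image.shape[0]
    # model frame -> image frame: pixels, y-up with row 0 at the top
    v = seed_poly.vertices.copy()
    v[:, 0] = (v[:, 0] - x0) / px - 0.5
    v[:, 1] = (height - 1.0) - ((y_top - v[:, 1]) / px - 0.5)
    return image, Polygon(v)


def raster_j_oracle(a: Polygon, b: Polygon, resolution: int = 2000) -> float:
    """Brute-force J by pixel counting on a common grid.

    Both polygons are sampled at pixel centers over their joint
    bounding box (long side = ``resolution`` pixels); shared and
    unshared pixel counts give J = C/(C+D)×100.
    """
    if resolution < 64:
        raise InvalidParameterError("oracle resolution must be >= 64")
    xmin = min(a.bounds[0], b.bounds[0])
    ymin = min(a.bounds[1], b.bounds[1])
    xmax = max(a.bounds[2], b.bounds[2])
    ymax = max(a.bounds[3], b.bounds[3])
    px = max(xmax - xmin, ymax - ymin) / resolution
    nx = max(int(math.ceil((xmax - xmin) / px)), 1)
    ny = max(int(math.ceil((ymax - ymin) / px)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * px
    ys = ymin + (np.arange(ny) + 0.5) * px
    in_a = rasterize_grid(a, xs, ys)
    in_b = rasterize_grid(b, xs, ys)
    shared = int(np.count_nonzero(in_a & in_b))
    unshared = int(np.count_nonzero(in_a ^ in_b))
    if shared + unshared == 0:
        return 100.0
    return 100.0 * shared / (shared + unshared)
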