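"""Geometric model curves used as seed-shape references.

Seed silhouettes are compared against a small family of closed plane
curves: the circle/ellipse, the cardioid ``r = a(1 + cos θ)`` (the
heart-shaped outline typical of Arabidopsis, Lotus, Capparis and Rhus
seeds), cardioids anisotropically stretched by the golden ratio Phi
along one axis, and a Hügelschäffer-type egg curve ("ovoid").  All
curves are sampled into :class:`Polygon` objects, the common currency
of every downstream comparison.

Model coordinates are dimensionless; physical units enter the pipeline
only through image pixel-size metadata.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import shapely.geometry as sgeom


class InvalidParameterError(ValueError):
    """A model-construction parameter violates its contract."""


def golden_ratio() -> float:
    """The golden ratio Phi = (1 + sqrt 5)/2 ≈ 1.618, used as the
    anisotropic stretch factor for elongated cardioid models."""
    return (1.0 + math.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class Polygon:
    """A simple closed planar vertex chain, stored counter-clockwise.

    The last vertex connects implicitly back to the first.  Vertices
    are an ``(n, 2)`` float array in abstract length units.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidParameterError(
                f"polygon needs an (n>=3, 2) vertex array, got shape {v.shape}"
            )
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        d = np.diff(np.vstack([v, v[:1]]), axis=0)
        if np.any(np.all(d == 0.0, axis=1)):
            raise InvalidParameterError("consecutive vertices must be distinct")
        sa = _signed_area(v)
        if sa == 0.0:
            raise InvalidParameterError("polygon has zero signed area")
        if sa < 0.0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    # -- scalar geometry -------------------------------------------------
    @property
    def area(self) -> float:
        """Shoelace area (positive; orientation is CCW by construction)."""
        return _signed_area(self.vertices)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Area centroid (center of mass of the enclosed region)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return float(cx), float(cy)

    def is_simple(self) -> bool:
        return bool(sgeom.LinearRing(self.vertices).is_simple)

    # -- transforms ------------------------------------------------------
    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.vertices + np.array([dx, dy]))

    def rotated(self, angle: float, origin: tuple[float, float] | None = None) -> "Polygon":
        """Rotate CCW by ``angle`` radians about ``origin`` (default centroid)."""
        ox, oy = self.centroid if origin is None else origin
        c, s = math.cos(angle), math.sin(angle)
        v = self.vertices - [ox, oy]
        rot = v @ np.array([[c, s], [-s, c]])
        return Polygon(rot + [ox, oy])

    def scaled(self, factor: float, origin: tuple[float, float] | None = None) -> "Polygon":
        if factor <= 0:
            raise InvalidParameterError("scale factor must be positive")
        ox, oy = self.centroid if origin is None else origin
        return Polygon((self.vertices - [ox, oy]) * factor + [ox, oy])

    def mirrored(self, origin: tuple[float, float] | None = None) -> "Polygon":
        """Reflect across the horizontal line through ``origin``."""
        ox, oy = self.centroid if origin is None else origin
        v = self.vertices.copy()
        v[:, 1] = 2.0 * oy - v[:, 1]
        return Polygon(v)

    # -- interop ---------------------------------------------------------
    def to_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    @classmethod
    def from_shapely(cls, p: sgeom.Polygon) -> "Polygon":
        return cls(np.asarray(p.exterior.coords)[:-1])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        v = self.vertices
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return float((x * np.roll(y, -1) - np.roll(x, -1) * y).sum() / 2.0)


class ModelKind(str, enum.Enum):
    CIRCLE = "circle"
    ELLIPSE = "ellipse"
    CARDIOID = "cardioid"
    CARDIOID_X_PHI = "cardioid_x_phi"
    CARDIOID_Y_PHI = "cardioid_y_phi"
    OVOID = "ovoid"


@dataclass(frozen=True)
class ModelShape:
    """A named parametric reference curve sampled as a polygon."""

    kind: ModelKind
    parameters: Mapping[str, float]
    polygon: Polygon = field(repr=False)


def _check_n(n_vertices: int, minimum: int = 16) -> int:
    n = int(n_vertices)
    if n < minimum:
        raise InvalidParameterError(f"n_vertices must be >= {minimum}, got {n_vertices}")
    return n


def make_cardioid(scale: float, n_vertices: int = 720) -> ModelShape:
    """Sample the cardioid ``r(θ) = scale·(1 + cos θ)``.

    The curve's long axis lies along x, with the rounded lobe at
    ``x = 2·scale`` and the cusp at the origin (θ = π).  The cusp is
    always included as a vertex: for odd ``n_vertices`` the grid point
    nearest π is snapped onto it.
    """
    if scale <= 0:
        raise InvalidParameterError("scale must be positive")
    n = _check_n(n_vertices)
    theta = 2.0 * math.pi * np.arange(n) / n
    if n % 2:  # grid misses θ=π exactly; snap the nearest sample to the cusp
        theta[np.argmin(np.abs(theta - math.pi))] = math.pi
    r = scale * (1.0 + np.cos(theta))
    poly = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return ModelShape(ModelKind.CARDIOID, {"scale": float(scale)}, poly)


def make_ellipse(semi_major: float, semi_minor: float, n_vertices: int = 720) -> ModelShape:
    """Sample ``(a·cos θ, b·sin θ)``; a circle when a == b."""
    if not (semi_major >= semi_minor > 0):
        raise InvalidParameterError(
            f"need semi_major >= semi_minor > 0, got a={semi_major}, b={semi_minor}"
        )
    n = _check_n(n_vertices)
    theta = 2.0 * math.pi * np.arange(n) / n
    poly = Polygon(
        np.column_stack([semi_major * np.cos(theta), semi_minor * np.sin(theta)])
    )
    kind = ModelKind.CIRCLE if semi_major == semi_minor else ModelKind.ELLIPSE
    return ModelShape(
        kind, {"semi_major": float(semi_major), "semi_minor": float(semi_minor)}, poly
    )


#: default semi-minor/semi-major ratio of the ovoid's underlying ellipse
OVOID_ASPECT = 0.75


def ovoid_half_width(x: np.ndarray | float, a: float, b: float, w: float):
    """Half-width y(x) >= 0 of the Hügelschäffer egg curve.

    ``y² = b²(a² − x²) / (a² − 2wx + w²)`` for x in [−a, a]; w = 0
    degenerates exactly to the ellipse with semi-axes (a, b).  The
    denominator equals ``(a−w)² + 2w(a−x)`` and is positive for
    0 <= w < a, so the curve is well defined and simple over the whole
    asymmetry range; the blunt (wider) end points toward +x.
    """
    x = np.asarray(x, dtype=float)
    num = b * b * (a * a - x * x)
    den = a * a - 2.0 * w * x + w * w
    return np.sqrt(np.clip(num, 0.0, None) / den)


def make_ovoid(
    scale: float,
    asymmetry: float,
    n_vertices: int = 720,
    aspect: float = OVOID_ASPECT,
) -> ModelShape:
    """Sample a Hügelschäffer-type egg curve, blunt end toward +x.

    ``scale`` is the semi-length a of the long (symmetry) axis;
    ``aspect`` fixes the cross semi-axis b = aspect·a; ``asymmetry`` in
    [0, 1) shifts area toward one end (w = asymmetry·a), with 0 giving
    vertex-for-vertex the ellipse of :func:`make_ellipse`.
    """
    if scale <= 0:
        raise InvalidParameterError("scale must be positive")
    if not (0.0 <= asymmetry < 1.0):
        raise InvalidParameterError(f"asymmetry must be in [0, 1), got {asymmetry}")
    if not (0.0 < aspect <= 1.0):
        raise InvalidParameterError("aspect must be in (0, 1]")
    n = _check_n(n_vertices)
    a, b, w = float(scale), float(aspect * scale), float(asymmetry * scale)
    theta = 2.0 * math.pi * np.arange(n) / n
    x = a * np.cos(theta)
    y = ovoid_half_width(x, a, b, w) * np.sign(np.sin(theta))
    y[(theta == 0.0) | (theta == math.pi)] = 0.0
    poly = Polygon(np.column_stack([x, y]))
    return ModelShape(
        ModelKind.OVOID,
        {"scale": a, "asymmetry": float(asymmetry), "aspect": float(aspect)},
        poly,
    )


def elongate(p: Polygon, axis: str, factor: float) -> Polygon:
    """Stretch one coordinate of every vertex by ``factor`` about the
    polygon's area centroid.  Orientation is preserved (factor > 0)."""
    if factor <= 0:
        raise InvalidParameterError("elongation factor must be positive")
    if axis not in ("x", "y"):
        raise InvalidParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    cx, cy = p.centroid
    v = p.vertices.copy()
    if axis == "x":
        v[:, 0] = cx + (v[:, 0] - cx) * factor
    else:
        v[:, 1] = cy + (v[:, 1] - cy) * factor
    return Polygon(v)


def make_model(kind: ModelKind | str, scale: float = 1.0, n_vertices: int = 720,
               **params: float) -> ModelShape:
    """Build any named model by kind; the one-stop factory used by the
    CLI and the fixture generator.

    ``ellipse`` takes ``aspect`` (semi-minor/semi-major, default 1/Phi);
    ``ovoid`` takes ``asymmetry`` (default 0.3) and ``aspect``.
    """
    kind = ModelKind(kind)
    if kind is ModelKind.CIRCLE:
        return make_ellipse(scale, scale, n_vertices)
    if kind is ModelKind.ELLIPSE:
        aspect = float(params.get("aspect", 1.0 / golden_ratio()))
        return make_ellipse(scale, scale * aspect, n_vertices)
    if kind is ModelKind.CARDIOID:
        return make_cardioid(scale, n_vertices)
    if kind in (ModelKind.CARDIOID_X_PHI, ModelKind.CARDIOID_Y_PHI):
        base = make_cardioid(scale, n_vertices)
        axis = "x" if kind is ModelKind.CARDIOID_X_PHI else "y"
        poly = elongate(base.polygon, axis, golden_ratio())
        return ModelShape(kind, {"scale": float(scale)}, poly)
    if kind is ModelKind.OVOID:
        return make_ovoid(
            scale,
            float(params.get("asymmetry", 0.3)),
            n_vertices,
            float(params.get("aspect", OVOID_ASPECT)),
        )
    raise InvalidParameterError(f"unknown model kind {kind!r}")
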