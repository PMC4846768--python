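"""Similarity of a seed silhouette to a geometric model: the J index.

Once a model curve is superimposed on a seed outline, J compares the
shared area C with the total unshared area D:

    J = C / (C + D) × 100

J ranges from 0 (disjoint figures) to 100 (coincident figures, D = 0)
and is algebraically 100× the intersection-over-union (Jaccard index)
of the two regions, since C + D is the area of their union.

Alignment is area-normalized — the model is rescaled to the seed's
exact area before comparison — so J measures shape only, never size.
The pose search matches centroids and principal axes, resolves the
180° and mirror ambiguities by evaluating J for the four candidate
poses, and can optionally polish rotation and translation with a
derivative-free local search.

Regional J applies the same formula to the pieces of C and D clipped
to half-planes (left/right of the seed) or quadrants (Q1–Q4), and a
morphotype classifier labels seeds A/B/C/BC from the left/right values
against configurable thresholds (defaults 92 and 80, the cutoffs used
for cardioid-like sumac seeds).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import shapely.geometry as sgeom
from scipy.optimize import minimize

from .errors import DegenerateRegionError, InvalidGeometryError, InvalidMeasurementError
from .geometry import ModelKind, ModelShape, Polygon
from .silhouette import Silhouette, principal_axis_angle

#: default morphotype cutoffs on regional J (percent)
LEFT_THRESHOLD = 92.0
RIGHT_THRESHOLD = 80.0


@dataclass(frozen=True)
class ModelFit:
    """Rigid-plus-uniform-scale transform taking a model polygon onto a
    seed: mirror (optional) about the model's horizontal axis, rotate
    by ``rotation``, scale by ``scale``, then place the model centroid
    at ``translation``."""

    translation: tuple[float, float]
    rotation: float
    scale: float
    flipped: bool = False


@dataclass(frozen=True)
class OverlapResult:
    """Shared area C, unshared area D, the J value they define, and the
    fit that produced the superposition (None for pre-aligned input)."""

    area_C: float
    area_D: float
    j: float
    fit: ModelFit | None = None


@dataclass(frozen=True)
class RegionalJ:
    """Per-region J values keyed by region id ('left'/'right' or
    'Q1'..'Q4'), with the per-region C and D areas kept for auditing."""

    values: Mapping[str, float]
    areas_C: Mapping[str, float]
    areas_D: Mapping[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


class Morphotype(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    BC = "BC"


def _as_polygon(obj: Silhouette | ModelShape | Polygon) -> Polygon:
    if isinstance(obj, Silhouette):
        return obj.outline
    if isinstance(obj, ModelShape):
        return obj.polygon
    return obj


def _valid_shapely(p: Polygon, name: str) -> sgeom.Polygon:
    sp = p.to_shapely()
    if not sp.is_valid:
        raise InvalidGeometryError(f"{name} polygon is self-intersecting or invalid")
    return sp


def apply_fit(model: Polygon, fit: ModelFit) -> Polygon:
    """Apply a :class:`ModelFit` to a model polygon (in model frame)."""
    cx, cy = model.centroid
    v = model.vertices - [cx, cy]
    if fit.flipped:
        v = v * [1.0, -1.0]
    c, s = math.cos(fit.rotation), math.sin(fit.rotation)
    v = v @ np.array([[c, s], [-s, c]])
    return Polygon(v * fit.scale + list(fit.translation))


def compute_j(seed: Polygon, model: Polygon) -> OverlapResult:
    """J of two simple polygons already in a common frame.

    C is the area of the intersection and D the area of the symmetric
    difference, both by exact polygon boolean operations.  The Jaccard
    identity C + D = area(union) is asserted numerically on each call.
    """
    sp_seed = _valid_shapely(seed, "seed")
    sp_model = _valid_shapely(model, "model")
    # boolean ops are not bit-identical under operand swap; canonicalize
    # the order so J is exactly symmetric in its arguments
    first, second = sorted((sp_seed, sp_model), key=lambda g: g.wkb)
    area_c = first.intersection(second).area
    area_d = first.symmetric_difference(second).area
    union = first.union(second).area
    if not math.isclose(area_c + area_d, union, rel_tol=1e-9, abs_tol=1e-12):
        raise InvalidGeometryError(
            f"boolean-operation inconsistency: C+D={area_c + area_d} != union={union}"
        )
    j = 100.0 * area_c / (area_c + area_d) if area_c + area_d > 0 else 100.0
    return OverlapResult(area_C=float(area_c), area_D=float(area_d), j=float(j))


def align_model(
    s: Silhouette | Polygon,
    m: ModelShape | Polygon,
    refine: bool = True,
) -> ModelFit:
    """Superimpose a model on a seed for a shape-only comparison.

    The model is scaled so the two areas are equal, centroids are
    matched, and principal axes aligned; of the four candidate poses
    (axis angle θ and θ+π, each mirrored or not) the one maximizing J
    is kept.  With ``refine`` a Nelder–Mead search over (rotation, dx,
    dy) polishes the pose; scale stays fixed by the equal-area
    constraint throughout.
    """
    seed = _as_polygon(s)
    model = _as_polygon(m)
    if seed.area <= 0 or model.area <= 0:
        raise DegenerateRegionError("both figures need positive area")
    scale = math.sqrt(seed.area / model.area)
    tx, ty = seed.centroid
    phi_seed = principal_axis_angle(seed)
    phi_model = principal_axis_angle(model)

    best: tuple[float, ModelFit] | None = None
    for flipped in (False, True):
        # mirroring about the model's horizontal axis maps its principal
        # axis angle to its negative
        base = phi_seed - (-phi_model if flipped else phi_model)
        for extra in (0.0, math.pi):
            fit = ModelFit((tx, ty), base + extra, scale, flipped)
            j = compute_j(seed, apply_fit(model, fit)).j
            if best is None or j > best[0]:
                best = (j, fit)
    assert best is not None
    fit = best[1]

    if refine:
        span = math.sqrt(seed.area)

        def neg_j(params: np.ndarray) -> float:
            cand = ModelFit(
                (fit.translation[0] + params[1], fit.translation[1] + params[2]),
                fit.rotation + params[0],
                scale,
                fit.flipped,
            )
            return -compute_j(seed, apply_fit(model, cand)).j

        res = minimize(
            neg_j,
            x0=np.zeros(3),
            method="Nelder-Mead",
            options={
                "initial_simplex": np.vstack(
                    [np.zeros(3), np.diag([0.05, 0.02 * span, 0.02 * span])]
                ),
                "xatol": 1e-4,
                "fatol": 1e-4,
                "maxiter": 200,
            },
        )
        if -res.fun > best[0]:
            fit = ModelFit(
                (fit.translation[0] + res.x[1], fit.translation[1] + res.x[2]),
                fit.rotation + res.x[0],
                scale,
                fit.flipped,
            )
    return fit


def _region_boxes(
    scheme: str, span: float
) -> dict[str, sgeom.Polygon]:
    """Axis-aligned half-plane / quadrant boxes in the (u, v) frame."""
    big = 4.0 * span
    if scheme == "halves_lr":
        return {
            "left": sgeom.box(-big, -big, 0.0, big),
            "right": sgeom.box(0.0, -big, big, big),
        }
    if scheme == "quadrants":
        return {
            "Q1": sgeom.box(0.0, 0.0, big, big),
            "Q2": sgeom.box(-big, 0.0, 0.0, big),
            "Q3": sgeom.box(-big, -big, 0.0, 0.0),
            "Q4": sgeom.box(0.0, -big, big, 0.0),
        }
    raise InvalidMeasurementError(f"unknown region scheme {scheme!r}")


def regional_j(
    seed: Polygon,
    model: Polygon,
    scheme: str = "halves_lr",
    origin: tuple[float, float] | None = None,
    axis_angle: float | None = None,
) -> RegionalJ:
    """J evaluated region by region in an aligned frame.

    The partition axes pass through ``origin`` (default: seed centroid)
    parallel and perpendicular to ``axis_angle`` (default: the seed's
    principal axis).  'right' is the half-plane toward +axis_angle; Q1
    is the upper-right quadrant, numbered counter-clockwise.  The
    region-wise C and D sum exactly to the global values, so the
    area-weighted recombination of regional J reproduces global J.
    """
    sp_seed = _valid_shapely(seed, "seed")
    sp_model = _valid_shapely(model, "model")
    if origin is None:
        origin = seed.centroid
    if axis_angle is None:
        axis_angle = principal_axis_angle(seed)

    # move both figures into the (u, v) partition frame
    c, s = math.cos(-axis_angle), math.sin(-axis_angle)
    rot = np.array([[c, s], [-s, c]])

    def to_frame(sp: sgeom.Polygon) -> sgeom.Polygon:
        coords = (np.asarray(sp.exterior.coords) - list(origin)) @ rot
        return sgeom.Polygon(coords)

    fs, fm = to_frame(sp_seed), to_frame(sp_model)
    inter = fs.intersection(fm)
    diff = fs.symmetric_difference(fm)
    span = max(
        abs(b) for geom in (fs, fm) for b in geom.bounds
    )
    values: dict[str, float] = {}
    areas_c: dict[str, float] = {}
    areas_d: dict[str, float] = {}
    for name, box in _region_boxes(scheme, span).items():
        if fs.intersection(box).area <= 0:
            raise DegenerateRegionError(f"no seed area in region {name!r}")
        c_r = inter.intersection(box).area
        d_r = diff.intersection(box).area
        areas_c[name] = float(c_r)
        areas_d[name] = float(d_r)
        values[name] = 100.0 * c_r / (c_r + d_r) if c_r + d_r > 0 else 100.0
    return RegionalJ(values, areas_c, areas_d)


def classify_morphotype(
    left_j: float,
    right_j: float,
    left_threshold: float = LEFT_THRESHOLD,
    right_threshold: float = RIGHT_THRESHOLD,
) -> Morphotype:
    """Label a seed from its left/right similarity to the cardioid.

    A: left >= 92 and right >= 80; B: left < 92, right >= 80;
    C: left >= 92, right < 80; BC: both below.  Threshold values
    themselves count as "above" so every (left, right) pair in
    [0, 100]² gets exactly one of the four labels.
    """
    for name, v in (("left_j", left_j), ("right_j", right_j)):
        if not (0.0 <= v <= 100.0):
            raise InvalidMeasurementError(f"{name}={v} outside [0, 100]")
    left_high = left_j >= left_threshold
    right_high = right_j >= right_threshold
    if left_high and right_high:
        return Morphotype.A
    if right_high:
        return Morphotype.B
    if left_high:
        return Morphotype.C
    return Morphotype.BC


@dataclass(frozen=True)
class ComparisonResult:
    """Full model-comparison record for one seed: global J, left/right
    and quadrant J, morphotype, and the fit used."""

    overlap: OverlapResult
    halves: RegionalJ
    quadrants: RegionalJ
    morphotype: Morphotype
    model_kind: ModelKind


def compare_to_model(
    s: Silhouette | Polygon,
    model: ModelShape,
    refine: bool = True,
    left_threshold: float = LEFT_THRESHOLD,
    right_threshold: float = RIGHT_THRESHOLD,
) -> ComparisonResult:
    """Align, compute global/regional J, and classify in one call.

    The left/right convention follows the model's reference
    orientation: for cardioid models the cusp side is 'right' (the
    cusp sits on the model's −x side, so 'right' points along the
    aligned model's −x direction); for other models 'right' is the
    aligned +x direction (blunt end of the ovoid).
    """
    seed = _as_polygon(s)
    fit = align_model(seed, model, refine=refine)
    placed = apply_fit(model.polygon, fit)
    overlap = compute_j(seed, placed)
    overlap = OverlapResult(overlap.area_C, overlap.area_D, overlap.j, fit)
    cardioid_like = model.kind in (
        ModelKind.CARDIOID,
        ModelKind.CARDIOID_X_PHI,
        ModelKind.CARDIOID_Y_PHI,
    )
    right_angle = fit.rotation + (math.pi if cardioid_like else 0.0)
    origin = seed.centroid
    halves = regional_j(seed, placed, "halves_lr", origin, right_angle)
    quadrants = regional_j(seed, placed, "quadrants", origin, right_angle)
    morpho = classify_morphotype(
        halves["left"], halves["right"], left_threshold, right_threshold
    )
    return ComparisonResult(overlap, halves, quadrants, morpho, model.kind)
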