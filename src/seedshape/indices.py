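"""Classical scalar shape descriptors of particle analysis.

Six caliper- and contour-based indices, each a dimensionless ratio and
therefore scale-invariant:

========================  =====================================
eccentricity index (EI)   L / W
aspect ratio (AR)         major axis / minor axis (fitted ellipse)
flatness index (FI)       (L + W) / (2 H)     — needs a 3-D height
circularity (I)           4π · area / perimeter²
roundness (R)             4 · area / (π · major axis²)
rugosity                  perimeter / convex perimeter
========================  =====================================

Circularity is 1 for a circle and drops with boundary irregularity;
roundness is insensitive to small perimeter protuberances (for an
ellipse it equals minor/major); rugosity is 1 for convex outlines.
The flatness index needs the seed height H, which a 2-D image cannot
provide: it is only computed from explicit user-supplied L, W, H.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import InvalidMeasurementError
from .silhouette import FittedEllipse, Silhouette

logger = logging.getLogger(__name__)

#: discretization slack: raster noise may push a ratio this far past its
#: theoretical bound before it is treated as an upstream bug.
DISCRETIZATION_EPS = 1e-3


def eccentricity_index(L: float, W: float) -> float:
    """Length/width ratio, the simplest elongation descriptor.  Swaps
    the inputs (with a warning) if given W > L."""
    if W <= 0 or L <= 0:
        raise InvalidMeasurementError(f"need L, W > 0, got L={L}, W={W}")
    if W > L:
        logger.warning("eccentricity_index: W=%g > L=%g, swapping", W, L)
        L, W = W, L
    return L / W


def aspect_ratio(e: FittedEllipse) -> float:
    """Major/minor axis ratio of the particle's fitted ellipse."""
    if e.minor_axis <= 0:
        raise InvalidMeasurementError(f"degenerate ellipse: minor={e.minor_axis}")
    return e.major_axis / e.minor_axis


def flatness_index(L: float, W: float, H: float) -> float:
    """(L + W)/(2H): 1 for spheres, above 2 for spindly seeds."""
    if min(L, W, H) <= 0:
        raise InvalidMeasurementError(f"need L, W, H > 0, got {L}, {W}, {H}")
    return (L + W) / (2.0 * H)


def _clamp(value: float, upper: float, what: str) -> float:
    if value > upper + DISCRETIZATION_EPS:
        raise InvalidMeasurementError(
            f"{what}={value} exceeds {upper} beyond discretization slack"
        )
    if value > upper:
        logger.warning("%s=%g clamped to %g (raster discretization)", what, value, upper)
        return upper
    return value


def circularity(area: float, perimeter: float) -> float:
    """Form factor 4π·area/perimeter²; 1 for circles, lower for figures
    with boundary protuberances.  Values within 1e-3 above 1 (raster
    noise) are clamped with a warning; larger excesses are rejected."""
    if area <= 0 or perimeter <= 0:
        raise InvalidMeasurementError(
            f"need area, perimeter > 0, got {area}, {perimeter}"
        )
    return _clamp(4.0 * math.pi * area / perimeter**2, 1.0, "circularity")


def roundness(area: float, major_axis: float) -> float:
    """4·area/(π·major²); like circularity but insensitive to perimeter
    irregularities.  Equals minor/major for an exact ellipse."""
    if area <= 0 or major_axis <= 0:
        raise InvalidMeasurementError(
            f"need area, major_axis > 0, got {area}, {major_axis}"
        )
    return _clamp(4.0 * area / (math.pi * major_axis**2), 1.0, "roundness")


def rugosity(perimeter: float, convex_perimeter: float) -> float:
    """Ps/Pc, perimeter over convex-hull perimeter; 1 for convex
    outlines, larger for wrinkled ones.  Ps < Pc (beyond slack) signals
    inconsistent upstream geometry and is rejected."""
    if perimeter <= 0 or convex_perimeter <= 0:
        raise InvalidMeasurementError(
            f"need perimeters > 0, got Ps={perimeter}, Pc={convex_perimeter}"
        )
    value = perimeter / convex_perimeter
    if value < 1.0 - DISCRETIZATION_EPS:
        raise InvalidMeasurementError(
            f"rugosity={value} < 1: perimeter smaller than convex perimeter"
        )
    return max(value, 1.0)


@dataclass(frozen=True)
class IndexSet:
    """The full descriptor row for one silhouette.  ``flatness`` is None
    unless an explicit height H was supplied."""

    eccentricity: float
    aspect_ratio: float
    circularity: float
    roundness: float
    rugosity: float
    flatness: float | None = None


def compute_indices(s: Silhouette, height: float | None = None) -> IndexSet:
    """All indices measurable from one silhouette (plus FI if the seed
    height ``height`` is supplied in the same physical units)."""
    ell = FittedEllipse(s.centroid, s.major_axis, s.minor_axis, s.orientation)
    return IndexSet(
        eccentricity=eccentricity_index(s.bbox_length, s.bbox_width),
        aspect_ratio=aspect_ratio(ell),
        circularity=circularity(s.area, s.perimeter),
        roundness=roundness(s.area, s.major_axis),
        rugosity=rugosity(s.perimeter, s.convex_perimeter),
        flatness=(
            None if height is None else flatness_index(s.bbox_length, s.bbox_width, height)
        ),
    )
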