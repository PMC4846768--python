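"""Batch measurement runs: image reading, CSV schema, configuration.

One :class:`MeasurementRecord` per extracted silhouette aggregates the
scalar measurements, the six shape indices, and (when a model is
selected) the global, left/right and quadrant J values, morphotype and
fit parameters.  Output is a UTF-8 CSV with '.' decimal separator and
values formatted at 6 significant digits, in deterministic order
(lexicographic file order, then silhouette order within an image).
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from . import __version__
from .errors import EmptyResultError, SeedShapeError
from .geometry import make_model
from .indices import compute_indices
from .jindex import LEFT_THRESHOLD, RIGHT_THRESHOLD, compare_to_model
from .silhouette import DEFAULT_MIN_AREA_PX, Silhouette, binarize, extract_silhouettes

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

#: CSV column order
RECORD_COLUMNS = [
    "file", "seed_id", "pixel_size",
    "area", "perimeter", "convex_perimeter",
    "L", "W", "major_axis", "minor_axis",
    "EI", "AR", "circularity", "roundness", "rugosity",
    "J", "J_left", "J_right", "Q1", "Q2", "Q3", "Q4",
    "morphotype", "model_kind",
    "fit_dx", "fit_dy", "fit_rotation", "fit_scale", "fit_flipped",
]


@dataclass(frozen=True)
class MeasurementRecord:
    file: str
    seed_id: int
    pixel_size: float
    area: float
    perimeter: float
    convex_perimeter: float
    L: float
    W: float
    major_axis: float
    minor_axis: float
    EI: float
    AR: float
    circularity: float
    roundness: float
    rugosity: float
    J: float | None = None
    J_left: float | None = None
    J_right: float | None = None
    Q1: float | None = None
    Q2: float | None = None
    Q3: float | None = None
    Q4: float | None = None
    morphotype: str | None = None
    model_kind: str | None = None
    fit_dx: float | None = None
    fit_dy: float | None = None
    fit_rotation: float | None = None
    fit_scale: float | None = None
    fit_flipped: bool | None = None


@dataclass
class MeasureConfig:
    """Everything one batch run needs; mirrored by CLI flags (flags win)."""

    inputs: list[str] = field(default_factory=list)
    model: str | None = None
    n_vertices: int = 720
    model_params: dict = field(default_factory=dict)
    threshold: float | None = None
    dark_foreground: bool = True
    min_area: int = DEFAULT_MIN_AREA_PX
    pixel_size: float = 1.0
    refine: bool = True
    left_threshold: float = LEFT_THRESHOLD
    right_threshold: float = RIGHT_THRESHOLD
    out: str | None = None


def load_config(path: str | Path) -> MeasureConfig:
    """Read a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(MeasureConfig)}
    unknown = set(data) - known
    if unknown:
        raise SeedShapeError(f"unknown config keys: {sorted(unknown)}")
    return MeasureConfig(**data)


def read_image(path: str | Path) -> np.ndarray:
    """Load PNG/TIFF as a 2-D intensity array; RGB is converted by
    luminance, 16-bit grayscale is kept at full depth."""
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "F", "L", "1"):
            arr = np.asarray(img)
        else:
            arr = np.asarray(img.convert("L"))
    if arr.ndim != 2:
        arr = arr[..., 0]
    return arr


def measure_silhouette(
    s: Silhouette, cfg: MeasureConfig, file: str, seed_id: int
) -> MeasurementRecord:
    """Indices (and J, if a model is configured) for one silhouette."""
    idx = compute_indices(s)
    record = dict(
        file=file,
        seed_id=seed_id,
        pixel_size=s.pixel_size,
        area=s.area,
        perimeter=s.perimeter,
        convex_perimeter=s.convex_perimeter,
        L=s.bbox_length,
        W=s.bbox_width,
        major_axis=s.major_axis,
        minor_axis=s.minor_axis,
        EI=idx.eccentricity,
        AR=idx.aspect_ratio,
        circularity=idx.circularity,
        roundness=idx.roundness,
        rugosity=idx.rugosity,
    )
    if cfg.model is not None:
        model = make_model(cfg.model, 1.0, cfg.n_vertices, **cfg.model_params)
        cmp_res = compare_to_model(
            s, model, cfg.refine, cfg.left_threshold, cfg.right_threshold
        )
        fit = cmp_res.overlap.fit
        record.update(
            J=cmp_res.overlap.j,
            J_left=cmp_res.halves["left"],
            J_right=cmp_res.halves["right"],
            Q1=cmp_res.quadrants["Q1"],
            Q2=cmp_res.quadrants["Q2"],
            Q3=cmp_res.quadrants["Q3"],
            Q4=cmp_res.quadrants["Q4"],
            morphotype=cmp_res.morphotype.value,
            model_kind=cmp_res.model_kind.value,
            fit_dx=fit.translation[0],
            fit_dy=fit.translation[1],
            fit_rotation=fit.rotation,
            fit_scale=fit.scale,
            fit_flipped=fit.flipped,
        )
    return MeasurementRecord(**record)


def measure_image(
    image: np.ndarray, cfg: MeasureConfig, file: str = "<array>"
) -> list[MeasurementRecord]:
    b = binarize(image, cfg.threshold, cfg.dark_foreground, cfg.pixel_size)
    silhouettes = extract_silhouettes(b, cfg.min_area)
    return [
        measure_silhouette(s, cfg, file, i) for i, s in enumerate(silhouettes)
    ]


def records_to_dataframe(records: list[MeasurementRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.reindex(columns=RECORD_COLUMNS)


def write_csv(records: list[MeasurementRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def run_measure(cfg: MeasureConfig) -> list[MeasurementRecord]:
    """Measure every readable input image, in lexicographic file order.

    Unreadable or seed-free images are skipped with a logged warning;
    an :class:`EmptyResultError` is raised only if no image at all
    yields a seed.  Writes ``cfg.out`` (CSV) when set.
    """
    logger.info(
        "seedshape %s: model=%s threshold=%s min_area=%d pixel_size=%g refine=%s",
        __version__, cfg.model, cfg.threshold, cfg.min_area, cfg.pixel_size,
        cfg.refine,
    )
    records: list[MeasurementRecord] = []
    for path in sorted(str(p) for p in cfg.inputs):
        try:
            image = read_image(path)
        except (OSError, UnidentifiedImageError) as exc:
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        try:
            rows = measure_image(image, cfg, file=path)
        except SeedShapeError as exc:
            logger.warning("no measurable seeds in %s: %s", path, exc)
            continue
        logger.info("%s: %d seed(s)", path, len(rows))
        records.extend(rows)
    if not records:
        raise EmptyResultError("no seeds found in any input image")
    if cfg.out:
        write_csv(records, cfg.out)
        logger.info("wrote %d records to %s", len(records), cfg.out)
    return records
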