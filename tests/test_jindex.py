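"""J-index computation, alignment, regional values, morphotypes."""

import itertools
import math

import numpy as np
import pytest

from seedshape.errors import (
    DegenerateRegionError,
    InvalidGeometryError,
    InvalidMeasurementError,
)
from seedshape.geometry import Polygon, make_cardioid, make_ellipse, make_model
from seedshape.jindex import (
    Morphotype,
    align_model,
    apply_fit,
    classify_morphotype,
    compare_to_model,
    compute_j,
    regional_j,
)


class TestComputeJ:
    def test_identical_polygons_give_100(self, cardioid_polygon):
        res = compute_j(cardioid_polygon, cardioid_polygon)
        assert res.j == 100.0
        assert res.area_D == 0.0

    def test_disjoint_polygons_give_0(self, unit_square):
        far = unit_square.translated(10.0, 0.0)
        assert compute_j(unit_square, far).j == 0.0

    def test_half_overlapping_unit_squares(self, unit_square):
        shifted = unit_square.translated(0.5, 0.0)
        res = compute_j(unit_square, shifted)
        assert res.area_C == pytest.approx(0.5, abs=1e-12)
        assert res.area_D == pytest.approx(1.0, abs=1e-12)
        assert res.j == pytest.approx(100 / 3, abs=1e-9)

    def test_symmetry(self, unit_square, cardioid_polygon):
        a = compute_j(unit_square, cardioid_polygon)
        b = compute_j(cardioid_polygon, unit_square)
        assert a.j == b.j

    def test_rigid_invariance(self, unit_square, cardioid_polygon):
        base = compute_j(unit_square, cardioid_polygon).j
        for ang, dx, dy in [(0.3, 1, -2), (2.0, -5, 0.1), (-1.2, 0, 7)]:
            a = unit_square.rotated(ang, origin=(0, 0)).translated(dx, dy)
            b = cardioid_polygon.rotated(ang, origin=(0, 0)).translated(dx, dy)
            assert compute_j(a, b).j == pytest.approx(base, abs=1e-9)

    def test_clipping_a_protrusion_decreases_j(self, cardioid_polygon):
        model = cardioid_polygon
        seed_small = model.scaled(0.9)
        j_full = compute_j(model, model).j
        j_small = compute_j(seed_small, model).j
        j_smaller = compute_j(model.scaled(0.8), model).j
        assert j_full > j_small > j_smaller

    def test_self_intersecting_input_rejected(self):
        bowtie = Polygon.__new__(Polygon)
        object.__setattr__(
            bowtie,
            "vertices",
            np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float),
        )
        square = Polygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        with pytest.raises(InvalidGeometryError):
            compute_j(bowtie, square)

    def test_jaccard_identity(self, unit_square):
        shifted = unit_square.translated(0.25, 0.4)
        res = compute_j(unit_square, shifted)
        union = unit_square.to_shapely().union(shifted.to_shapely()).area
        assert res.area_C + res.area_D == pytest.approx(union, rel=1e-12)
        iou = res.area_C / union
        assert res.j == pytest.approx(100 * iou, rel=1e-12)


class TestAlignModel:
    def test_fixed_point(self, cardioid_polygon):
        model = make_cardioid(1.0, 360)
        fit = align_model(cardioid_polygon, model, refine=False)
        cx, cy = cardioid_polygon.centroid
        assert abs(fit.translation[0] - cx) < 1e-9
        assert abs(fit.translation[1] - cy) < 1e-9
        assert abs(fit.rotation) % (2 * math.pi) < 1e-9
        assert fit.scale == pytest.approx(1.0, abs=1e-12)
        assert not fit.flipped

    def test_area_contract(self, rng):
        model = make_model("ovoid", 1.0, 256)
        seed = make_cardioid(2.5, 300).polygon.rotated(1.1).translated(4, -2)
        fit = align_model(seed, model, refine=False)
        placed = apply_fit(model.polygon, fit)
        assert placed.area == pytest.approx(seed.area, rel=1e-6)

    @pytest.mark.parametrize("angle,dx,dy", [
        (math.radians(40), 5.0, 3.0),
        (math.radians(-100), -2.0, 0.5),
        (math.radians(170), 0.0, -8.0),
    ])
    def test_self_recovery_of_displaced_copies(self, angle, dx, dy):
        model = make_cardioid(1.0, 360)
        seed = model.polygon.rotated(angle).translated(dx, dy)
        fit = align_model(seed, model, refine=False)
        j = compute_j(seed, apply_fit(model.polygon, fit)).j
        assert j >= 99.9

    def test_mirror_ambiguity_resolved(self):
        # an asymmetric seed: ovoid with a notch on one side
        model = make_model("ovoid", 1.0, 256, asymmetry=0.4)
        v = model.polygon.vertices.copy()
        top = (v[:, 1] > 0.3) & (np.abs(v[:, 0]) < 0.3)
        v[top] *= [1.0, 0.6]
        seed_base = Polygon(v)
        mirrored_seed = seed_base.mirrored().rotated(0.8).translated(1, 2)
        fit = align_model(mirrored_seed, seed_base, refine=False)
        j = compute_j(mirrored_seed, apply_fit(seed_base, fit)).j
        assert fit.flipped
        assert j >= 99.9

    def test_refinement_does_not_hurt(self):
        model = make_cardioid(1.0, 180)
        seed = model.polygon.rotated(0.35).translated(1.0, -0.7)
        j0 = compute_j(
            seed, apply_fit(model.polygon, align_model(seed, model, refine=False))
        ).j
        j1 = compute_j(
            seed, apply_fit(model.polygon, align_model(seed, model, refine=True))
        ).j
        assert j1 >= j0 - 1e-9


class TestRegionalJ:
    def test_symmetric_figures_have_equal_halves(self):
        seed = make_ellipse(2.0, 1.0, 360).polygon
        model = make_cardioid(1.0, 360).polygon
        model = model.translated(
            seed.centroid[0] - model.centroid[0],
            seed.centroid[1] - model.centroid[1],
        ).scaled(math.sqrt(seed.area / model.area))
        # both figures are mirror-symmetric across the x-axis, so split
        # along x (axis_angle 90°) to get two congruent halves
        reg = regional_j(seed, model, "halves_lr", axis_angle=math.pi / 2)
        assert reg["left"] == pytest.approx(reg["right"], abs=1e-6)

    def test_regions_recombine_to_global(self, cardioid_polygon):
        seed = cardioid_polygon
        model = make_ellipse(1.3, 0.9, 256).polygon.translated(*seed.centroid)
        glob = compute_j(seed, model)
        for scheme in ("halves_lr", "quadrants"):
            reg = regional_j(seed, model, scheme)
            assert sum(reg.areas_C.values()) == pytest.approx(glob.area_C, rel=1e-6)
            assert sum(reg.areas_D.values()) == pytest.approx(glob.area_D, rel=1e-6)
            c, d = sum(reg.areas_C.values()), sum(reg.areas_D.values())
            assert 100 * c / (c + d) == pytest.approx(glob.j, abs=1e-6)

    def test_notch_lowers_its_own_side(self):
        model = make_cardioid(1.0, 720).polygon
        v = model.vertices.copy()
        # carve a notch on the right (lobe side, +x beyond the centroid)
        right = v[:, 0] > 1.5
        cx, cy = model.centroid
        v[right] = (v[right] - [cx, cy]) * 0.8 + [cx, cy]
        seed = Polygon(v)
        placed = model.translated(
            seed.centroid[0] - model.centroid[0],
            seed.centroid[1] - model.centroid[1],
        )
        reg = regional_j(seed, placed, "halves_lr", axis_angle=0.0)
        assert reg["right"] < reg["left"]

    def test_empty_region_rejected(self, unit_square):
        far_origin = (50.0, 0.0)
        with pytest.raises(DegenerateRegionError):
            regional_j(unit_square, unit_square, "halves_lr", origin=far_origin)

    def test_quadrant_keys(self, cardioid_polygon):
        model = cardioid_polygon.scaled(1.05)
        reg = regional_j(cardioid_polygon, model, "quadrants")
        assert set(reg.values) == {"Q1", "Q2", "Q3", "Q4"}
        assert all(0 <= v <= 100 for v in reg.values.values())


class TestMorphotype:
    @pytest.mark.parametrize("left,right,expected", [
        (95, 85, Morphotype.A),
        (90, 85, Morphotype.B),
        (95, 70, Morphotype.C),
        (90, 70, Morphotype.BC),
        (92, 80, Morphotype.A),   # thresholds inclusive on the "above" side
        (91.999, 80, Morphotype.B),
    ])
    def test_examples(self, left, right, expected):
        assert classify_morphotype(left, right) is expected

    def test_exhaustive_grid_yields_exactly_four_labels(self):
        labels = {
            classify_morphotype(l, r)
            for l, r in itertools.product(range(0, 101, 2), repeat=2)
        }
        assert labels == {Morphotype.A, Morphotype.B, Morphotype.C, Morphotype.BC}

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            classify_morphotype(101.0, 50.0)


class TestCompareToModel:
    def test_cardioid_cusp_right_convention(self):
        # seed = the model itself: right region contains the cusp side
        model = make_cardioid(1.0, 360)
        seed = model.polygon.rotated(0.9).translated(3, 1)
        res = compare_to_model(seed, model, refine=False)
        assert res.overlap.j >= 99.9
        assert res.morphotype is Morphotype.A
        assert set(res.quadrants.values) == {"Q1", "Q2", "Q3", "Q4"}

    def test_noise_free_ovoid_against_itself(self):
        model = make_model("ovoid", 1.0, 256, asymmetry=0.3)
        seed = model.polygon.rotated(-1.4).translated(-2, 5)
        res = compare_to_model(seed, model, refine=False)
        assert res.overlap.j >= 99.9
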