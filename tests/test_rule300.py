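"""Green-space extraction, 300 m buffering, and proximity shares."""

import math

import numpy as np
import pytest
from scipy import ndimage
from shapely.geometry import box

from conftest import make_grid
from urban330.rule300 import (
    GREEN_URBAN_AREAS,
    NON_URBAN,
    URBAN_FABRIC,
    Rule300Config,
    buffer_green,
    extract_green_areas,
    population_within_distance,
    rule300_compliance,
    rule300_population_share,
)


def landuse_with_patch(shape=(20, 20), patch=None, cell=50.0):
    lu = np.full(shape, URBAN_FABRIC, dtype=np.int64)
    if patch is not None:
        lu[patch] = GREEN_URBAN_AREAS
    return make_grid(lu, cell_size=cell, role="landuse_class")


class TestExtraction:
    def test_one_hectare_patch_kept_inclusive(self):
        # 2x2 cells at 50 m = exactly 10,000 m^2
        lu = landuse_with_patch(patch=np.s_[4:6, 4:6])
        greens = extract_green_areas(lu, Rule300Config(), box(*lu.bounds))
        assert len(greens) == 1
        assert greens[0].area_m2 == pytest.approx(10_000.0)

    def test_sub_hectare_patch_dropped(self):
        lu = landuse_with_patch(patch=np.s_[4:5, 4:5])  # 2500 m^2
        assert extract_green_areas(lu, Rule300Config(), box(*lu.bounds)) == []

    def test_large_patch_area(self):
        lu = landuse_with_patch(patch=np.s_[5:15, 5:15])  # 10x10 cells
        greens = extract_green_areas(lu, Rule300Config(), box(*lu.bounds))
        assert len(greens) == 1
        assert greens[0].area_m2 == pytest.approx(250_000.0)
        assert greens[0].class_code == GREEN_URBAN_AREAS

    def test_urban_ceiling_masks_non_urban(self):
        # same codes, but a ceiling below the green classes excludes them
        lu = landuse_with_patch(patch=np.s_[2:8, 2:8])
        cfg = Rule300Config(urban_class_ceiling=1200.0)
        assert extract_green_areas(lu, cfg, box(*lu.bounds)) == []

    def test_non_green_classes_ignored(self):
        lu = np.full((20, 20), URBAN_FABRIC, dtype=np.int64)
        lu[0:10, 0:10] = NON_URBAN
        layer = make_grid(lu, cell_size=50.0, role="landuse_class")
        assert extract_green_areas(layer, Rule300Config(), box(*layer.bounds)) == []


class TestBuffer:
    def test_zero_buffer_is_identity(self):
        lu = landuse_with_patch(patch=np.s_[4:8, 4:8])
        greens = extract_green_areas(lu, Rule300Config(), box(*lu.bounds))
        cfg = Rule300Config(buffer_m=0.0)
        buf = buffer_green(greens, cfg)
        assert buf.area == pytest.approx(greens[0].polygon.area)

    def test_minkowski_closed_form_for_square(self):
        # square side a buffered by r: area = a^2 + 4 a r + pi r^2
        lu = landuse_with_patch(patch=np.s_[8:10, 8:10])  # 100 m square
        greens = extract_green_areas(lu, Rule300Config(), box(*lu.bounds))
        buf = buffer_green(greens, Rule300Config(buffer_m=300.0))
        exact = 100.0**2 + 4 * 100.0 * 300.0 + math.pi * 300.0**2
        assert abs(buf.area - exact) / exact < 0.005

    def test_disjoint_parks_add(self):
        lu = np.full((40, 40), URBAN_FABRIC, dtype=np.int64)
        lu[2:6, 2:6] = GREEN_URBAN_AREAS
        lu[34:38, 34:38] = GREEN_URBAN_AREAS
        layer = make_grid(lu, cell_size=50.0, role="landuse_class")
        greens = extract_green_areas(layer, Rule300Config(), box(*layer.bounds))
        assert len(greens) == 2
        buf = buffer_green(greens, Rule300Config(buffer_m=300.0))
        singles = [buffer_green([g], Rule300Config(buffer_m=300.0)) for g in greens]
        assert buf.area == pytest.approx(sum(s.area for s in singles))

    def test_empty_input(self):
        assert buffer_green([], Rule300Config()).is_empty


class TestCompliance:
    def _park_city(self):
        """Park strip on the left 200 m of a 10x10 (1 km) city at 100 m cells."""
        lu = np.full((20, 20), URBAN_FABRIC, dtype=np.int64)
        lu[:, :4] = GREEN_URBAN_AREAS  # x in [0, 200]
        landuse = make_grid(lu, cell_size=50.0, role="landuse_class")
        pop = make_grid(np.full((10, 10), 10.0), role="population")
        return landuse, pop

    def test_center_distance_rule(self):
        landuse, pop = self._park_city()
        greens = extract_green_areas(landuse, Rule300Config(), box(*landuse.bounds))
        buf = buffer_green(greens, Rule300Config(buffer_m=300.0))
        comp = rule300_compliance(buf, pop)
        # park edge at x=200; centers at 250..450 are within 300 m, 550 is not
        assert comp.values[0, 2] and comp.values[0, 4]
        assert not comp.values[0, 5]

    def test_center_on_buffer_boundary_is_inside(self):
        square = box(0, 0, 100, 100)
        from urban330.rule300 import GreenSpace

        buf = buffer_green(
            [GreenSpace(square, 10_000.0, GREEN_URBAN_AREAS)], Rule300Config(buffer_m=50.0)
        )
        pop = make_grid(np.zeros((2, 2)), cell_size=100.0)
        comp = rule300_compliance(buf, pop)
        # center (150, 50) sits exactly on the straight buffer edge x=150
        assert comp.values[1, 1]

    def test_share_extremes_and_consistency(self):
        landuse, pop = self._park_city()
        boundary = box(*landuse.bounds)
        greens = extract_green_areas(landuse, Rule300Config(), boundary)
        buf = buffer_green(greens, Rule300Config(buffer_m=300.0))
        comp = rule300_compliance(buf, pop)
        share = rule300_population_share(comp, pop, 1000.0)
        assert share == pytest.approx(0.5)  # columns 0-4 of 10
        # the generalized distance operation reproduces it exactly
        assert population_within_distance(greens, pop, 1000.0, 300.0) == share
        # distance 0: inside-park population only (columns 0-1)
        assert population_within_distance(greens, pop, 1000.0, 0.0) == pytest.approx(0.2)
        assert population_within_distance(greens, pop, 1000.0, math.inf) == 1.0
        assert rule300_population_share(
            rule300_compliance(buffer_green([], Rule300Config()), pop), pop, 1000.0
        ) == 0.0

    def test_monotone_in_buffer_and_min_area(self):
        rng = np.random.default_rng(12)
        lu = np.full((30, 30), URBAN_FABRIC, dtype=np.int64)
        lu[3:7, 3:7] = GREEN_URBAN_AREAS
        lu[20:22, 20:22] = GREEN_URBAN_AREAS
        lu[12, 25] = GREEN_URBAN_AREAS  # sub-hectare
        landuse = make_grid(lu, cell_size=50.0, role="landuse_class")
        boundary = box(*landuse.bounds)
        pop = make_grid(rng.uniform(0, 30, size=(15, 15)), role="population")
        total = pop.values.sum()

        def share(buffer_m, min_area):
            cfg = Rule300Config(buffer_m=buffer_m, min_area_m2=min_area)
            greens = extract_green_areas(landuse, cfg, boundary)
            comp = rule300_compliance(buffer_green(greens, cfg), pop)
            return rule300_population_share(comp, pop, total)

        shares_r = [share(b, 10_000.0) for b in (0.0, 100.0, 300.0, 600.0)]
        assert all(a <= b for a, b in zip(shares_r, shares_r[1:]))
        shares_a = [share(300.0, a) for a in (2000.0, 10_000.0, 50_000.0)]
        assert all(a >= b for a, b in zip(shares_a, shares_a[1:]))

    def test_vector_buffer_agrees_with_distance_transform(self):
        """Cross-check: polygon buffering vs. a raster Euclidean distance transform."""
        rng = np.random.default_rng(3)
        lu = np.full((60, 60), URBAN_FABRIC, dtype=np.int64)
        for _ in range(4):
            r, c = rng.integers(5, 50, size=2)
            lu[r : r + 4, c : c + 4] = GREEN_URBAN_AREAS
        landuse = make_grid(lu, cell_size=50.0, role="landuse_class")
        boundary = box(*landuse.bounds)
        cfg = Rule300Config(buffer_m=300.0)
        greens = extract_green_areas(landuse, cfg, boundary)
        pop = make_grid(np.zeros((30, 30)), cell_size=100.0, role="population")
        vec = rule300_compliance(buffer_green(greens, cfg), pop).values
        # raster route: burn green polygons by center membership, then an
        # exact Euclidean distance transform between cell centers
        import shapely

        X, Y = pop.cell_centers()
        inside = np.zeros((30, 30), dtype=bool)
        for g in greens:
            inside |= shapely.intersects_xy(g.polygon, X.ravel(), Y.ravel()).reshape(30, 30)
        dist = ndimage.distance_transform_edt(~inside, sampling=100.0)
        ras = dist <= 300.0
        assert (vec != ras).mean() <= 0.01
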