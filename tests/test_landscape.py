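"""Landscape-metric oracles: hand geometry and brute-force raster counts."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from linkerscape.config import AREA_CLASS_CODES
from linkerscape.landscape import (
    edge_density, geographic_distance, link_metrics, link_strip, metric_wide,
    node_buffer, node_metrics, percent_cover, relative_linear_length,
    shannon_heterogeneity,
)
from linkerscape.maps import LandUseMap
from linkerscape.rasters import Raster


def make_map(data, cell=10.0, lines=None):
    data = np.asarray(data)
    n_years = 3
    crop = {
        "MAIZE": np.zeros((n_years,) + data.shape, dtype=bool),
        "RAPESEED": np.zeros((n_years,) + data.shape, dtype=bool),
        "CEREAL": np.zeros((n_years,) + data.shape, dtype=bool),
    }
    return LandUseMap(
        landuse=Raster(data, 0.0, 0.0, cell),
        crop_years=crop, years=tuple(range(2008, 2008 + n_years)),
        lines=lines or {},
    )


def full_zone(lum):
    xmin, ymin, xmax, ymax = lum.landuse.extent
    return box(xmin, ymin, xmax, ymax)


class TestPercentCover:
    def test_uniform_class_gives_one(self):
        lum = make_map(np.full((10, 10), AREA_CLASS_CODES["GRASS"]))
        assert percent_cover(lum, full_zone(lum), "GRASS") == 1.0

    def test_absent_class_gives_zero(self):
        lum = make_map(np.full((10, 10), AREA_CLASS_CODES["GRASS"]))
        assert percent_cover(lum, full_zone(lum), "WATER") == 0.0

    def test_half_split_rectangle(self):
        data = np.full((10, 10), AREA_CLASS_CODES["GRASS"])
        data[:, 5:] = AREA_CLASS_CODES["ARABLE"]
        lum = make_map(data)
        assert percent_cover(lum, full_zone(lum), "ARABLE") == pytest.approx(0.5)

    def test_cover_sums_to_one_over_random_zones(self):
        rng = np.random.default_rng(1)
        data = rng.integers(1, 10, size=(40, 40)).astype(np.int16)
        lum = make_map(data)
        for _ in range(5):
            cx, cy = rng.uniform(100, 300, size=2)
            zone = node_buffer((cx, cy), rng.uniform(40, 120))
            total = sum(
                percent_cover(lum, zone, name) for name in AREA_CLASS_CODES
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_added_cells(self):
        data = np.full((20, 20), AREA_CLASS_CODES["GRASS"])
        lum = make_map(data)
        zone = node_buffer((100, 100), 50)
        before = percent_cover(lum, zone, "WATER")
        data[9:11, 9:11] = AREA_CLASS_CODES["WATER"]
        after = percent_cover(lum, zone, "WATER")
        assert after >= before


class TestCropDominance:
    def test_extremes_and_ratio(self):
        data = np.full((4, 4), AREA_CLASS_CODES["ARABLE"])
        lum = make_map(data)
        lum.crop_years["MAIZE"] = np.zeros((10, 4, 4), dtype=bool)
        lum.years = tuple(range(2008, 2018))
        lum.crop_years["MAIZE"][:, 0, 0] = True          # all 10 years
        lum.crop_years["MAIZE"][:3, 1, 1] = True         # 3 of 10 years
        dom = lum.dominance("MAIZE")
        assert dom.data[0, 0] == 1.0
        assert dom.data[1, 1] == pytest.approx(0.3)
        assert dom.data[2, 2] == 0.0

    def test_period_selection(self):
        data = np.full((2, 2), AREA_CLASS_CODES["ARABLE"])
        lum = make_map(data)
        lum.crop_years["MAIZE"][0, :, :] = True  # present only in 2008
        dom = lum.dominance("MAIZE", period=(2008, 2009))
        assert dom.data[0, 0] == pytest.approx(0.5)


class TestLinearLength:
    def test_no_lines_is_zero(self):
        lum = make_map(np.ones((10, 10)))
        assert relative_linear_length(lum, full_zone(lum), "L_ROAD") == 0.0

    def test_straight_line_in_unit_zone(self):
        # 100 m line fully inside a 1 km^2 zone -> 1e-4 per metre
        lum = make_map(np.ones((100, 100)), lines={
            "L_ROAD": [LineString([(450, 500), (550, 500)])],
        })
        zone = box(0, 0, 1000, 1000)
        assert relative_linear_length(lum, zone, "L_ROAD") == pytest.approx(1e-4)

    def test_clipped_diagonal_hand_geometry(self):
        # two-segment polyline; first segment crosses the zone boundary
        zone = box(0, 0, 100, 100)
        line = LineString([(-50, 50), (50, 50), (50, 150)])
        lum = make_map(np.ones((10, 10)), lines={"L_WOOD": [line]})
        # inside: (0,50)-(50,50) = 50 m and (50,50)-(50,100) = 50 m
        expected = 100.0 / zone.area
        assert relative_linear_length(lum, zone, "L_WOOD") == pytest.approx(expected)


class TestShannon:
    def test_single_class_zero(self):
        lum = make_map(np.ones((10, 10)))
        assert shannon_heterogeneity(lum, full_zone(lum)) == 0.0

    def test_four_equal_classes(self):
        data = np.zeros((10, 10))
        data[:5, :5], data[:5, 5:], data[5:, :5], data[5:, 5:] = 1, 2, 3, 4
        lum = make_map(data)
        assert shannon_heterogeneity(lum, full_zone(lum)) == pytest.approx(math.log(4))

    def test_direct_summation_oracle(self):
        # p = (0.5, 0.3, 0.2) over a 10-cell strip
        data = np.array([[1, 1, 1, 1, 1, 2, 2, 2, 3, 3]])
        lum = make_map(data)
        expected = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
        assert shannon_heterogeneity(lum, full_zone(lum)) == pytest.approx(expected)
        assert expected == pytest.approx(1.0297, abs=1e-4)

    def test_bounded_by_log_classes(self):
        rng = np.random.default_rng(2)
        data = rng.integers(1, 6, size=(30, 30))
        lum = make_map(data)
        h = shannon_heterogeneity(lum, full_zone(lum))
        assert 0.0 <= h <= math.log(len(np.unique(data)))


def brute_edge_density(data, cell):
    """Count unlike rook-neighbour edges by explicit loops."""
    n_r, n_c = data.shape
    length = 0.0
    for r in range(n_r):
        for c in range(n_c):
            if c + 1 < n_c and data[r, c] != data[r, c + 1]:
                length += cell
            if r + 1 < n_r and data[r, c] != data[r + 1, c]:
                length += cell
    return length / (data.size * cell * cell)


class TestEdgeDensity:
    def test_uniform_zone_zero(self):
        lum = make_map(np.ones((10, 10)))
        assert edge_density(lum, full_zone(lum)) == 0.0

    def test_vertical_half_split(self):
        data = np.ones((10, 10))
        data[:, 5:] = 2
        cell = 10.0
        lum = make_map(data, cell=cell)
        expected = 10 * cell / (100 * cell * cell)
        assert edge_density(lum, full_zone(lum)) == pytest.approx(expected)

    @pytest.mark.parametrize("pattern", ["checkerboard", "random"])
    def test_brute_force_oracle(self, pattern):
        cell = 10.0
        if pattern == "checkerboard":
            data = np.indices((12, 12)).sum(axis=0) % 2 + 1
        else:
            data = np.random.default_rng(3).integers(1, 4, size=(12, 12))
        lum = make_map(data, cell=cell)
        assert edge_density(lum, full_zone(lum)) == pytest.approx(
            brute_edge_density(data, cell)
        )


class TestStripGeometry:
    def test_area_is_ratio_times_d_squared(self):
        p1, p2 = (0.0, 0.0), (300.0, 400.0)   # d = 500
        for ratio in (1 / 7, 1 / 3, 2 / 3):
            strip = link_strip(p1, p2, ratio)
            assert strip.area == pytest.approx(ratio * 500.0 ** 2)

    def test_symmetric_in_endpoints(self):
        a = link_strip((10, 20), (200, 80), 0.5)
        b = link_strip((200, 80), (10, 20), 0.5)
        assert a.symmetric_difference(b).area == pytest.approx(0.0, abs=1e-6)

    def test_coincident_endpoints_error(self):
        with pytest.raises(ValueError):
            link_strip((5, 5), (5, 5), 0.5)

    def test_rotated_strip_cover_vs_rasterized_oracle(self):
        # diagonal strip over a half/half raster: compare with per-cell check
        data = np.full((60, 60), AREA_CLASS_CODES["GRASS"])
        data[:, 30:] = AREA_CLASS_CODES["ARABLE"]
        cell = 10.0
        lum = make_map(data, cell=cell)
        strip = link_strip((100, 100), (500, 450), 1 / 3)
        got = percent_cover(lum, strip, "ARABLE")
        inside_total, inside_arable = 0, 0
        for r in range(60):
            for c in range(60):
                x, y = (c + 0.5) * cell, (60 - r - 0.5) * cell
                if strip.contains(Point(x, y)):
                    inside_total += 1
                    if data[r, c] == AREA_CLASS_CODES["ARABLE"]:
                        inside_arable += 1
        assert got == pytest.approx(inside_arable / inside_total)


class TestDistanceAndTables:
    def test_distance_basics(self):
        assert geographic_distance((3, 4), (3, 4)) == 0.0
        assert geographic_distance((0, 0), (3, 4)) == 5.0
        assert geographic_distance((0, 0), (3, 4)) == geographic_distance((3, 4), (0, 0))

    def test_node_metrics_match_single_calls(self):
        rng = np.random.default_rng(4)
        data = rng.integers(1, 6, size=(50, 50))
        lum = make_map(data)
        lum.patch_centroids = {"A": (200.0, 250.0)}
        table = node_metrics(lum, lum.patch_centroids, radii=(60.0,),
                             metrics=("GRASS", "LANDHET", "EDGEDEN"))
        zone = node_buffer((200.0, 250.0), 60.0)
        byname = dict(zip(table["metric"], table["value"]))
        assert byname["GRASS"] == pytest.approx(percent_cover(lum, zone, "GRASS"))
        assert byname["LANDHET"] == pytest.approx(shannon_heterogeneity(lum, zone))
        assert byname["EDGEDEN"] == pytest.approx(edge_density(lum, zone))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.integers(1, 6, size=(40, 40))
        lum1 = make_map(data)
        lum2 = make_map(data)
        lum2.landuse.x0 += 1000.0
        lum2.landuse.y0 += 500.0
        z1 = node_buffer((200, 200), 80)
        z2 = node_buffer((1200, 700), 80)
        for name in ("GRASS", "ARABLE"):
            assert percent_cover(lum1, z1, name) == percent_cover(lum2, z2, name)
        assert shannon_heterogeneity(lum1, z1) == shannon_heterogeneity(lum2, z2)

    def test_metric_wide_naming(self):
        import pandas as pd
        tidy = pd.DataFrame([
            {"window": "W0", "unit": "A", "metric": "MAIZE", "scale": "2000",
             "value": 0.4, "level": "node"},
            {"window": "W0", "unit": "A", "metric": "DISTANCE", "scale": "-",
             "value": 812.0, "level": "link"},
        ])
        wide = metric_wide(tidy)
        assert "MAIZE2000" in wide.columns and "DISTANCE" in wide.columns
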