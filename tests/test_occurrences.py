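"""Occurrence cleaning, pixelization, validation, and the mobility buffer."""

import numpy as np
import pandas as pd
import pytest

from metarange.errors import UndefinedStatisticError
from metarange.gridspace import GridSpec, PresenceLayer, cell_of
from metarange.occurrences import (
    buffer_recovery,
    clean_occurrences,
    haversine_km,
    load_occurrences,
    pixelize,
    validate,
)


@pytest.fixture
def spec():
    return GridSpec()  # the default African window


def records(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "year"])


class TestCleanOccurrences:
    def test_null_island_record_is_dropped(self, spec):
        df = records([("sp", 0.5, 0.5, 2010)])
        assert len(clean_occurrences(df, spec)) == 0

    def test_pre_2001_record_is_dropped(self, spec):
        df = records([("sp", 30.0, -5.0, 1998)])
        assert len(clean_occurrences(df, spec)) == 0

    def test_year_2000_is_dropped_and_2001_kept_by_default(self, spec):
        df = records([("sp", 30.0, -5.0, 2000), ("sp", 30.0, -5.0, 2001)])
        out = clean_occurrences(df, spec)
        assert list(out["year"]) == [2001]

    def test_min_year_override(self, spec):
        df = records([("sp", 30.0, -5.0, 2000)])
        assert len(clean_occurrences(df, spec, min_year=2000)) == 1

    def test_null_island_box_is_closed(self, spec):
        df = records([("a", 2.0, 2.0, 2010), ("b", 2.01, 2.0, 2010)])
        out = clean_occurrences(df, spec)
        assert list(out["species"]) == ["b"]

    def test_planted_violation_classes_are_filtered_exactly(self, spec):
        good = [("g", 20.0 + i, -10.0, 2005) for i in range(5)]
        missing = [("m", np.nan, -10.0, 2005)] * 2
        outside = [("o", 100.0, -10.0, 2005)] * 3
        island = [("i", 1.0, -1.0, 2005)] * 4
        old = [("y", 20.0, -10.0, 1987)] * 6
        undated = [("u", 20.0, -10.0, np.nan)] * 2
        df = records(good + missing + outside + island + old + undated)
        out = clean_occurrences(df, spec)
        assert len(out) == len(good)
        assert set(out["species"]) == {"g"}

    def test_cleaning_is_idempotent(self, spec):
        rng = np.random.default_rng(4)
        df = records(
            [
                ("sp", rng.uniform(-30, 60), rng.uniform(-40, 45), int(rng.integers(1980, 2024)))
                for _ in range(200)
            ]
        )
        once = clean_occurrences(df, spec)
        twice = clean_occurrences(once, spec)
        pd.testing.assert_frame_equal(once, twice)


class TestPixelize:
    def test_repeated_sampling_collapses_to_one_pixel(self, spec):
        df = records([("sp", 30.1 + 0.001 * i, -5.1, 2010) for i in range(100)])
        layers = pixelize(df, spec)
        assert layers["sp"].range_size == 1

    def test_no_records_gives_no_layers(self, spec):
        assert pixelize(records([]), spec) == {}

    def test_matches_pointwise_cell_of_binning(self, spec):
        rng = np.random.default_rng(19)
        rows = [
            ("sp", rng.uniform(spec.lon_min, spec.lon_max - 1e-6),
             rng.uniform(spec.lat_min + 1e-6, spec.lat_max), 2010)
            for _ in range(300)
        ]
        layers = pixelize(records(rows), spec)
        expected = {cell_of(lon, lat, spec) for _, lon, lat, _ in rows}
        got = set(zip(*np.nonzero(layers["sp"].grid)))
        assert got == expected


class TestValidate:
    def layer_from(self, spec, cells):
        grid = np.zeros(spec.shape, dtype=bool)
        for rc in cells:
            grid[rc] = True
        return PresenceLayer("sp", grid, spec)

    def test_nested_layers_give_perfect_agreement(self, spec):
        gbif = self.layer_from(spec, [(10, 10), (11, 11)])
        adjusted = self.layer_from(spec, [(10, 10), (11, 11), (12, 12)])
        original = self.layer_from(spec, [(10, 10), (11, 11), (12, 12), (13, 13)])
        rec = validate(gbif, original, adjusted)
        assert (rec.prop_in_original, rec.prop_in_adjusted, rec.delta) == (1.0, 1.0, 0.0)

    def test_empty_adjusted_range_drops_agreement_to_zero(self, spec):
        gbif = self.layer_from(spec, [(10, 10), (11, 11)])
        original = self.layer_from(spec, [(10, 10)])
        adjusted = self.layer_from(spec, [])
        rec = validate(gbif, original, adjusted)
        assert rec.prop_in_adjusted == 0.0
        assert rec.delta == rec.prop_in_original == 0.5

    def test_hand_built_ten_pixel_fixture(self, spec):
        gbif_cells = [(0, i) for i in range(10)]
        rec = validate(
            self.layer_from(spec, gbif_cells),
            self.layer_from(spec, gbif_cells[:7]),
            self.layer_from(spec, gbif_cells[:4]),
        )
        assert rec.n_gbif_pixels == 10
        assert (rec.prop_in_original, rec.prop_in_adjusted) == (0.7, 0.4)
        assert rec.delta == pytest.approx(0.3)

    def test_adjusted_proportion_never_exceeds_original(self, spec):
        rng = np.random.default_rng(6)
        for _ in range(20):
            original = PresenceLayer("sp", rng.random(spec.shape) < 0.3, spec)
            adjusted = PresenceLayer(
                "sp", original.grid & (rng.random(spec.shape) < 0.7), spec
            )
            gbif = PresenceLayer("sp", rng.random(spec.shape) < 0.05, spec)
            if gbif.range_size == 0:
                continue
            rec = validate(gbif, original, adjusted)
            assert rec.prop_in_adjusted <= rec.prop_in_original

    def test_zero_gbif_pixels_is_undefined(self, spec):
        empty = self.layer_from(spec, [])
        some = self.layer_from(spec, [(0, 0)])
        with pytest.raises(UndefinedStatisticError):
            validate(empty, some, some)


class TestBufferRecovery:
    def removed(self, spec, cells):
        grid = np.zeros(spec.shape, dtype=bool)
        for rc in cells:
            grid[rc] = True
        return PresenceLayer("pred", grid, spec)

    def test_points_at_removed_cell_centers_with_zero_radius(self, spec):
        cells = [(10, 10), (20, 20), (30, 30)]
        removed = self.removed(spec, cells)
        pts = records(
            [("prey", *spec.cell_center(*cells[0]), 2010),
             ("prey", *spec.cell_center(*cells[1]), 2010)]
        )
        points_in, coverage = buffer_recovery(removed, pts, radius_km=0.0)
        assert points_in == 1.0
        assert coverage == pytest.approx(2 / 3)

    def test_all_points_outside_with_zero_radius(self, spec):
        removed = self.removed(spec, [(10, 10)])
        pts = records([("prey", *spec.cell_center(100, 100), 2010)])
        assert buffer_recovery(removed, pts, radius_km=0.0) == (0.0, 0.0)

    def test_coverage_is_non_decreasing_in_radius(self, spec):
        rng = np.random.default_rng(13)
        removed = self.removed(
            spec, [(int(r), int(c)) for r, c in rng.integers(0, 150, size=(25, 2))]
        )
        pts = records(
            [("prey", rng.uniform(-19, 54), rng.uniform(-34, 39), 2010) for _ in range(15)]
        )
        radii = [0, 50, 200, 1000, 5000]
        coverages = [buffer_recovery(removed, pts, r)[1] for r in radii]
        assert coverages == sorted(coverages)
        assert coverages[-1] == 1.0  # 5000 km blankets the study window

    def test_matches_all_pairs_haversine_oracle(self, spec):
        rng = np.random.default_rng(29)
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 150, size=(12, 2))]
        removed = self.removed(spec, cells)
        pts = [
            ("prey", rng.uniform(-19, 54), rng.uniform(-34, 39), 2010) for _ in range(9)
        ]
        radius = 750.0
        _, coverage = buffer_recovery(removed, records(pts), radius)
        hit = 0
        for r, c in set(cells):
            lon0, lat0 = spec.cell_center(r, c)
            if any(
                haversine_km(lon0, lat0, lon, lat) <= radius for _, lon, lat, _ in pts
            ):
                hit += 1
        assert coverage == pytest.approx(hit / len(set(cells)))

    def test_empty_removed_area_is_undefined(self, spec):
        with pytest.raises(UndefinedStatisticError):
            buffer_recovery(self.removed(spec, []), records([]), 50.0)


def test_gbif_column_aliases_are_accepted(tmp_path):
    path = tmp_path / "occ.csv"
    path.write_text(
        "species,decimalLongitude,decimalLatitude,year\nPanthera leo,30.0,-5.0,2012\n"
    )
    df = load_occurrences(str(path))
    assert list(df.columns) == ["species", "lon", "lat", "year"]
    assert df.iloc[0]["lon"] == 30.0


def test_haversine_matches_known_distance():
    # one degree of latitude on the sphere: R * pi / 180 ~ 111.19 km
    assert float(haversine_km(0.0, 0.0, 0.0, 1.0)) == pytest.approx(111.19, abs=0.01)
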