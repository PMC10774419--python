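"""Spatial allocation: gear cascade, prorating, masks, smoothing, regions."""

import numpy as np
import pandas as pd
import pytest

from effortmap import mapping
from effortmap.grid import Grid


@pytest.fixture(scope="module")
def families():
    return mapping.load_gear_families()


@pytest.fixture()
def open_grid():
    g = Grid(lat_min=0, lat_max=3.5, lon_min=0, lon_max=3.5, cell_size=0.5)
    g.coastal[:] = True  # no constraints unless a test sets them
    return g


class TestGearCascade:
    def test_exact_match_preferred(self, families):
        level, gears = mapping.match_gear("gillnets", {"gillnets", "seines"}, families)
        assert level == "exact" and gears == {"gillnets"}

    def test_family_fallback_collects_family_members(self, families):
        level, gears = mapping.match_gear("liftnets", {"gillnets", "seines", "longlines"}, families)
        assert level == "family" and gears == {"gillnets", "seines"}

    def test_country_level_when_no_family_overlap(self, families):
        level, gears = mapping.match_gear("traps", {"gillnets", "longlines"}, families)
        assert level == "country" and gears == {"gillnets", "longlines"}

    def test_unmapped_gear_raises(self, families):
        with pytest.raises(KeyError, match="unmapped gear"):
            mapping.match_gear("space_laser", {"gillnets"}, families)

    def test_cascade_is_total_for_known_gears(self, families):
        for gear in families:
            level, gears = mapping.match_gear(gear, {"bottom_trawls"}, families)
            assert level in {"exact", "family", "country"} and gears


class TestFunctionalGroupAllocation:
    def test_single_group_single_category_takes_all(self):
        out = mapping.allocate_to_functional_groups(
            100.0, pd.Series({"demersal": 5.0}), pd.Series({"cat": 1.0})
        )
        assert out.loc["demersal", "cat"] == pytest.approx(100.0)

    def test_catch_proportional_split(self):
        out = mapping.allocate_to_functional_groups(
            100.0, pd.Series({"d": 75.0, "p": 25.0}), pd.Series({"cat": 1.0})
        )
        assert out.loc["d", "cat"] == pytest.approx(75.0)
        assert out.loc["p", "cat"] == pytest.approx(25.0)

    def test_outer_product_hand_case(self):
        # GT shares 0.6/0.4 x FG catch 50/50 -> 0.30/0.30/0.20/0.20 of total
        out = mapping.allocate_to_functional_groups(
            100.0, pd.Series({"d": 1.0, "p": 1.0}), pd.Series({"big": 0.6, "small": 0.4})
        )
        np.testing.assert_allclose(
            out.loc[["d", "p"], ["big", "small"]].to_numpy(), [[30, 20], [30, 20]]
        )
        assert out.to_numpy().sum() == pytest.approx(100.0)

    def test_zero_catch_falls_back_uniform_with_flag(self):
        out = mapping.allocate_to_functional_groups(
            60.0, pd.Series({"d": 0.0, "p": 0.0}), pd.Series({"cat": 1.0})
        )
        assert out.attrs["fallback"] is True
        np.testing.assert_allclose(out["cat"].to_numpy(), [30.0, 30.0])


class TestCellAllocation:
    def test_all_catch_in_one_cell_takes_all_effort(self):
        cells = pd.DataFrame({"lat": [0.25, 0.75], "lon": [0.25, 0.25], "catch": [10.0, 0.0]})
        out = mapping.allocate_to_cells(50.0, cells)
        assert out.set_index("lat").loc[0.25, "effort"] == pytest.approx(50.0)

    def test_equal_catch_splits_equally(self):
        cells = pd.DataFrame({"lat": [0.25, 0.75], "lon": [0.25, 0.25], "catch": [5.0, 5.0]})
        out = mapping.allocate_to_cells(50.0, cells)
        np.testing.assert_allclose(out["effort"], [25.0, 25.0])

    def test_zero_catch_raises_for_fallback_path(self):
        cells = pd.DataFrame({"lat": [0.25], "lon": [0.25], "catch": [0.0]})
        with pytest.raises(ValueError, match="no catch"):
            mapping.allocate_to_cells(1.0, cells)


class TestConstraints:
    def test_unmotorized_moved_to_coastal_cells_proportionally(self, open_grid, families):
        open_grid.coastal[:] = False
        open_grid.coastal[0, :] = True  # only the southern row is coastal
        cells = pd.DataFrame(
            {
                "lat": [0.25, 0.25, 1.25, 2.25],
                "lon": [0.25, 0.75, 0.25, 0.25],
                "effort": [10.0, 20.0, 30.0, 40.0],
            }
        )
        out = mapping.apply_constraints(cells, open_grid, "UP", "liftnets", families)
        assert out["effort"].sum() == pytest.approx(100.0)
        out = out.set_index(["lat", "lon"])["effort"]
        # 30+40 redistributed over the two coastal cells in 1:2 proportion
        assert out.loc[(0.25, 0.25)] == pytest.approx(100 / 3)
        assert out.loc[(0.25, 0.75)] == pytest.approx(200 / 3)

    def test_trawl_ban_redistributes(self, open_grid, families):
        open_grid.trawl_ban[2, :] = True
        cells = pd.DataFrame(
            {"lat": [0.25, 1.25], "lon": [0.25, 0.25], "effort": [60.0, 40.0]}
        )
        banned = pd.DataFrame({"lat": [1.25], "lon": [0.25], "effort": [40.0]})
        # lat 1.25 -> row 2 is banned for trawls
        out = mapping.apply_constraints(
            pd.concat([cells.iloc[[0]], banned], ignore_index=True),
            open_grid, "I", "bottom_trawls", families,
        )
        assert out["effort"].sum() == pytest.approx(100.0)
        assert (out["lat"] != 1.25).all()

    def test_no_masked_cells_is_identity(self, open_grid, families):
        cells = pd.DataFrame({"lat": [0.25, 1.25], "lon": [0.25, 0.75], "effort": [1.0, 2.0]})
        out = mapping.apply_constraints(cells, open_grid, "I", "gillnets", families)
        pd.testing.assert_frame_equal(
            out.sort_values(["lat", "lon"]).reset_index(drop=True),
            cells.sort_values(["lat", "lon"]).reset_index(drop=True),
        )

    def test_all_disallowed_uses_uniform_coastal_fallback(self, open_grid, families):
        open_grid.coastal[:] = False
        open_grid.coastal[0, 0] = True
        open_grid.coastal[0, 1] = True
        cells = pd.DataFrame({"lat": [2.25], "lon": [2.25], "effort": [80.0]})
        fb = pd.DataFrame({"lat": [0.25, 0.25], "lon": [0.25, 0.75]})
        out = mapping.apply_constraints(cells, open_grid, "UP", "liftnets", families, fb)
        np.testing.assert_allclose(out["effort"], [40.0, 40.0])

    def test_all_disallowed_without_fallback_raises(self, open_grid, families):
        open_grid.coastal[:] = False
        cells = pd.DataFrame({"lat": [2.25], "lon": [2.25], "effort": [1.0]})
        with pytest.raises(ValueError, match="all cells disallowed"):
            mapping.apply_constraints(cells, open_grid, "UP", "liftnets", families)


class TestSmoothing:
    def test_width_zero_is_identity(self, open_grid, families):
        cells = pd.DataFrame({"lat": [1.25], "lon": [1.25], "effort": [9.0]})
        out = mapping.smooth_spread(cells, open_grid, sigma=0.0)
        pd.testing.assert_frame_equal(out, cells)

    def test_point_mass_spreads_to_discrete_gaussian(self, families):
        # 7x7 open grid, point mass at the centre, sigma 1: the smoothed
        # field must equal the truncated discrete Gaussian kernel itself
        g = Grid(lat_min=0, lat_max=3.5, lon_min=0, lon_max=3.5, cell_size=0.5)
        cells = pd.DataFrame({"lat": [1.75], "lon": [1.75], "effort": [1.0]})
        out = mapping.smooth_spread(cells, g, sigma=1.0, families=families)
        w = np.exp(-(np.arange(-3, 4) ** 2) / 2.0)
        kernel = np.outer(w, w) / np.outer(w, w).sum()
        dense = np.zeros((7, 7))
        dense[g.lat_index(out["lat"].to_numpy()), g.lon_index(out["lon"].to_numpy())] = out[
            "effort"
        ].to_numpy()
        np.testing.assert_allclose(dense, kernel, atol=1e-12)
        centre = out.set_index(["lat", "lon"])["effort"].loc[(1.75, 1.75)]
        assert centre == out["effort"].max()

    def test_total_conserved_even_at_boundaries(self, open_grid, families):
        cells = pd.DataFrame({"lat": [0.25], "lon": [0.25], "effort": [5.0]})
        out = mapping.smooth_spread(cells, open_grid, sigma=1.5, families=families)
        assert out["effort"].sum() == pytest.approx(5.0, rel=1e-9)

    def test_smoothing_respects_banned_cells(self, open_grid, families):
        open_grid.trawl_ban[:, 3:] = True
        cells = pd.DataFrame({"lat": [1.25], "lon": [1.25], "effort": [5.0]})
        out = mapping.smooth_spread(
            cells, open_grid, sigma=1.0, sector="I", gear="bottom_trawls", families=families
        )
        assert (out["lon"] < 1.75).all()
        assert out["effort"].sum() == pytest.approx(5.0, rel=1e-9)


class TestRegionalAggregation:
    def _effort(self):
        return pd.DataFrame(
            {
                "year": [2000, 2000, 2000],
                "lat": [0.25, 0.75, 1.25],
                "lon": [0.25, 0.25, 0.25],
                "effort": [1.0, 2.0, 4.0],
            }
        )

    def test_single_region_equals_global_total(self):
        regions = pd.DataFrame(
            {"lat": [0.25, 0.75, 1.25], "lon": 0.25, "region": "all"}
        )
        out = mapping.aggregate_by_region(self._effort(), regions)
        assert out["effort"].sum() == pytest.approx(7.0)

    def test_regions_partition_the_total(self):
        regions = pd.DataFrame(
            {"lat": [0.25, 0.75], "lon": 0.25, "region": ["south", "mid"]}
        )
        out = mapping.aggregate_by_region(self._effort(), regions).set_index("region")["effort"]
        assert out.loc["south"] == 1.0 and out.loc["mid"] == 2.0 and out.loc["none"] == 4.0
        assert out.sum() == pytest.approx(7.0)

    def test_yearly_relative_change_hand_case(self):
        eff = pd.DataFrame(
            {
                "year": [2000, 2001, 2002],
                "lat": 0.25,
                "lon": 0.25,
                "effort": [100.0, 110.0, 99.0],
            }
        )
        regions = pd.DataFrame({"lat": [0.25], "lon": [0.25], "region": ["r"]})
        out = mapping.aggregate_by_region(eff, regions).sort_values("year")
        rel = out["effort"].pct_change().dropna().to_numpy()
        np.testing.assert_allclose(rel, [0.10, -0.10])


def test_pipeline_conservation_after_all_stages(small_world, small_result):
    """Mapped nominal effort reproduces each national segment total."""
    saup = dict(zip(small_world.countries["country"], small_world.countries["saup"]))
    seg = small_result.segments.copy()
    seg["SAUP"] = seg["country"].map(saup)
    national = seg.set_index(["year", "SAUP", "sector", "length_class", "gear"])["nominal"]
    mapped = small_result.records.groupby(
        ["Year", "SAUP", "Sector", "Length_Category", "Gear"]
    )["NomActive"].sum()
    mapped.index.names = national.index.names
    joined = pd.concat([mapped.rename("mapped"), national.rename("national")], axis=1)
    assert not joined.isna().any().any()
    rel = (joined["mapped"] - joined["national"]).abs() / joined["national"]
    assert rel.max() < 1e-6


def test_mapped_records_non_negative_and_on_lattice(small_world, small_result):
    r = small_result.records
    for col in ("NV", "P", "GT", "NomActive", "EffActive"):
        assert (r[col] >= 0).all()
    assert small_world.grid.on_lattice(r["Lat"].to_numpy(), r["Lon"].to_numpy()).all()


def test_unmotorized_effort_confined_to_coastal_cells(small_world, small_result):
    up = small_result.records[small_result.records["Sector"] == "UP"]
    g = small_world.grid
    coastal = g.coastal[g.lat_index(up["Lat"].to_numpy()), g.lon_index(up["Lon"].to_numpy())]
    assert coastal.all()
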