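"""Equal-area grid, rasterization and aggregation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from polyselect.spatial import (
    BehrmannGrid,
    Raster,
    bin_by_latitude,
    bio4_from_monthly,
    cell_means,
    centroid_latitude,
    coarsen_occupancy,
    occupancy_from_bands,
    range_mean_raster,
    rasterize_range,
    read_cell_lists,
    write_cell_lists,
)


@pytest.fixture()
def grid():
    return BehrmannGrid(resolution_km=200.0)


def test_equal_area_property(grid):
    """Spherical band area between cell-edge latitudes equals the projected cell area."""
    R, res = grid.radius_km, grid.resolution_km
    # pick a few rows spread from equator to pole and compare sphere-band areas
    for row_offset in (0, 10, 25, 30):
        y0 = row_offset * res
        y1 = y0 + res
        lat0 = math.degrees(math.asin(min(y0 * grid._k / R, 1.0)))
        lat1 = math.degrees(math.asin(min(y1 * grid._k / R, 1.0)))
        band = 2 * math.pi * R**2 * (math.sin(math.radians(lat1)) - math.sin(math.radians(lat0)))
        n_cells_per_band = 2 * math.pi * R * grid._k / res
        assert band / n_cells_per_band == pytest.approx(grid.cell_area_km2, rel=1e-6)


def test_projection_round_trip(grid):
    lons = np.array([-170.0, -30.0, 0.0, 45.0, 179.0])
    lats = np.array([-60.0, -10.0, 0.0, 30.0, 75.0])
    x, y = grid.project(lons, lats)
    lon2, lat2 = grid.unproject(x, y)
    assert np.allclose(lons, lon2, atol=1e-10)
    assert np.allclose(lats, lat2, atol=1e-10)


def test_point_maps_back_to_containing_cell(grid):
    rng = np.random.default_rng(0)
    lon = rng.uniform(-179, 179, 50)
    lat = rng.uniform(-85, 85, 50)
    cid = grid.cell_of(lon, lat)
    x0, y0, x1, y1 = grid.cell_bounds(cid)
    x, y = grid.project(lon, lat)
    assert np.all((x >= x0) & (x < x1) & (y >= y0) & (y < y1))


def test_equatorial_row_centroid_latitude(grid):
    """Cells just north of the equator have centroid latitude within half a cell."""
    cid = grid.cell_of(0.0, 0.001)
    _, lat = grid.centroid_latlon(cid)
    half_cell_deg = math.degrees(grid.resolution_km * grid._k / grid.radius_km)
    assert 0.0 < float(lat) < half_cell_deg


def test_rasterize_exact_rectangle():
    grid = BehrmannGrid(resolution_km=100.0)
    # rectangle exactly covering a 2x2 block of projected cells
    res = grid.resolution_km
    rect = box(0.0, 0.0, 2 * res, 2 * res)
    cells = rasterize_range(rect, grid, geographic=False)
    assert len(cells) == 4


def test_rasterize_overlap_threshold():
    grid = BehrmannGrid(resolution_km=100.0)
    res = grid.resolution_km
    # covers 40% of one cell -> excluded; 60% -> included
    assert rasterize_range(box(0, 0, 0.4 * res, res), grid, geographic=False) == set()
    assert len(rasterize_range(box(0, 0, 0.6 * res, res), grid, geographic=False)) == 1


def test_rasterize_l_shape_against_exact_intersections():
    """L-shaped polygon on a 3x3 block, checked against shapely's exact areas."""
    grid = BehrmannGrid(resolution_km=100.0)
    res = grid.resolution_km
    L = Polygon([(0, 0), (3 * res, 0), (3 * res, res), (res, res),
                 (res, 3 * res), (0, 3 * res)])
    got = rasterize_range(L, grid, geographic=False)
    expected = set()
    for i in range(3):
        for j in range(3):
            cell = box(j * res, i * res, (j + 1) * res, (i + 1) * res)
            frac = L.intersection(cell).area / res**2
            if frac >= 0.5:
                row = i + grid.n_rows // 2
                col = j + grid.n_cols // 2
                expected.add(row * grid.n_cols + col)
    assert got == expected


def test_cell_means_threshold_and_values():
    grid = BehrmannGrid(resolution_km=200.0)
    c0 = int(grid.cell_of(0, 0))
    c1 = int(grid.cell_of(10, 0))
    occupancies = {}
    scores = {}
    # cell c0: 10 species, half scored 0 and half 4; cell c1: 9 species
    for i in range(10):
        occupancies[f"a{i}"] = {c0}
        scores[f"a{i}"] = 0.0 if i < 5 else 4.0
    for i in range(9):
        occupancies[f"b{i}"] = {c1}
        scores[f"b{i}"] = 1.0
    out = cell_means(occupancies, scores, grid, min_richness=10)
    assert list(out["cell_id"]) == [c0]
    assert out["mean_score"].iloc[0] == pytest.approx(2.0)


def test_cell_means_three_cell_world_hand_computed():
    grid = BehrmannGrid(resolution_km=200.0)
    cells = [int(grid.cell_of(lon, 0)) for lon in (0, 30, 60)]
    occ = {"s1": {cells[0], cells[1]}, "s2": {cells[1], cells[2]}, "s3": {cells[2]}}
    scores = {"s1": 1.0, "s2": 3.0, "s3": 2.0}
    out = cell_means(occ, scores, grid, min_richness=1).set_index("cell_id")
    assert out.loc[cells[0], "mean_score"] == pytest.approx(1.0)
    assert out.loc[cells[1], "mean_score"] == pytest.approx(2.0)
    assert out.loc[cells[2], "mean_score"] == pytest.approx(2.5)
    # incidence conservation: total richness equals total occupied-cell count
    assert out["richness"].sum() == sum(len(v) for v in occ.values())


def test_cell_means_permutation_invariance_and_missing_score_error():
    grid = BehrmannGrid(resolution_km=200.0)
    c = int(grid.cell_of(0, 0))
    occ = {f"s{i}": {c} for i in range(12)}
    scores = {f"s{i}": float(i % 5) for i in range(12)}
    a = cell_means(occ, scores, grid, min_richness=1)
    b = cell_means(dict(reversed(list(occ.items()))), scores, grid, min_richness=1)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError, match="no score"):
        cell_means({"x": {c}}, {}, grid, min_richness=1)


def test_range_mean_raster():
    grid = BehrmannGrid(resolution_km=1000.0)
    r = Raster.constant(grid, 7.5)
    cells = {int(grid.cell_of(0, 0)), int(grid.cell_of(20, 10))}
    assert range_mean_raster(cells, r) == pytest.approx(7.5)
    vals = np.full((grid.n_rows, grid.n_cols), np.nan)
    ids = sorted(cells)
    rows, cols = grid.rowcol(np.array(ids))
    vals[rows[0], cols[0]] = 10.0
    vals[rows[1], cols[1]] = 30.0
    assert range_mean_raster(cells, Raster(grid, vals)) == pytest.approx(20.0)
    assert np.isnan(range_mean_raster(set(), r))


def test_bio4_from_monthly():
    grid = BehrmannGrid(resolution_km=2000.0)
    identical = [Raster.constant(grid, 12.0) for _ in range(12)]
    assert np.allclose(bio4_from_monthly(identical).values, 0.0)
    alternating = [Raster.constant(grid, 1.0 if m % 2 == 0 else -1.0) for m in range(12)]
    assert np.allclose(bio4_from_monthly(alternating).values, 1.0)
    series = np.array([3.0, 5.0, 7.0, 4.0, 6.0, 8.0, 2.0, 9.0, 1.0, 5.5, 6.5, 3.5])
    layers = [Raster.constant(grid, v) for v in series]
    assert bio4_from_monthly(layers).values[0, 0] == pytest.approx(series.std(ddof=0))
    with pytest.raises(ValueError):
        bio4_from_monthly(layers[:11])


def test_centroid_latitude():
    sym = box(-20, -15, 20, 15)
    assert centroid_latitude(sym) == pytest.approx(0.0, abs=1e-9)
    north = box(0, 10, 30, 20)
    lat = centroid_latitude(north)
    assert 10 < lat < 20


def test_bin_by_latitude_histogram_oracle():
    rng = np.random.default_rng(4)
    lat = rng.uniform(-30, 30, 200)
    df = pd.DataFrame({"centroid_lat": lat, "score": rng.integers(0, 5, 200)})
    out = bin_by_latitude(df, width=5.0)
    counts, _ = np.histogram(lat, bins=np.arange(-90, 95, 5))
    expected = {(-90 + 5 * i + 2.5): c for i, c in enumerate(counts) if c > 0}
    got = dict(zip(out["bin_lat_mid"], out["n_species"]))
    assert got == expected
    assert (out.loc[out["n_species"] < 10, "excluded"]).all()
    single = bin_by_latitude(pd.DataFrame({"centroid_lat": [12.0] * 11,
                                           "score": [1] * 11}), width=5.0)
    assert len(single) == 1 and not single["excluded"].iloc[0]


def test_coarsen_occupancy_union_and_conservation():
    fine = BehrmannGrid(resolution_km=100.0)
    coarse = BehrmannGrid(resolution_km=200.0)
    bands = pd.DataFrame({"species_id": ["s1"], "lat_min": [-5.0], "lat_max": [5.0],
                          "lon_min": [-10.0], "lon_max": [10.0]})
    occ = occupancy_from_bands(bands, fine)
    c_occ = coarsen_occupancy(occ, fine, coarse)
    # every fine cell's centroid must land inside one of the coarse cells claimed
    ids = np.array(sorted(occ["s1"]))
    x0, y0, x1, y1 = fine.cell_bounds(ids)
    claimed = coarse.cell_of_projected((x0 + x1) / 2, (y0 + y1) / 2)
    assert set(int(c) for c in claimed) == c_occ["s1"]
    assert len(c_occ["s1"]) <= len(occ["s1"])


def test_cell_list_roundtrip(tmp_path):
    occ = {"a": {1, 2, 3}, "b": {7}}
    path = tmp_path / "cells.csv"
    write_cell_lists(occ, path)
    assert read_cell_lists(path) == occ


def test_raster_text_roundtrip(tmp_path):
    grid = BehrmannGrid(resolution_km=2000.0)
    rng = np.random.default_rng(1)
    r = Raster(grid, rng.normal(size=(grid.n_rows, grid.n_cols)))
    p = tmp_path / "r.txt"
    r.write_text(p)
    back = Raster.read_text(p)
    assert back.grid == grid
    assert np.allclose(back.values, r.values, atol=1e-6)
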