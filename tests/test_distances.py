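import itertools

import numpy as np
import pytest

from landgen.distances import (DistanceMatrix, environment_matrix,
                               geographic_matrix, haversine_km,
                               least_cost_matrix, linearize_fst)
from landgen.genotypes import SiteTable, load_packaged_sites
from landgen.raster import ElevationRaster, read_esri_ascii, write_esri_ascii

from oracles import haversine_longhand, least_cost_enumerate

import pandas as pd


def sites_from(records):
    df = pd.DataFrame(records).set_index("population")
    return SiteTable(df)


# ---------------------------------------------------------------------------
# DistanceMatrix container
# ---------------------------------------------------------------------------

def test_distance_matrix_rejects_asymmetry():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_distance_matrix_rejects_nonzero_diagonal():
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_distance_matrix_round_trips_tsv(tmp_path):
    m = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]],
                                                 dtype=float))
    m.write_tsv(tmp_path / "m.tsv")
    back = DistanceMatrix.read_tsv(tmp_path / "m.tsv")
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values)


# ---------------------------------------------------------------------------
# Geographic distance
# ---------------------------------------------------------------------------

def test_one_degree_latitude_is_111_km():
    assert haversine_km(40.0, -3.0, 41.0, -3.0) == pytest.approx(111.195, abs=0.01)


def test_identical_coordinates_zero():
    assert haversine_km(40.0, -3.0, 40.0, -3.0) == 0.0


def test_geographic_matrix_matches_independent_formula(packaged_sites):
    """NAJ-PEN ~ 11.1 km, cross-checked by the spherical law of cosines."""
    m = geographic_matrix(packaged_sites)
    df = m.to_dataframe()
    naj = packaged_sites.data.loc["NAJ"]
    pen = packaged_sites.data.loc["PEN"]
    oracle = haversine_longhand(naj["lat"], naj["lon"], pen["lat"], pen["lon"])
    assert df.loc["NAJ", "PEN"] == pytest.approx(oracle, abs=1e-6)
    assert df.loc["NAJ", "PEN"] == pytest.approx(11.1, abs=0.3)


def test_log_transform_of_coincident_sites_is_error():
    sites = sites_from([
        dict(population="a", lat=40.0, lon=-3.0),
        dict(population="b", lat=40.0, lon=-3.0),
    ])
    with pytest.raises(ValueError, match="coincide"):
        geographic_matrix(sites, log_transform=True)


# ---------------------------------------------------------------------------
# Environmental distance
# ---------------------------------------------------------------------------

def test_environment_matrix_absolute_difference(packaged_sites):
    m = environment_matrix(packaged_sites, "tmin").to_dataframe()
    assert m.loc["NAJ", "PEN"] == pytest.approx(1.9)
    assert m.loc["NAJ", "NAJ"] == 0.0


@pytest.mark.parametrize("variable", ["tmax", "tmin"])
def test_environment_triangle_inequality_all_triples(packaged_sites, variable):
    m = environment_matrix(packaged_sites, variable).values
    n = m.shape[0]
    for i, j, k in itertools.permutations(range(n), 3):
        assert m[i, j] <= m[i, k] + m[k, j] + 1e-12


def test_environment_missing_variable_is_error(packaged_sites):
    with pytest.raises(ValueError, match="no variable"):
        environment_matrix(packaged_sites, "snowpack")


# ---------------------------------------------------------------------------
# Least-cost distance
# ---------------------------------------------------------------------------

def flat_raster(values, cell=100.0):
    arr = np.asarray(values, dtype=float)
    return ElevationRaster(values=arr, xll=0.0, yll=0.0, cell_size=cell,
                           geographic=False)


def projected_sites(points):
    # projected raster: coordinates go in the x/y columns
    return sites_from([dict(population=p, lat=0.0, lon=0.0, x=x, y=y)
                       for p, x, y in points])


def test_straight_line_on_1x5_raster():
    raster = flat_raster([[2000.0] * 5])
    sites = projected_sites([("a", 50.0, 50.0), ("b", 450.0, 50.0)])
    m = least_cost_matrix(raster, sites)
    assert m.values[0, 1] == pytest.approx(4 * 100.0)


def test_site_to_itself_zero():
    raster = flat_raster([[2000.0] * 3])
    sites = projected_sites([("a", 150.0, 50.0)])
    m = least_cost_matrix(raster, sites)
    assert m.values[0, 0] == 0.0


def test_threshold_semantics():
    """1279 m is impassable, 1281 m passable, at the 1280 m default."""
    raster = flat_raster([[2000.0, 1279.0, 2000.0]])
    sites = projected_sites([("a", 50.0, 50.0), ("b", 250.0, 50.0)])
    with pytest.warns(UserWarning, match="disconnected"):
        blocked = least_cost_matrix(raster, sites)
    assert np.isinf(blocked.values[0, 1])
    raster2 = flat_raster([[2000.0, 1281.0, 2000.0]])
    open_ = least_cost_matrix(raster2, sites)
    assert open_.values[0, 1] == pytest.approx(200.0)


def test_site_on_impassable_cell_is_error():
    raster = flat_raster([[2000.0, 900.0]])
    sites = projected_sites([("a", 150.0, 50.0)])
    with pytest.raises(ValueError, match="impassable"):
        least_cost_matrix(raster, sites)


def test_barrier_grid_matches_path_enumeration():
    """5x5 grid, impassable middle column except one gap cell."""
    grid = np.full((5, 5), 2000.0)
    grid[:, 2] = 900.0
    grid[3, 2] = 2000.0          # the gap
    raster = flat_raster(grid, cell=10.0)
    sites = projected_sites([("a", 5.0, 45.0), ("b", 45.0, 45.0)])
    m = least_cost_matrix(raster, sites)
    passable = (grid >= 1280.0).tolist()
    oracle = least_cost_enumerate(passable, (0, 0), (0, 4), dx=10.0, dy=10.0)
    assert m.values[0, 1] == pytest.approx(oracle, abs=1e-9)


def test_empty_grid_equals_octile_distance():
    grid = np.full((6, 7), 2000.0)
    raster = flat_raster(grid, cell=10.0)
    sites = projected_sites([("a", 5.0, 55.0), ("b", 65.0, 15.0)])
    m = least_cost_matrix(raster, sites)
    # octile closed form: diag steps over the short axis, straight the rest
    drow, dcol = 4, 6
    expected = min(drow, dcol) * 10.0 * np.sqrt(2) + abs(drow - dcol) * 10.0
    assert m.values[0, 1] == pytest.approx(expected, abs=1e-9)
    # also bounded below by the straight line
    assert m.values[0, 1] >= np.hypot(drow * 10.0, dcol * 10.0) - 1e-9


def test_lowering_threshold_never_increases_cost(ibd_scenario):
    _, raster, sites, *_ = ibd_scenario
    high = least_cost_matrix(raster, sites, threshold_m=1280.0)
    low = least_cost_matrix(raster, sites, threshold_m=1000.0)
    assert (low.values <= high.values + 1e-9).all()


def test_geographic_raster_row_scaling():
    """East-west steps shrink with cos(latitude) on geographic rasters."""
    grid = np.full((1, 3), 2000.0)
    raster = ElevationRaster(values=grid, xll=0.0, yll=59.995, cell_size=0.01,
                             geographic=True)
    sites = sites_from([dict(population="a", lat=60.0, lon=0.005),
                        dict(population="b", lat=60.0, lon=0.025)])
    m = least_cost_matrix(raster, sites)
    expected = 2 * 0.01 * 6371.0088e3 * np.pi / 180.0 * np.cos(np.radians(60.0))
    assert m.values[0, 1] == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# FST linearization
# ---------------------------------------------------------------------------

def test_linearize_fst_values():
    m = DistanceMatrix(["a", "b", "c"],
                       np.array([[0.0, 0.5, 0.09], [0.5, 0.0, 0.0],
                                 [0.09, 0.0, 0.0]]), kind="genetic")
    out = linearize_fst(m)
    assert out.values[0, 1] == pytest.approx(1.0)
    assert out.values[0, 2] == pytest.approx(0.09 / 0.91)
    assert out.values[1, 2] == 0.0


def test_linearize_fst_floors_negatives_and_rejects_one():
    m = DistanceMatrix(["a", "b"], np.array([[0.0, -0.02], [-0.02, 0.0]]))
    with pytest.warns(UserWarning, match="floored"):
        out = linearize_fst(m)
    assert out.values[0, 1] == 0.0
    bad = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError, match=">= 1"):
        linearize_fst(bad)


def test_linearize_fst_strictly_increasing():
    x = np.linspace(0, 0.95, 50)
    y = x / (1 - x)
    assert (np.diff(y) > 0).all()


# ---------------------------------------------------------------------------
# ESRI ASCII raster I/O
# ---------------------------------------------------------------------------

def test_esri_ascii_round_trip(tmp_path):
    grid = np.array([[1000.0, np.nan], [1500.0, 2000.0]])
    raster = ElevationRaster(values=grid, xll=-6.0, yll=40.0, cell_size=0.02)
    write_esri_ascii(raster, tmp_path / "r.asc")
    back = read_esri_ascii(tmp_path / "r.asc")
    assert back.cell_size == raster.cell_size
    assert back.xll == raster.xll
    assert np.allclose(back.values, raster.values, equal_nan=True)
    assert back.geographic


def test_cell_of_maps_corners():
    raster = ElevationRaster(values=np.zeros((2, 3)), xll=0.0, yll=0.0,
                             cell_size=1.0, geographic=False)
    assert raster.cell_of(0.5, 1.5) == (0, 0)      # top-left cell
    assert raster.cell_of(2.5, 0.5) == (1, 2)      # bottom-right cell
    with pytest.raises(ValueError, match="outside"):
        raster.cell_of(3.5, 0.5)
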