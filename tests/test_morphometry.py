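"""Inundation, grid measures vs brute-force oracles, the change table."""

import numpy as np
import pandas as pd
import pytest

from phytoind import (
    TerrainGrid,
    change_table,
    generate_terrain,
    inundate,
    measure,
    measure_scenarios,
    percent_decrease,
    read_ascii_grid,
    write_ascii_grid,
)


BOWL = TerrainGrid(np.array([[2.0, 2, 2], [2, 0, 2], [2, 2, 2]]), cell_size=1.0)


def test_bowl_single_cell_body():
    labels = inundate(BOWL, 1.0)
    assert labels.max() == 1
    assert (labels > 0).sum() == 1


def test_level_below_minimum_no_bodies():
    labels = inundate(BOWL, -5.0)
    assert labels.max() == 0
    m = measure(BOWL, labels, -5.0)
    assert m.surface_area_m2 == 0 and m.volume_m3 == 0 and m.shoreline_length_m == 0


def test_level_exactly_at_minimum_dry():
    """Strict inequality: cells at the level are dry."""
    labels = inundate(BOWL, 0.0)
    assert labels.max() == 0


def test_bowl_measures_hand_count():
    labels = inundate(BOWL, 1.0)
    m = measure(BOWL, labels, 1.0)
    assert m.surface_area_m2 == pytest.approx(1.0)
    assert m.volume_m3 == pytest.approx(1.0)
    assert m.shoreline_length_m == pytest.approx(4.0)
    assert m.n_bodies == 1


def _flood_fill_count(water: np.ndarray) -> int:
    """Brute-force 8-connected component count."""
    seen = np.zeros_like(water, bool)
    n = 0
    for i in range(water.shape[0]):
        for j in range(water.shape[1]):
            if water[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < water.shape[0]
                                and 0 <= xx < water.shape[1]
                                and water[yy, xx]
                                and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return n


def test_two_pits_flood_fill_oracle():
    z = np.full((7, 7), 5.0)
    z[1, 1] = 0.0
    z[5, 5] = 0.0
    grid = TerrainGrid(z, 1.0)
    labels = inundate(grid, 1.0)
    assert labels.max() == 2
    assert _flood_fill_count(grid.elevations < 1.0) == 2


def test_diagonal_cells_connect():
    z = np.full((4, 4), 5.0)
    z[1, 1] = 0.0
    z[2, 2] = 0.0
    labels = inundate(TerrainGrid(z, 1.0), 1.0)
    assert labels.max() == 1  # 8-connectivity joins diagonals


def _brute_measures(grid, level):
    """Independent per-cell summation oracle."""
    water = (grid.elevations < level) & ~grid.nodata
    cs = grid.cell_size
    area = water.sum() * cs * cs
    volume = ((level - grid.elevations)[water]).sum() * cs * cs
    edges = 0
    ny, nx = water.shape
    for i in range(ny):
        for j in range(nx):
            if not water[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < ny and 0 <= jj < nx) or not water[ii, jj]:
                    edges += 1
    return edges * cs, float(area), float(volume)


def test_random_grid_measures_equal_bruteforce():
    rng = np.random.default_rng(11)
    z = rng.uniform(0, 10, (50, 50))
    grid = TerrainGrid(z, cell_size=12.5)
    level = 5.0
    m = measure(grid, inundate(grid, level), level)
    shoreline, area, volume = _brute_measures(grid, level)
    assert m.shoreline_length_m == pytest.approx(shoreline, abs=1e-9)
    assert m.surface_area_m2 == pytest.approx(area, abs=1e-9)
    assert m.volume_m3 == pytest.approx(volume, rel=1e-12)


def test_nodata_is_dry_and_generates_shoreline():
    z = np.array([[np.nan, 0.0], [5.0, 5.0]])
    grid = TerrainGrid(z, 1.0)
    labels = inundate(grid, 1.0)
    assert (labels > 0).sum() == 1
    m = measure(grid, labels, 1.0)
    assert m.shoreline_length_m == pytest.approx(4.0)


def test_area_volume_monotone_in_level():
    rng = np.random.default_rng(12)
    z = rng.uniform(0, 10, (30, 30))
    grid = TerrainGrid(z, 2.0)
    prev_area, prev_vol = -1.0, -1.0
    for level in np.linspace(0, 12, 25):
        m = measure(grid, inundate(grid, level), level)
        assert m.surface_area_m2 >= prev_area
        assert m.volume_m3 >= prev_vol - 1e-9
        prev_area, prev_vol = m.surface_area_m2, m.volume_m3


def test_dv_dlevel_approximates_area():
    rng = np.random.default_rng(13)
    z = rng.uniform(0, 10, (40, 40))
    grid = TerrainGrid(z, 5.0)
    dl = 0.01
    for level in (3.0, 5.0, 7.0):
        m0 = measure(grid, inundate(grid, level), level)
        m1 = measure(grid, inundate(grid, level + dl), level + dl)
        dv_dl = (m1.volume_m3 - m0.volume_m3) / dl
        cell_volume = grid.cell_size**2 * dl
        # tolerance: one cell volume per step plus cells entering the mask
        assert abs(dv_dl - m0.surface_area_m2) <= max(
            m1.surface_area_m2 - m0.surface_area_m2, grid.cell_size**2
        ) + 1e-6


def test_paraboloid_volume_close_to_analytic():
    grid, depressions = generate_terrain(
        nx=60, ny=60, n_depressions=1, depth_range=(5.0, 5.0), seed=3,
        radius_range_cells=(12.0, 12.0),
    )
    level = 20.0  # base elevation: floods the depression to its rim
    m = measure(grid, inundate(grid, level), level)
    analytic = depressions["analytic_volume_m3"].iloc[0]
    assert m.volume_m3 == pytest.approx(analytic, rel=0.05)


def test_ascii_grid_roundtrip(tmp_path):
    grid, _ = generate_terrain(seed=4)
    grid.elevations[0, 0] = np.nan  # nodata corner
    grid2 = TerrainGrid(grid.elevations, grid.cell_size)
    path = tmp_path / "dem.asc"
    write_ascii_grid(grid2, path)
    back = read_ascii_grid(path)
    assert back.cell_size == grid2.cell_size
    assert back.nodata[0, 0]
    ok = ~grid2.nodata
    assert np.allclose(back.elevations[ok], grid2.elevations[ok], atol=1e-4)


# --- change table -----------------------------------------------------------


def test_percent_decrease_rounding_half_up():
    assert percent_decrease(38658, 8953) == 76.8
    assert percent_decrease(1413644, 163523) == 88.4
    assert percent_decrease(100, 100) == 0.0
    assert percent_decrease(0, 5) is None
    assert percent_decrease(1000, 875.5) == 12.5  # 12.45 rounds half-up


def test_change_table_unknown_scenario():
    from phytoind.morphometry import WaterBodyMorphometry

    m = WaterBodyMorphometry("spring", 15.0, 100.0, 200.0, 300.0, 1)
    with pytest.raises(KeyError):
        change_table([m], [("spring", "summer")])


def test_change_table_from_scenarios():
    z = np.full((20, 20), 10.0)
    z[5:15, 5:15] = 0.0
    grid = TerrainGrid(z, 1.0)
    measures = measure_scenarios(grid, {"high": 4.0, "low": 2.0})
    tab = change_table(measures, [("high", "low")])
    row = tab.loc["high->low"]
    assert row["surface_area_m2"] == 0.0  # same footprint
    assert row["volume_m3"] == 50.0  # 400 -> 200
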