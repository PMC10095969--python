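import math

import numpy as np
import pandas as pd
import pytest

from helpers import make_profile, step_profile_grid
from phytokin import (
    DegenerateProfileError,
    KinematicConfig,
    analyze_plant,
    cell_number,
    growth_zone_end,
    kinematic_analysis,
)

LN2 = math.log(2.0)


class TestGrowthZoneEnd:
    def test_step_profile(self, step_profile):
        x_gz, l_mat = growth_zone_end(step_profile)
        assert x_gz == 0.5
        assert l_mat == 100.0

    def test_strictly_increasing_profile(self):
        grid = np.arange(0, 1.05, 0.1)
        values = 20.0 + 80.0 * grid  # max 100 at x=1
        prof = make_profile(grid, values)
        x_gz, l_mat = growth_zone_end(prof, mature_fraction=0.95)
        # first grid point with value >= 95: x = 0.9375 -> grid 1.0
        assert x_gz == pytest.approx(1.0)
        assert l_mat == pytest.approx(100.0)

    def test_constant_profile_is_degenerate(self):
        prof = make_profile(np.arange(0, 1.05, 0.1), np.full(11, 80.0))
        with pytest.raises(DegenerateProfileError):
            growth_zone_end(prof)


class TestCellNumber:
    def test_constant_density(self):
        prof = make_profile(np.arange(0, 0.25, 0.05), np.full(5, 50.0))
        assert cell_number(prof, 0.0, 0.2) == pytest.approx(40.0)
        prof20 = make_profile(np.arange(0, 0.25, 0.05), np.full(5, 20.0))
        assert cell_number(prof20, 0.0, 0.2) == pytest.approx(100.0)

    def test_off_grid_endpoints_interpolate(self):
        prof = make_profile([0.0, 1.0], [50.0, 50.0])
        assert cell_number(prof, 0.13, 0.77) == pytest.approx(
            (0.77 - 0.13) * 1e4 / 50.0
        )

    def test_against_fine_grid_quadrature_oracle(self):
        grid = np.arange(0, 8.05, 0.1)
        values = 20 + 110 / (1 + np.exp(-(grid - 3.5) / 0.9))
        prof = make_profile(grid, values)
        n = cell_number(prof, 0.7, 6.3)
        xs = np.arange(0.7, 6.3 + 1e-12, 1e-4)
        oracle = np.trapezoid(1.0 / np.interp(xs, grid, values), xs) * 1e4
        assert n == pytest.approx(oracle, rel=1e-3)

    def test_midpoint_rule_close_to_trapezoid_on_dense_grid(self):
        grid = np.arange(0, 8.05, 0.1)
        values = 20 + 110 / (1 + np.exp(-(grid - 3.5) / 0.9))
        prof = make_profile(grid, values)
        a = cell_number(prof, 0.0, 8.0, rule="trapezoid")
        b = cell_number(prof, 0.0, 8.0, rule="midpoint")
        assert b == pytest.approx(a, rel=1e-3)

    def test_nonpositive_profile_errors(self):
        prof = make_profile([0.0, 0.5, 1.0], [50.0, -1.0, 50.0])
        with pytest.raises(ValueError, match="non-positive"):
            cell_number(prof, 0.0, 1.0)

    def test_bad_limits_error(self, step_profile):
        with pytest.raises(ValueError, match="limits"):
            cell_number(step_profile, 0.5, 0.2)


class TestAnalyzePlant:
    def expected_step_values(self):
        """Hand-evaluated chain on the gridded step profile (0.1 cm grid,
        20 µm below 0.5 cm, 100 µm from 0.5 cm): trapezoid across the jump
        cell gives N_el = 0.005 + 0.005 + (0.05 + 0.01)/2 * 0.1 cm/µm
        = 0.013 cm/µm -> 130 cells."""
        n_el = 130.0
        p = 20.0
        return {
            "ler_mm_h": 2.0,
            "meristem_length_mm": 2.0,
            "elongation_zone_length_mm": 3.0,
            "growth_zone_length_mm": 5.0,
            "cell_length_leaving_meristem_um": 20.0,
            "mature_cell_length_um": 100.0,
            "cells_in_meristem": 100.0,
            "cells_in_elongation_zone": n_el,
            "cells_in_growth_zone": 230.0,
            "cell_production_rate_cells_h": p,
            "cell_division_rate_cells_cell_h": 0.2,
            "relative_elongation_rate_um_um_h": math.log(5.0) / (n_el / p),
            "cell_cycle_duration_h": LN2 / 0.2,
            "time_in_meristem_h": (LN2 / 0.2) * math.log2(100.0),
            "time_in_elongation_zone_h": n_el / p,
        }

    def test_step_profile_chain(self, step_profile):
        res = analyze_plant(2.0, step_profile, 2000.0)
        for key, val in self.expected_step_values().items():
            assert getattr(res, key) == pytest.approx(val, rel=1e-9), key

    def test_homogeneity_in_ler(self, step_profile):
        r1 = analyze_plant(2.0, step_profile, 2000.0)
        r2 = analyze_plant(4.0, step_profile, 2000.0)
        rel = 1e-12
        assert r2.cell_production_rate_cells_h == pytest.approx(
            2 * r1.cell_production_rate_cells_h, rel=rel
        )
        assert r2.cell_division_rate_cells_cell_h == pytest.approx(
            2 * r1.cell_division_rate_cells_cell_h, rel=rel
        )
        assert r2.relative_elongation_rate_um_um_h == pytest.approx(
            2 * r1.relative_elongation_rate_um_um_h, rel=rel
        )
        for key in (
            "cell_cycle_duration_h",
            "time_in_meristem_h",
            "time_in_elongation_zone_h",
        ):
            assert getattr(r2, key) == pytest.approx(getattr(r1, key) / 2, rel=rel)
        for key in (
            "meristem_length_mm",
            "elongation_zone_length_mm",
            "growth_zone_length_mm",
            "cells_in_meristem",
            "cells_in_elongation_zone",
            "mature_cell_length_um",
        ):
            assert getattr(r2, key) == getattr(r1, key)

    def test_single_meristem_cell_spends_zero_time_there(self):
        # l = 100 µm below 0.5 cm and 1000 µm above; meristem of 0.01 cm
        # holds exactly one 100 µm cell
        grid = np.round(np.arange(0.0, 1.05, 0.01), 10)
        values = np.where(grid < 0.5, 100.0, 1000.0)
        prof = make_profile(grid, values)
        res = analyze_plant(2.0, prof, 100.0)
        assert res.cells_in_meristem == pytest.approx(1.0, rel=1e-12)
        assert res.time_in_meristem_h == pytest.approx(0.0, abs=1e-12)

    def test_submeristem_cell_count_reports_missing_division_stats(self, caplog):
        grid = np.round(np.arange(0.0, 1.05, 0.01), 10)
        values = np.where(grid < 0.5, 100.0, 1000.0)
        prof = make_profile(grid, values)
        with caplog.at_level("WARNING", logger="phytokin.kinematics"):
            res = analyze_plant(2.0, prof, 50.0)  # N_mer = 0.5
        assert math.isnan(res.cell_division_rate_cells_cell_h)
        assert math.isnan(res.cell_cycle_duration_h)
        assert any("DEGENERATE_DIVISION" in r.message for r in caplog.records)

    def test_meristem_beyond_growth_zone_names_plant(self, step_profile):
        with pytest.raises(ValueError, match="T1.*exceeds"):
            analyze_plant(2.0, step_profile, 6000.0)

    def test_unit_handling_against_mm_only_reference(self, step_profile):
        """Independent oracle: the same chain written in mm everywhere."""
        res = analyze_plant(2.0, step_profile, 2000.0)
        x_mm = step_profile.grid * 10.0
        l_mm = step_profile.fitted_length / 1000.0
        mer_mm = 2.0
        l_max = l_mm.max()
        idx = int(np.flatnonzero(l_mm >= 0.95 * l_max)[0])
        x_gz_mm = x_mm[idx]
        l_mat_mm = l_mm[idx:].mean()
        l_div_mm = np.interp(mer_mm, x_mm, l_mm)

        def count(a, b):
            inner = x_mm[(x_mm > a) & (x_mm < b)]
            xs = np.concatenate(([a], inner, [b]))
            return np.trapezoid(1.0 / np.interp(xs, x_mm, l_mm), xs)

        n_mer = count(0.0, mer_mm)
        n_el = count(mer_mm, x_gz_mm)
        p = 2.0 / l_mat_mm
        d = p / n_mer
        assert res.cells_in_meristem == pytest.approx(n_mer, rel=1e-12)
        assert res.cells_in_elongation_zone == pytest.approx(n_el, rel=1e-12)
        assert res.cell_production_rate_cells_h == pytest.approx(p, rel=1e-12)
        assert res.cell_division_rate_cells_cell_h == pytest.approx(d, rel=1e-12)
        assert res.mature_cell_length_um == pytest.approx(l_mat_mm * 1000, rel=1e-12)
        assert res.cell_length_leaving_meristem_um == pytest.approx(
            l_div_mm * 1000, rel=1e-12
        )


class TestKinematicAnalysis:
    def tidy_inputs(self, n_plants=3):
        grid, values = step_profile_grid()
        tidy = pd.concat(
            [
                pd.DataFrame(
                    {"plant_id": f"P{i}", "position": grid, "fitted_length": values}
                )
                for i in range(n_plants)
            ],
            ignore_index=True,
        )
        means = pd.DataFrame(
            {
                "plant_id": [f"P{i}" for i in range(n_plants)],
                "mean_ler_mm_h": [2.0 + 0.5 * i for i in range(n_plants)],
            }
        )
        mer = pd.DataFrame(
            {
                "plant_id": [f"P{i}" for i in range(n_plants)],
                "mer_length_um": [2000.0] * n_plants,
            }
        )
        return means, tidy, mer

    def test_one_row_per_plant_with_identities(self):
        means, tidy, mer = self.tidy_inputs()
        res = kinematic_analysis(means, tidy, mer)
        assert len(res) == 3
        for _, row in res.iterrows():
            assert row["growth_zone_length_mm"] == pytest.approx(
                row["meristem_length_mm"] + row["elongation_zone_length_mm"],
                rel=1e-9,
            )
            assert row["cell_production_rate_cells_h"] == pytest.approx(
                row["cell_division_rate_cells_cell_h"] * row["cells_in_meristem"],
                rel=1e-9,
            )
            assert row["cell_cycle_duration_h"] * row[
                "cell_division_rate_cells_cell_h"
            ] == pytest.approx(LN2, rel=1e-9)

    def test_missing_meristem_entry_skips_only_that_plant(self, caplog):
        means, tidy, mer = self.tidy_inputs()
        mer = mer[mer["plant_id"] != "P1"]
        with caplog.at_level("WARNING", logger="phytokin.kinematics"):
            res = kinematic_analysis(means, tidy, mer)
        assert list(res["plant_id"]) == ["P0", "P2"]
        assert any(pid == "P1" for pid, _ in res.attrs["failures"])

    def test_column_order_is_the_reporting_order(self):
        from phytokin import RESULT_COLUMNS

        means, tidy, mer = self.tidy_inputs(1)
        res = kinematic_analysis(means, tidy, mer)
        assert list(res.columns) == ["plant_id", *RESULT_COLUMNS]
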