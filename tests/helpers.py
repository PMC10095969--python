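"""Shared builders for test fixtures."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from phytokin import FittedProfile, LeafLengthTable


def make_leaf_table(lengths_by_plant, start="2021/03/01 10:00", interval_h=24.0):
    """LeafLengthTable from {plant_id: [length or nan, ...]}."""
    t0 = datetime.strptime(start, "%Y/%m/%d %H:%M")
    n = max(len(v) for v in lengths_by_plant.values())
    times = [t0 + timedelta(hours=interval_h * k) for k in range(n)]
    frame = pd.DataFrame.from_dict(
        {pid: list(v) + [np.nan] * (n - len(v)) for pid, v in lengths_by_plant.items()},
        orient="index",
        columns=times,
    )
    frame.index.name = "plant_id"
    return LeafLengthTable(frame)


def make_leaf_table_at_times(lengths_by_plant, times):
    frame = pd.DataFrame.from_dict(lengths_by_plant, orient="index", columns=times)
    frame.index.name = "plant_id"
    return LeafLengthTable(frame)


def make_profile(grid, values, plant_id="T1"):
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    return FittedProfile(
        plant_id=plant_id,
        grid=grid,
        fitted_length=values,
        derivative=np.gradient(values, grid),
        extrapolated=np.zeros(grid.size, dtype=bool),
    )


def step_profile_grid(interval=0.1, x_step=0.5, x_end=1.0, lo=20.0, hi=100.0):
    """The idealised step profile sampled on a regular grid."""
    grid = np.round(np.arange(0.0, x_end + interval / 2, interval), 10)
    values = np.where(grid < x_step, lo, hi).astype(float)
    return grid, values


def brute_force_local_linear(x, y, grid, h):
    """Independent local-linear oracle: explicit WLS solve per grid point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(len(grid))
    for j, g in enumerate(grid):
        d = x - g
        w = np.exp(-(d**2) / (2.0 * h * h))
        X = np.column_stack([np.ones_like(d), d])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        out[j] = beta[0]
    return out
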