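"""Leaf elongation rates (LER) from irregular leaf-length time series.

Each consecutive pair of *non-missing* measurements of a plant defines one
interval; a missing measurement in the middle of a series simply merges its
two bracketing intervals into one longer interval, so the rate over the
merged span is the duration-weighted mean of the rates it replaces.  The
per-plant mean LER, the steady-state elongation rate fed into the kinematic
equations, averages the first ``n_LER_for_mean`` interval rates
(chronologically, starting at the first non-missing measurement); plants
with fewer intervals contribute all they have.

Rates are in mm·h⁻¹ with interval durations computed at exact minute
resolution.  Negative rates (shrinking length readings) are computed as-is
but flagged: they indicate measurement or data-entry error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import LeafLengthTable

__all__ = ["compute_interval_lers", "calculate_ler", "OUTPUT_MODES"]

logger = logging.getLogger(__name__)

OUTPUT_MODES = ("means", "tidy_LER", "wide_LER")

_TIDY_COLUMNS = [
    "plant_id",
    "interval_index",
    "t_start",
    "t_end",
    "delta_t_h",
    "delta_L_mm",
    "ler_mm_h",
]


def compute_interval_lers(leaf: LeafLengthTable) -> pd.DataFrame:
    """Per-interval elongation rates for every plant.

    Returns a tidy frame with columns plant_id, interval_index (1-based,
    chronological), t_start, t_end, delta_t_h, delta_L_mm and ler_mm_h.
    Plants with fewer than two non-missing measurements contribute no rows
    and are reported through a warning.
    """
    times = leaf.timepoints
    rows = []
    for pid in leaf.plant_ids:
        values = leaf.lengths(pid)
        present = np.flatnonzero(np.isfinite(values))
        if present.size < 2:
            logger.warning(
                "[NO_INTERVALS] plant %s has %d usable measurement(s); "
                "cannot compute any LER", pid, present.size,
            )
            continue
        for k, (i, j) in enumerate(zip(present[:-1], present[1:]), start=1):
            dt_h = (times[j] - times[i]).total_seconds() / 3600.0
            dl = values[j] - values[i]
            ler = dl / dt_h
            if ler < 0:
                logger.warning(
                    "[NEGATIVE_LER] plant %s interval %d has LER %.4g mm/h; "
                    "leaf lengths should not decrease", pid, k, ler,
                )
            rows.append((pid, k, times[i], times[j], dt_h, dl, ler))
    return pd.DataFrame(rows, columns=_TIDY_COLUMNS)


def calculate_ler(
    leaf: LeafLengthTable,
    n_LER_for_mean: int = 2,
    output: str = "means",
    time_weighted: bool = False,
):
    """Interval LERs and per-plant means.

    ``output`` selects the result layout: ``means`` (one mean LER per
    plant, the default), ``tidy_LER`` (all intervals, long form) or
    ``wide_LER`` (plants × intervals matrix).  The mean uses the first
    ``n_LER_for_mean`` intervals of each plant; when a plant has fewer,
    all available intervals enter the mean.  ``time_weighted=True`` swaps
    the plain arithmetic mean of interval rates for total growth divided
    by total time over those intervals (the two differ when interval
    durations are unequal).
    """
    if output not in OUTPUT_MODES:
        raise ValueError(
            f"output must be one of {list(OUTPUT_MODES)}, got {output!r}"
        )
    if n_LER_for_mean < 1:
        raise ValueError("n_LER_for_mean must be >= 1")

    tidy = compute_interval_lers(leaf)
    if output == "tidy_LER":
        return tidy
    if output == "wide_LER":
        wide = tidy.pivot(
            index="plant_id", columns="interval_index", values="ler_mm_h"
        )
        return wide.reindex([p for p in leaf.plant_ids if p in wide.index])

    rows = []
    by_plant = dict(iter(tidy.groupby("plant_id", sort=False)))
    for pid in leaf.plant_ids:
        sub = by_plant.get(pid)
        if sub is None:
            rows.append((pid, float("nan"), 0))
            continue
        head = sub.nsmallest(n_LER_for_mean, "interval_index")
        if time_weighted:
            mean = head["delta_L_mm"].sum() / head["delta_t_h"].sum()
        else:
            mean = head["ler_mm_h"].mean()
        rows.append((pid, float(mean), int(len(head))))
    return pd.DataFrame(rows, columns=["plant_id", "mean_ler_mm_h", "n_intervals_used"])
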