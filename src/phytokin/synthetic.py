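"""Synthetic growth-zone data with analytically known kinematic truth.

The simulator emulates the three measurement tables a kinematic experiment
produces — leaf-length time series, cell-length profiles and meristem
sizes — from a parameterised steady-state growth-zone model, so the whole
pipeline can be exercised end-to-end against exact ground truth without
any laboratory data.

A scenario fixes a true cell-length profile l*(x) along the leaf axis
(logistic by default: a smooth rise from small meristematic cells to a
mature-length plateau; a piecewise-exponential and an idealised step
profile are also available), a true leaf elongation rate, and a measured
meristem length.  Measurements are then sampled with configurable noise,
replication and missing-data patterns, deterministically per seed.

``ground_truth`` evaluates the same kinematic equation chain as the
analysis module but on the *analytic* noiseless profile, with exact
(piecewise closed-form or high-accuracy adaptive) integrals instead of
grid quadrature — an independent oracle for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .io_tables import (
    LeafLengthTable,
    write_cell_lengths,
    write_leaf_lengths,
    write_meristem_sizes,
)
from .kinematics import RESULT_COLUMNS, UM_PER_CM, UM_PER_MM, MM_PER_CM, KinematicConfig

__all__ = [
    "SimScenario",
    "simulate_profile",
    "simulate_cell_lengths",
    "simulate_leaf_lengths",
    "simulate_meristem",
    "ground_truth",
    "write_scenario_files",
    "true_profile",
]

PROFILE_SHAPES = ("logistic", "piecewise_exponential", "step")

_DEFAULT_POSITIONS = tuple(round(0.05 + 0.1 * k, 3) for k in range(100))


@dataclass
class SimScenario:
    """Parameters of one simulated experiment.

    The defaults mirror a typical maize setting: a ~10 cm sampled basal
    region, a 1 cm meristem of ~20 µm cells expanding to a ~130 µm mature
    plateau by 6 cm, an elongation rate of 3 mm/h, daily leaf measurements
    and 5–7 dissected plants.

    ``x_gz_cm`` anchors the profile shape: for the logistic it is the
    position where l* reaches 95% of its upper asymptote, for the
    piecewise-exponential the start of the mature plateau, for the step
    the jump position.  ``noise_sd_um`` is the additive Gaussian SD of a
    single cell-length measurement (draws are floored at 1 µm); with
    ``multiplicative_noise`` it is reinterpreted as a coefficient of
    variation.  ``missing_leaf`` maps plant index → time-point indices
    whose leaf-length measurement is dropped.
    """

    n_plants: int = 7
    ler_mm_h: float = 3.0
    initial_leaf_length_mm: float = 50.0
    mer_length_um: float = 10000.0
    mer_jitter_um: float = 0.0
    l_init_um: float = 18.0
    l_div_um: float = 25.0
    l_mat_um: float = 130.0
    x_gz_cm: float = 6.0
    profile_shape: str = "logistic"
    noise_sd_um: float = 5.0
    multiplicative_noise: bool = False
    cells_per_position: int = 3
    sampling_positions: tuple = _DEFAULT_POSITIONS
    n_leaf_measurements: int = 4
    measurement_interval_h: float = 24.0
    start_time: str = "2021/03/01 10:00"
    leaf_noise_sd_mm: float = 1.0
    missing_leaf: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.profile_shape not in PROFILE_SHAPES:
            raise ValueError(f"profile_shape must be one of {PROFILE_SHAPES}")
        if not 0 < self.l_init_um <= self.l_div_um < self.l_mat_um:
            raise ValueError("need 0 < l_init <= l_div < l_mat")
        if self.mer_length_um / UM_PER_CM >= self.x_gz_cm:
            raise ValueError("meristem must end before the growth zone does")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")

    def plant_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_plants)]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["missing_leaf"] = {str(k): list(v) for k, v in self.missing_leaf.items()}
        d["sampling_positions"] = list(self.sampling_positions)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        d = json.loads(text)
        d["missing_leaf"] = {
            int(k): tuple(v) for k, v in d.get("missing_leaf", {}).items()
        }
        d["sampling_positions"] = tuple(d["sampling_positions"])
        return cls(**d)


def _rng(scn: SimScenario, stream: int, plant: int = 0) -> np.random.Generator:
    return np.random.default_rng([scn.seed, stream, plant])


# ---------------------------------------------------------------------------
# analytic true profiles
# ---------------------------------------------------------------------------


class _StepProfile:
    """l = l_lo below the jump, l_hi from it on (right-continuous)."""

    def __init__(self, l_lo, l_hi, x_step):
        self.l_lo, self.l_hi, self.x_step = l_lo, l_hi, x_step
        self.breakpoints = (x_step,)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x < self.x_step, self.l_lo, self.l_hi)

    def threshold_crossing(self, thr):
        if thr <= self.l_lo:
            return 0.0
        return self.x_step

    def _split(self, a, b):
        below = max(0.0, min(b, self.x_step) - a)
        return below, (b - a) - below

    def integral_inverse(self, a, b):
        below, above = self._split(a, b)
        return below / self.l_lo + above / self.l_hi

    def mean_length(self, a, b):
        below, above = self._split(a, b)
        return (below * self.l_lo + above * self.l_hi) / (b - a)


class _LogisticProfile:
    """l(x) = lo + (hi - lo) / (1 + exp(-(x - x0)/s))."""

    def __init__(self, lo, hi, x0, s):
        self.lo, self.hi, self.x0, self.s = lo, hi, x0, s
        self.breakpoints = ()

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.lo + (self.hi - self.lo) / (1.0 + np.exp(-(x - self.x0) / self.s))

    def threshold_crossing(self, thr):
        p = (thr - self.lo) / (self.hi - self.lo)
        if p <= 0.0:
            return 0.0
        return self.x0 + self.s * math.log(p / (1.0 - p))

    def integral_inverse(self, a, b):
        val, _ = quad(lambda x: 1.0 / float(self(x)), a, b,
                      epsabs=1e-13, epsrel=1e-13, limit=200)
        return val

    def mean_length(self, a, b):
        val, _ = quad(lambda x: float(self(x)), a, b,
                      epsabs=1e-11, epsrel=1e-13, limit=200)
        return val / (b - a)


class _PiecewiseExpProfile:
    """Exponential growth within meristem and elongation zone, then flat.

    l rises exponentially from l_init at the base to l_div at the meristem
    end, exponentially again to l_mat at the growth-zone end, and stays at
    l_mat beyond.
    """

    def __init__(self, l_init, l_div, l_mat, mer_cm, x_gz):
        self.l_init, self.l_div, self.l_mat = l_init, l_div, l_mat
        self.mer_cm, self.x_gz = mer_cm, x_gz
        self.alpha = math.log(l_div / l_init) / mer_cm if l_div > l_init else 0.0
        self.beta = math.log(l_mat / l_div) / (x_gz - mer_cm)
        self.breakpoints = (mer_cm, x_gz)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        mer = self.l_init * np.exp(self.alpha * np.minimum(x, self.mer_cm))
        elo = self.l_div * np.exp(
            self.beta * np.clip(x - self.mer_cm, 0.0, self.x_gz - self.mer_cm)
        )
        return np.where(x <= self.mer_cm, mer, np.minimum(elo, self.l_mat))

    def threshold_crossing(self, thr):
        if thr <= self.l_init:
            return 0.0
        if thr <= self.l_div and self.alpha > 0:
            return math.log(thr / self.l_init) / self.alpha
        if thr <= self.l_mat:
            return self.mer_cm + math.log(thr / self.l_div) / self.beta
        return self.x_gz

    def _seg_inv(self, l0, rate, x0, a, b):
        # integral of dx / (l0 * exp(rate * (x - x0))) over [a, b]
        if rate == 0.0:
            return (b - a) / l0
        return (math.exp(-rate * (a - x0)) - math.exp(-rate * (b - x0))) / (l0 * rate)

    def integral_inverse(self, a, b):
        total = 0.0
        segs = [
            (0.0, self.mer_cm, self.l_init, self.alpha, 0.0),
            (self.mer_cm, self.x_gz, self.l_div, self.beta, self.mer_cm),
            (self.x_gz, math.inf, self.l_mat, 0.0, self.x_gz),
        ]
        for lo, hi, l0, rate, x0 in segs:
            aa, bb = max(a, lo), min(b, hi)
            if bb > aa:
                total += self._seg_inv(l0, rate, x0, aa, bb)
        return total

    def mean_length(self, a, b):
        val, _ = quad(lambda x: float(self(x)), a, b,
                      points=[p for p in self.breakpoints if a < p < b],
                      epsabs=1e-11, epsrel=1e-13, limit=200)
        return val / (b - a)


def true_profile(scn: SimScenario):
    """The analytic cell-length profile l*(x) implied by a scenario."""
    mer_cm = scn.mer_length_um / UM_PER_CM
    if scn.profile_shape == "step":
        return _StepProfile(scn.l_div_um, scn.l_mat_um, scn.x_gz_cm)
    if scn.profile_shape == "piecewise_exponential":
        return _PiecewiseExpProfile(
            scn.l_init_um, scn.l_div_um, scn.l_mat_um, mer_cm, scn.x_gz_cm
        )
    # logistic through (mer, l_div) and (x_gz, 0.95 * asymptote)
    lo, hi = scn.l_init_um, scn.l_mat_um
    p1 = (scn.l_div_um - lo) / (hi - lo)
    p2 = (0.95 * hi - lo) / (hi - lo)
    if not 0.0 < p1 < p2 < 1.0:
        raise ValueError(
            "logistic profile needs l_init < l_div < 0.95 * l_mat"
        )
    z1 = math.log(p1 / (1.0 - p1))
    z2 = math.log(p2 / (1.0 - p2))
    s = (scn.x_gz_cm - mer_cm) / (z2 - z1)
    x0 = mer_cm - s * z1
    return _LogisticProfile(lo, hi, x0, s)


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------


def simulate_profile(scn: SimScenario, plant: int) -> pd.DataFrame:
    """Noisy cell-length measurements for one plant (0-based index).

    At each sampling position, ``cells_per_position`` draws around the
    true profile; deterministic given (scenario, seed, plant).
    """
    prof = true_profile(scn)
    rng = _rng(scn, 0, plant)
    pid = scn.plant_ids()[plant]
    rows = []
    for pos in scn.sampling_positions:
        truth = float(prof(pos))
        for _ in range(scn.cells_per_position):
            if scn.noise_sd_um == 0:
                val = truth
            elif scn.multiplicative_noise:
                val = truth * (1.0 + rng.normal(0.0, scn.noise_sd_um))
            else:
                val = truth + rng.normal(0.0, scn.noise_sd_um)
            rows.append((pid, pos, max(val, 1.0)))
    return pd.DataFrame(rows, columns=["plant_id", "position", "cell_length"])


def simulate_cell_lengths(scn: SimScenario) -> pd.DataFrame:
    """Stacked cell-length table for all plants."""
    return pd.concat(
        [simulate_profile(scn, i) for i in range(scn.n_plants)],
        ignore_index=True,
    )


def simulate_leaf_lengths(scn: SimScenario) -> LeafLengthTable:
    """Leaf-length time series L(t) = L0 + LER·t + noise for all plants.

    The per-plant ``missing_leaf`` mask blanks individual time points,
    which downstream merges the bracketing elongation intervals.
    """
    t0 = datetime.strptime(scn.start_time, "%Y/%m/%d %H:%M")
    times = [
        t0 + timedelta(hours=scn.measurement_interval_h * k)
        for k in range(scn.n_leaf_measurements)
    ]
    hours = np.array(
        [scn.measurement_interval_h * k for k in range(scn.n_leaf_measurements)]
    )
    data = {}
    for i, pid in enumerate(scn.plant_ids()):
        rng = _rng(scn, 1, i)
        vals = scn.initial_leaf_length_mm + scn.ler_mm_h * hours
        if scn.leaf_noise_sd_mm > 0:
            vals = vals + rng.normal(0.0, scn.leaf_noise_sd_mm, vals.shape)
        for k in scn.missing_leaf.get(i, ()):
            vals[k] = np.nan
        data[pid] = vals
    frame = pd.DataFrame.from_dict(data, orient="index", columns=times)
    frame.index.name = "plant_id"
    return LeafLengthTable(frame)


def simulate_meristem(scn: SimScenario) -> pd.DataFrame:
    """Per-plant meristem lengths, optionally jittered around the truth."""
    rng = _rng(scn, 2)
    vals = np.full(scn.n_plants, scn.mer_length_um)
    if scn.mer_jitter_um > 0:
        vals = vals + rng.normal(0.0, scn.mer_jitter_um, scn.n_plants)
    return pd.DataFrame({"plant_id": scn.plant_ids(), "mer_length_um": vals})


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


def ground_truth(
    scn: SimScenario, config: KinematicConfig | None = None
) -> pd.DataFrame:
    """The kinematic parameters implied analytically by a scenario.

    Applies the same rules as the analysis (mature-fraction growth-zone
    end, density integral, flux balance) directly to the noiseless
    analytic profile with exact integration — the oracle against which the
    pipeline's estimates are compared.  One row per plant (rows differ
    only when the meristem jitter is non-zero).
    """
    if config is None:
        config = KinematicConfig()
    prof = true_profile(scn)
    x_end = float(max(scn.sampling_positions))
    mer_table = simulate_meristem(scn)

    l_max = float(prof(x_end))
    thr = config.mature_fraction * l_max
    x_gz = prof.threshold_crossing(thr)
    rows = []
    for pid, mer_um in zip(mer_table["plant_id"], mer_table["mer_length_um"]):
        mer_cm = mer_um / UM_PER_CM
        if not 0.0 < x_gz <= x_end or mer_cm >= x_gz:
            raise ValueError(
                f"scenario degenerate for plant {pid}: meristem "
                f"{mer_cm:g} cm vs growth zone end {x_gz:g} cm"
            )
        l_mat = prof.mean_length(x_gz, x_end)
        l_div = float(prof(mer_cm))
        n_mer = prof.integral_inverse(0.0, mer_cm) * UM_PER_CM
        n_el = prof.integral_inverse(mer_cm, x_gz) * UM_PER_CM
        production = scn.ler_mm_h * UM_PER_MM / l_mat
        division = production / n_mer
        t_c = math.log(2.0) / division
        t_mer = t_c * math.log2(n_mer)
        t_el = n_el / production
        r_el = math.log(l_mat / l_div) / t_el
        rows.append(
            {
                "plant_id": pid,
                "ler_mm_h": scn.ler_mm_h,
                "meristem_length_mm": mer_um / UM_PER_MM,
                "elongation_zone_length_mm": x_gz * MM_PER_CM - mer_um / UM_PER_MM,
                "growth_zone_length_mm": x_gz * MM_PER_CM,
                "cell_length_leaving_meristem_um": l_div,
                "mature_cell_length_um": l_mat,
                "cells_in_meristem": n_mer,
                "cells_in_elongation_zone": n_el,
                "cells_in_growth_zone": n_mer + n_el,
                "cell_production_rate_cells_h": production,
                "cell_division_rate_cells_cell_h": division,
                "relative_elongation_rate_um_um_h": r_el,
                "cell_cycle_duration_h": t_c,
                "time_in_meristem_h": t_mer,
                "time_in_elongation_zone_h": t_el,
            }
        )
    return pd.DataFrame(rows, columns=["plant_id", *RESULT_COLUMNS])


def write_scenario_files(scn: SimScenario, out_dir) -> dict[str, Path]:
    """Write the three input tables plus the ground truth to ``out_dir``.

    Returns the paths keyed by role.  Output is deterministic: identical
    (scenario, seed) give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "leaf_lengths": out_dir / "leaf_lengths.txt",
        "cell_lengths": out_dir / "cell_lengths.txt",
        "meristem_sizes": out_dir / "meristem_sizes.txt",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    write_leaf_lengths(simulate_leaf_lengths(scn), paths["leaf_lengths"])
    write_cell_lengths(simulate_cell_lengths(scn), paths["cell_lengths"])
    write_meristem_sizes(simulate_meristem(scn), paths["meristem_sizes"])
    ground_truth(scn).to_csv(
        paths["ground_truth"], sep="\t", index=False, float_format="%.10g"
    )
    return paths
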