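# Methods

## Model and assumptions

The analysis treats a growing monocot leaf as a one-dimensional file of
cells in steady state: over the measurement window the leaf elongation
rate (LER) is approximately constant and the cell-length profile l(x)
along the growth zone is stationary.  Under these assumptions the flux of
cells out of the growth zone equals the production of new cells in the
meristem, which yields the classical chain of kinematic equations
implemented in `phytokin.kinematics`:

* cell number between positions a and b (cm): N(a,b) = ∫ₐᵇ dx / l(x),
  because 1/l is the linear cell density (l in µm; the factor 10⁴ µm/cm
  makes N dimensionless);
* growth-zone end x_gz: the first position where l reaches
  `mature_fraction` (default 0.95) of the profile maximum; the mature
  cell length l_mat is the mean of the fitted profile beyond x_gz;
* production rate P = LER / l_mat (cells h⁻¹), division rate
  D = P / N_mer (h⁻¹), cell cycle T_c = ln2 / D;
* residence times: T_mer = T_c · log₂(N_mer) — the steady-state result
  that a cell crosses a meristem of N cells in log₂ N doublings — and
  T_el = N_el / P;
* mean relative elongation rate R_el = ln(l_mat / l_div) / T_el, with
  l_div = l(L_mer) the cell length at the meristem exit (linear
  interpolation on the profile grid).

The meristem length is a measured input (from nuclear staining), never
inferred from the profile.  Six algebraic identities
(L_gz = L_mer + L_el, N_gz = N_mer + N_el, P = D·N_mer, T_c·D = ln 2,
T_el·P = N_el, R_el·T_el = ln(l_mat/l_div)) hold for every output row by
construction and are verified to 1e-9 relative in the acceptance suite.

## Leaf elongation rates

Every consecutive pair of non-missing measurements defines one interval;
LER over an interval is ΔL/Δt with Δt computed at exact minute
resolution.  A missing interior measurement merges its two bracketing
intervals, so the merged rate is automatically the duration-weighted mean
of the rates it replaces — the property test asserts this algebra on
random series.  The per-plant mean uses the first `n_LER_for_mean`
(default 2) intervals, counting from the first non-missing measurement;
plants with fewer intervals contribute what they have.

The default mean is the plain arithmetic mean of interval rates, which is
what the per-interval presentation of the output tables implies.  When
intervals are unequal this differs from total growth over total time; a
`time_weighted` switch selects that alternative.  Negative rates are
computed as-is and flagged (`[NEGATIVE_LER]`) since shrinking length
readings indicate data errors.

## Cell-length profile fitting

Scattered cell lengths are smoothed by local-linear regression with a
Gaussian kernel, evaluated on a regular grid starting at the leaf base
(x = 0) with spacing `interval_in_cm` (default 0.1 cm) up to the largest
measured position rounded down to the grid.  Grid points outside the
measured position range are extrapolations of the local fit and carry a
flag.  The fit uses centred weighted moments, which keeps it stable when
kernel weights span hundreds of orders of magnitude; where the effective
window contains a single distinct position (weighted position variance
below 1e-25 cm²) the estimate degrades to the kernel-weighted mean, and
where it contains no data at all the value is missing.

The per-plant bandwidth comes from the Ruppert–Sheather–Wand direct
plug-in selector for local-linear regression (`phytokin._kernsmooth`):
linear binning onto a 401-point grid, a blocked quartic pilot with the
block count chosen by Mallows' Cp, a local-cubic stage for the curvature
functional θ₂₂, a binned local-linear stage for the residual variance,
and finally h = (σ̂²(b−a) / (2√π θ̂₂₂ n))^{1/5}.  The implementation
follows the reference R realisation of this algorithm closely enough that
one test checks agreement to five significant digits through `Rscript`.
Two practical notes:

* the *finite-sample* scaling of h with n is slightly shallower than the
  asymptotic n^{−1/5} (the acceptance script measures a log-log slope of
  about −0.18 on the simulator's default noise level over
  n = 100…3200), because the pilot estimates themselves drift with n;
* smoothing bias does not vanish on noiseless data: the blocked pilot
  reads lack-of-fit of curved profiles as residual variance, so the
  selector keeps a finite bandwidth.  This bias dominates the small
  residual recovery error in the noiseless acceptance measurement.

Selection fails (returns nothing rather than raising) on degenerate
input — fewer than five distinct positions, zero spread, singular pilot
fits.  Such plants are fitted at `alternative_bw` (default 0.5 cm), which
is a user-chosen *final* bandwidth: the `bw_multiplier` (default 1) is
deliberately not applied to it, since it replaces the computed value that
the multiplier is meant to scale.  A `mean_bandwidth` helper over the
bandwidth table provides the recommended choice for the alternative.
Multiplier semantics: values below 1 give a stricter fit, above 1 a
smoother one; the selected h scales exactly linearly with the
multiplier.

Total variation of the fitted curve decreases with h throughout the
operational range (roughly 0.3×–3× the plug-in choice, the range the
diagnostic multiplier comparison covers), but not asymptotically: as
h → ∞ the fit tends to the global least-squares line, whose end-to-end
variation can exceed the rise of a sigmoidal profile.  The property test
is therefore scoped to the operational range.

The profile's first derivative is computed by central finite differences
of the fitted grid values (one-sided at the ends); the grid is dense
enough (1 mm) that this is stable and directly testable.  A local
quadratic derivative estimate is available through
`derivative_method="local_quadratic"`.

## Cell-count integration

N(a,b) integrates 1/l over the profile grid by the trapezoid rule
(midpoint available), with l linearly interpolated at off-grid endpoints.
On the 1 mm default grid the two rules agree to well under 0.1% for
smooth profiles, and the grid quadrature agrees with exact analytic
integrals to the same order.  A deliberate nuance: for an idealised
*discontinuous* step profile the trapezoid rule on grid values spreads
the jump over one grid cell, so the gridded N_el differs from the exact
integral of the right-open step (130 vs 150 cells in the package's
worked example).  The analytic ground-truth path in
`phytokin.synthetic.ground_truth` integrates piecewise exactly and is
the reference for that idealised case; real fitted profiles are
continuous and unaffected.

Division statistics are reported missing (with a `[DEGENERATE_DIVISION]`
warning) when N_mer < 1 or P ≤ 0 rather than emitting infinities;
meristems extending past the growth-zone end, absent LER or meristem
entries, and profiles already mature at the base are per-plant errors
that do not abort the remaining plants.

## The simulator and its ground truth

`SimScenario` fixes a true profile l*(x) — logistic by default, rising
from `l_init_um` through `l_div_um` at the meristem boundary to an
`l_mat_um` plateau positioned so that 95% of the asymptote is reached at
`x_gz_cm`; piecewise-exponential and idealised step shapes are
available — plus a true LER, meristem length, sampling design and noise
levels.  Defaults describe a typical maize experiment: 7 plants, LER
3 mm h⁻¹, a 1 cm meristem of ~20 µm cells, 130 µm mature cells, growth
zone ending near 6 cm, cell lengths sampled every 1 mm over the basal
10 cm with 3 cells per position and 5 µm additive Gaussian noise
(floored at 1 µm), four daily leaf measurements with 1 mm noise.
Everything is deterministic per (scenario, seed); identical seeds give
byte-identical files.

`ground_truth` evaluates the same kinematic rules on the analytic
noiseless profile with exact piecewise or high-accuracy adaptive
integration — an independent code path from the gridded pipeline, used
as the oracle in parameter-recovery tests.

What the simulator does *not* emulate: non-steady growth (time-varying
LER or profiles), biological between-plant profile variability beyond
meristem-length jitter, position-dependent measurement error,
cell-length autocorrelation along files, or dissection artefacts near
the leaf base.  Passing recovery tests therefore demonstrate the
correctness and numerical behaviour of the estimation chain under the
stated noise model, not robustness to every failure mode of real
microscopy data.

## Input handling choices

Tab-delimited UTF-8 (BOM tolerated); header names and units are enforced
exactly, since silent unit mix-ups are the main practical failure mode.
Empty cells and `NA`/`na`/`NaN` tokens are missing values; decimal commas
raise a targeted error (locale-configured spreadsheet exports); extra
columns are rejected unless explicitly ignored.  Timestamps are
timezone-naive local times in `yyyy/mm/dd hh:mm[:ss]`; column order never
matters (chronological sorting is internal).  Written tables carry 6
significant digits, which exceeds measurement precision while keeping
diffs stable.

## Known limitations

* Steady-state only: organs without a stable growth zone (or without a
  division zone at all, e.g. hypocotyls) violate the model; the LER and
  profile-fitting stages remain usable descriptively, the kinematic
  stage does not.
* The profile represents one cell file (epidermal practice); whole-organ
  inferences inherit that choice.
* The growth-zone-end criterion (95% of maximum) is a convention; it is
  configurable (`mature_fraction`) and recorded in the output metadata,
  and results near a flat profile maximum are sensitive to it.
* Bandwidth selection assumes enough distinct sampling positions (≥ 5);
  sparse dissections fall back to the user's alternative bandwidth.
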