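# Methods

This note documents the model, the estimation procedure, the synthetic
data-generating process, and the numerical and design choices behind
`settleflow`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The gravity model and what identifies it

Migration flows between settlements are modelled with an unconstrained
(total-constrained) spatial interaction model

    F_ij = k · P_i · P_j^γ · f(d_ij),   i ≠ j,

where `P_i` is the origin population at the start of the interval, `P_j^γ`
is destination attractiveness (population raised to a scaling exponent
γ > 0), and `f` is the distance decay: inverse power `d^(−β)`
(β dimensionless) or exponential `exp(−β d)` (β per km).  β is
family-specific and not comparable across families.  Self-flows are
structurally excluded — the diagonal of every flow matrix is absent — which
also avoids the `d = 0` singularity of the power kernel.

Census data observe stocks, not moves, so the model is confronted with the
*growth-adjusted census change*.  A single national growth factor
`g = ΣP(end)/ΣP(start)` absorbs natural increase uniformly; the
net-migration target of settlement *i* is `ΔM_i = P_i(end) − g·P_i(start)`,
which sums to zero by construction.  This is the simplest construction that
separates migration from natural demographic change; it assumes birth and
death rates do not vary across settlements, which is wrong in detail (ageing
rural populations have higher death rates) but keeps the target identifiable
from two census waves alone.

### The scale constant k

Only the *pattern* of `ΔM` is informative about (γ, β, family); the scale
constant k is a nuisance parameter.  Two identification rules are
implemented:

* **`volume="profile"` (default).**  For each grid point let
  `u = net(W)/ΣW` be net migration per unit of gross flow volume, where
  `W_ij = P_i P_j^γ f(d_ij)`.  The gross volume is the least-squares
  solution `t = max(0, ⟨u, ΔM⟩/⟨u, u⟩)` and `k = t/ΣW`.  Profiling the
  scale out is what makes the exact-recovery oracle exact: on a noise-free
  gravity world the net pattern at the true grid point is exactly
  proportional to `ΔM`, so the fitted residual is zero there and positive
  elsewhere.
* **`volume="net_target"`.**  Fixes the gross volume to
  `T = Σ max(0, ΔM_i)`, the minimal volume consistent with the net targets.
  This is the transparent, closed-form choice, but it systematically
  understates gross migration (reciprocal flows cancel in net terms), and
  because raising γ inflates net asymmetry at fixed gross volume, it biases
  calibration toward larger γ.  It is retained as an option and used where a
  fixed, interpretable volume is wanted (e.g. the `predict` command).

`normalise_k` itself always enforces `Σ F̂ = T` exactly given a volume, and
predicted flows conserve that total to 1e-9 relative (numpy's pairwise
summation is relied on for this; no additional compensated summation proved
necessary at n ≤ 10⁴).

## Calibration

Calibration is an exhaustive, deterministic grid search per intercensal
interval: γ from 1.2 to 1.9 in steps of 0.1, β from 0.5 to 3.0 in steps of
0.25, both decay families — 8 × 11 × 2 = 176 configurations.  The β step is
a package choice (the range endpoints are the conventional ones; 0.25
resolves optima near 0.5 and 1.0 while keeping the grid small).  Each
configuration is scored by projecting end populations
(`P̂(end) = g·P(start) + net̂`, clamped at zero with a diagnostic count) and
comparing with the observed census: SRMSE is the selection objective, with
MAE and MAPE reported alongside.  SRMSE is chosen as the selector because it
is the scale-free member of the trio and comparable across intervals with
different total populations.  Ties break toward smaller β, then smaller γ,
then the power family; rows with non-finite metrics are flagged and excluded
from selection with a warning.  Exhaustive evaluation is preferred to
numerical optimisation: the grid is tiny (one search takes well under a
second at n = 200) and the surface need not be unimodal.

## Fit statistics and the regional benchmark

* `MAE = mean |obs − pred|` — same units as the data.
* `MAPE = 100 · mean |obs − pred|/obs` over entries with `obs ≠ 0`; the
  excluded zero-observed count is reported rather than raising, because MAPE
  is unstable for very small observed values.
* `SRMSE = rmse/mean(obs)` — dimensionless; requires positive mean.

Both flow matrices and population vectors are legal entry sets; the set
actually scored is recorded in the `FitMetrics` result so no silent choice
is made.

For regional validation, settlement flows are summed to a region × region
matrix (the diagonal holds intra-region moves between distinct settlements;
total flow is conserved exactly for integer flows) and compared with an
external benchmark through the cellwise relative difference
`RD_ab = (R̂_ab − R_ab)/R_ab`, positive meaning overestimation.  Cells with
zero observed flow are *undefined* by default and rendered as an en dash;
an opt-in ε mode computes `R̂/ε` instead (ε defaults to 1e-9).  The marker
default is used because the authoritative printed panels mark such cells
rather than inflating them.  Display rounds to 2 decimals; stored values
keep full precision.

The bundled seven-region Bulgarian benchmark ships with the marginals as
printed in its sources.  Those printed totals disagree with the sums of the
printed cells by up to ±2 (rounding in the source); the package recomputes
marginals from cells and the tests accept the printed totals within that
discrepancy.  The relative-difference panel reproduces the published one to
two decimals either way.

## Distances

Euclidean distances are planar norms for kilometre coordinates and
haversine great circles (Earth radius 6371 km) for lon/lat input; the
convention travels with every table and matrix.  Network distances snap each
settlement to its single nearest road node by a straight connector (zero if
coincident) and take Dijkstra shortest paths over the edge weights; two
settlements snapped to the same node are separated by the sum of their
connectors.  Parallel edges collapse to their shortest representative.
Unreachable pairs raise an error listing the components involved — a
sentinel "large distance" would silently distort decay calibration.  When
every edge weight dominates the straight-line separation of its endpoints
and connectors are straight lines, network ≥ Euclidean holds for every pair
by the triangle inequality; this is asserted on synthetic worlds.

## Terrain

TRI follows Riley's formulation: per cell, the square root of the summed
squared elevation differences to the eight neighbours, in metres.  Border
cells and cells with any missing neighbour yield nodata rather than a
partial sum — partial neighbourhoods would bias TRI low.  TRI is invariant
under elevation translation and scales linearly with elevation scaling;
both properties are tested, along with equivalence to a naive double-loop
implementation.

Settlement-level ruggedness is the mean of valid TRI cells whose centres
fall within a circular buffer (default radius 2 km, configurable) — a
stand-in for cadastral settlement polygons, which are not modelled.  An
empty buffer falls back to the nearest valid cell with a logged note.
Settlements are classified into k = 5 quantile groups by ascending rank
with ties broken by settlement id (determinism matters for tests); the
group of rank r among n is `ceil(k·r/n)`, so group sizes differ by at most
one for distinct values and group 5 is the most rugged.

DEM I/O is the ESRI ASCII grid format, with header coordinates and cell
size expressed in the kilometre frame of the settlement tables and cell
values in metres.

## The synthetic data generator

The generator emulates a national settlement system at experiment scale.
Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| n_settlements | 200 | large enough for stable calibration, small enough for sub-second searches |
| bbox | 500 × 350 km | extent of a mid-size country |
| rank-size exponent s | 1.0 | classical Zipf slope |
| top_population | 100 000 | primate city; smallest settlement ≈ 500 |
| n_regions | 7 | matches the macro-regional benchmark structure |
| clusters | 5, sd 25 km, 50% of settlements | lowland agglomeration around centres |
| DEM | 140 × 200 cells of 2.5 km, 3 ridges of 1200 m | ridge structure at national scale |
| road detour | lognormal(0.18, 0.08), clipped ≥ 1 | mean elongation ≈ 1.2 over the straight line |
| truth (family, β, γ) | power, 1.0, 1.5 | on-grid, mid-range |
| mobility m | 0.05 | ~5% of the population migrates per interval |
| growth g | 1.05 | mild national natural increase |

Populations are deterministic rank-size values `round(top · r^(−s))` with
ranks shuffled over locations — deterministic so examples are analytically
checkable.  Roads are Delaunay edges weighted by detour × Euclidean length
(degenerate point sets fall back to a chain; disconnected graphs are bridged
with shortest edges), so network distances dominate Euclidean by
construction.  Flows are Poisson draws around the gravity expectation with
the scale set so the expected gross volume is `T = m·ΣP(start)`; with
`poisson=False` the expectation is used directly and end populations stay
real-valued, which is what makes the exact-recovery oracle exact.  End
populations are `round(g·P) + inflow − outflow` (unrounded in noiseless
mode), clamped at zero with a diagnostic count; clamping beyond 1% of
settlements warns, and `strict_clamp` turns it into an error.  One master
seed is split into named substreams (settlements / dem / roads / flows) so
regenerating one layer never perturbs the others.

**Feasibility caveat.**  The unconstrained gravity expectation can drain a
small settlement next to a large attractor below zero; the simulator then
clamps and the world is no longer an exact realisation of the model.  The
exact-recovery property therefore holds for *feasible* (clamp-free)
noiseless worlds, and the corresponding test asserts that premise
explicitly.  Under Poisson noise, recovery within one grid step of the
truth is a statistical property, verified over 20 fixed seeds with a ≥ 90%
success criterion at gross volumes ≥ 10⁴.

What the generator does **not** emulate: real geography or road topology,
spatially varying natural increase, age structure, international migration,
multi-interval coupling (each interval is independent), or flow saturation
in small settlements.  Passing tests demonstrate the correctness of the
machinery and the recoverability of parameters under the stated generative
assumptions — not that the gravity model is an adequate description of any
particular historical system.

## Reporting conventions

* Flow-network export keeps edges strictly above the threshold (default
  > 1 migrant, applied to real-valued predictions without prior rounding);
  node inflow/outflow/net come from the unthresholded matrix so conserved
  quantities survive filtering.
* Histograms use base-10 log bins of width 0.25 dex starting at the
  smallest positive value, with zeros (and negatives, for net) tallied
  separately; linear histograms use 20 equal-width bins.  Skewness is the
  adjusted Fisher–Pearson sample coefficient, defined as 0 for constant
  samples.
* Box statistics per TRI group use linear interpolation between order
  statistics, with 5th/95th-percentile whiskers; net migration is in
  absolute counts by default with a per-capita option (small mountain
  settlements experience large proportional change at small absolute flows).
* Top destinations from the most rugged quantile sum all flows whose origin
  is in group 5 by destination; rugged destinations remain eligible; ties
  break by destination id.

## Known limitations

* The observed-flow construction (growth-adjusted census change) is a
  modelling decision, not an observed quantity; gross volumes are
  identified only up to the profile fit.
* Distance is the only travel cost; no travel time, one-way restrictions,
  or historical network change.
* The uniform growth factor ignores spatial variation in natural increase,
  which loads rural–urban vital-rate differences onto the migration
  estimates.
* MAPE is reported but unstable for near-empty settlements; rely on SRMSE
  for cross-interval comparison.
* Regional benchmarks partially derived from the same census material as
  the calibration targets introduce a degree of circularity that no metric
  here can detect.
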