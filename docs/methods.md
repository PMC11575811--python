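# Methods

## Problem

Daily pollen-concentration records (pollen grains per m³ of air, one value
per calendar day, station and taxon) are routinely incomplete: Hirst-type
volumetric samplers are read manually, and malfunction or maintenance
produces runs of consecutive missing days.  `pollengap` implements two
imputation methods for such series and the simulation machinery to compare
them under controlled missingness: fixed-length gap runs removed at target
proportions from a complete reference year, scored by RMSE, and analysed
with a log-linear error model.

## Imputation methods

### Moving mean

A univariate interpolation: for a missing run of length *L*, each missing
day *i* is filled with the mean of the *observed* values inside the
symmetric window `[i − h, i + h]` with half-width `h = ⌈w·L⌉` (default
window factor `w = 1`, i.e. a 2L+1-day window spanning twice the gap length
around each missing day; the factor is configurable because "a symmetrical
interval twice the gap length" admits more than one reading).  Windows are
truncated at the series edges; if a window contains no observed day, its
half-width doubles until it does.  Previously imputed values are never
reused as inputs, so the result does not depend on the fill order.
Consequences: every imputed value lies within the range of the observed
values in its window, and an isolated missing day gets the mean of its two
neighbours.

### Gappy SVD (iterative truncated-SVD completion)

A multivariate, data-driven method.  Aligned series — historical yearly
columns plus the gappy replicate columns of a scenario — are stacked into a
day × series matrix X.  Missing entries receive an initial guess (the
column mean of observed values, or linear interpolation along the day axis
with flat edge extension).  Then, iteratively:

1. decompose `X = U Σ Vᵀ` (full SVD);
2. truncate to the leading *N* modes: `X* = U* Σ* V*ᵀ`;
3. overwrite the *missing* entries of X with the corresponding entries of
   `X*`; observed entries are never altered;
4. stop when the mean squared change of the imputed entries between
   successive iterations falls below the tolerance (default `1e-6`,
   an absolute quantity in (p/m³)²; a relative variant —
   normalised by the mean square of the previous iterate — is available
   and makes the stopping rule scale-invariant), or at `max_iter`
   (default 1000), in which case the result is returned flagged
   `converged = False` rather than raising.

The convergence metric is the mean *squared* change: the stopping quantity
is a mean square error over the gap entries between consecutive iterates.
After the loop, imputed concentrations are clipped at zero — a physical
constraint of concentration data; clipping happens once, outside the
iteration, so it does not interfere with the fixed-point structure.

The leading modes capture the dominant seasonal structure shared across
columns; the discarded tail carries noise and the arbitrariness of the
initial fill.  Two configurations are evaluated by default, 5 modes with
mean initialisation (`gsvd-mean-5m`) and 10 modes with linear-interpolation
initialisation (`gsvd-interp-10m`).

Numerical notes.  The iteration is the classical hard-impute scheme and is
*initialisation-dependent*: on smooth, seasonally coherent columns both
initialisations converge to the same completion, but on unstructured
(randomly generated) matrices linear interpolation along the day axis can
be a poor enough starting point that the iteration stalls or drifts; the
test suite exercises exact low-rank recovery with mean initialisation for
that reason.  `n_modes` must not exceed `min(rows, cols)`; a fully masked
column is rejected (no information to complete from).

## Season definition and variability

The pollen season of a calendar year is the cumulative-percentage window:
it starts on the first day the running annual sum reaches 2.5% of the
annual total and ends on the first day it reaches 97.5% (inclusive `≥`
thresholds; at 100% coverage the window spans the first to last nonzero
day).  The study's fixed imputation window per taxon extends the earliest
season start across stations back to the first of its month and the latest
end forward to its month's last day, so all stations of a taxon share one
rectangular day axis; Feb 29 is dropped when stacking years of different
leap status.

The Variation Index (VIn) quantifies day-to-day variability: for every
pair of consecutive days with both values present, the two-day moving CV
is the sample SD of the pair (|a−b|/√2, the n−1 convention, matching the
default `sd` of common statistics environments) divided by the pair mean;
VIn is the average of these CVs over the season, in percent.  Pairs with a
missing member or zero mean (CV undefined) are excluded.  VIn is invariant
under positive rescaling of the series.

## Gap simulation

A scenario is (window length *n*, missing proportion *p*, gap length *L*).
The number of runs is `k = max(1, round(p·n / L))` with half-away-from-zero
rounding — the rule that reproduces all 24 cells of the canonical scenario table for
the 151- and 214-day windows; no exact .5 tie occurs there, so the tie rule is
a free choice (half-even is available).  The realized missing percentage
`kL/n` therefore deviates from nominal by up to about half a gap length,
more when the floor-at-1 rule binds.

Masks are drawn uniformly over all valid placements via the stars-and-bars
bijection (sample a sorted k-subset, convert to run start offsets), which
needs no rejection loop and provably reaches every feasible configuration.
By default runs may not touch (at least one observed day between runs), a
slightly stronger condition than non-overlap: it guarantees every realized
missing run has length exactly *L*, so the gap-length factor of the design
is never contaminated by merged runs.  Adjacency can be allowed
(`forbid_adjacent=False`).

Seeding: one master seed per study; every (taxon, station, proportion,
gap length, replicate) cell derives its placement seed deterministically
from the master seed and those keys (CRC-based entropy into a
`SeedSequence`), so runs are reproducible and replicates independent.

## Evaluation

RMSE between the completed and the true series is computed over *all* days
of the imputation window (observed days contribute zero error), following
the "total number of observations" denominator; a gap-days-only variant is
available via the `mask` argument since the definition admits both
readings.  Per-cell medians over replicates summarise each scenario, and
the per-unit VIn joins the median table for variability stratification.

The error model is an OLS of log(RMSE) per (taxon, station) stratum on
indicator-coded method, missing proportion and gap length (references:
moving mean, the smallest proportion, the shortest gap; factors are
unordered categories, not linear terms).  Standard errors are
heteroskedasticity-consistent (HC1 default, HC3 available).  Exponentiated
coefficients Exp(β) are ratios of geometric-mean RMSE versus the reference
level — exactly so in a balanced design, which the test suite verifies
against directly computed geometric means.  Zero RMSE values are rejected
(log undefined), as are designs with a missing reference level or a
rank-deficient design matrix.

## Synthetic data generator

Daily values are `amplitude_year × kernel(day-of-year) × exp(ε_day)`:

- **kernel** — a Gaussian bell in day-of-year, scaled to sum to the annual
  load in the noise-free limit (unimodal, the qualitative shape of single
  pollen seasons; skewed or multimodal curves are out of scope);
- **amplitude** — a mean-one lognormal draw per year with CV
  `year_amplitude_cv` (default 30%), emulating year-to-year load variation;
- **ε** — a stationary AR(1) Gaussian sequence (coefficient `autocorr`,
  marginal SD `noise_sigma`) carried across year boundaries, giving
  positively autocorrelated, heavy-tailed multiplicative noise — the only
  way to reach the very high day-level CVs of real pollen counts with
  strictly nonnegative values.

The default study fixture is 2 stations × 2 taxa × 5 years, complete, with
the last year as simulation target:

| unit | peak day | spread (d) | load (p·d/m³) | noise σ | autocorr |
|------|----------|-----------|---------------|---------|----------|
| alder-like, alpine | 83 | 18 | 1 800 | 1.4 | 0.5 |
| alder-like, lowland | 75 | 18 | 7 500 | 1.6 | 0.5 |
| grass-like, alpine | 178 | 40 | 2 200 | 0.9 | 0.9 |
| grass-like, lowland | 170 | 40 | 7 000 | 0.9 | 0.9 |

These settings realise the intended contrast: the alder-like regime has a
median 95% season of ≈ 65–70 days, day-level CV ≈ 170–210% and VIn ≈ 60–70%;
the grass-like regime ≈ 150 days, CV ≈ 95–100% and VIn ≈ 22%.  The
grass-like CV falls short of the ≈ 150% seen in real long-season records:
a Gaussian bell over its own 95% window cannot produce the spikiness of
real grass curves without inflating VIn or the season-length spread.  The
regime *ordering* — duration, CV and VIn all separating the two taxa — is
what the study's variability analysis relies on, and it is robust across
seeds.  What the generator does not emulate: discreteness of counted
concentrations (values are continuous and strictly positive), skewed
season shapes, meteorology-driven excursions, and spatial correlation
between stations.  Passing tests on this fixture therefore demonstrate
correctness of the machinery and direction of the effects, not absolute
error levels of real monitoring data.

## Study orchestration and its one structural caveat

`run_study` mirrors the full factorial design: 3 proportions × 4 gap
lengths × 2 taxa × 2 stations = 48 cells, 100 replicates each (4 800 gappy
series), three methods (14 400 evaluation records).  Moving mean is applied
per replicate; gappy SVD once per cell and configuration on the matrix of
historical yearly columns (the complete target-year column included by
default, `include_reference_year=False` to exclude it) plus all 100
replicate columns.

Pooling all replicates into one matrix has a consequence worth stating
plainly: each day removed in one replicate is still observed in most other
replicate columns, so the low-rank completion can recover gap values
almost exactly, and GSVD RMSEs in this design are orders of magnitude
below moving-mean RMSEs — a property of the evaluation design (mutual
information between replicate columns), not evidence about single-series
imputation accuracy.  Excluding the reference year does not change this;
imputing each replicate in its own matrix would, but is a different design
than the one implemented here.  The study's conclusions are therefore read
from the *directional* patterns, which are design-robust: error grows with
the missing proportion at fixed gap length for every method, and the
high-VIn regime is harder to impute than the smooth one within each
station.

Problem sizes were chosen to keep a full study (two of them, for the
determinism check) plus the property suites comfortably within a desk-scale
run: the full study takes under a minute per run on one CPU, dominated by
the 96 iterative SVD completions on ≈ 90–180 × 105 matrices.  With the
absolute 1e-6 tolerance on p/m³-scaled data a minority of cells reach the
1000-iteration cap and are flagged unconverged in the run log (per-cell
iterations, final delta, converged flag); their completions are still
well-behaved, and the relative-tolerance option exists for scale-free
stopping.

## Determinism

Everything downstream of the master seed is deterministic: the synthetic
fixture (seeded per station/taxon), the per-cell placement seeds, the SVD
iterations, and the record order.  Two runs under the same seeds produce
byte-identical records files.
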