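# Methods

`ar_overshoot` implements two connected pieces of machinery: (1) construction
of an ambitious, constrained afforestation/reforestation (AR) land-use
scenario from an ensemble of integrated-assessment land-area trajectories plus
restoration-potential and human-influence maps, and (2) probabilistic
diagnostics of temperature-overshoot dynamics and carbon-cycle efficiency on
small ensembles of Earth-system-model-like output. A seeded synthetic-world
module supplies every input, so the full pipeline runs on a laptop in seconds.

## Scenario construction

**Targets.** For every scenario in the database, the forest-area change per
5-year step is computed scenario-wise; the changes of all scenarios are pooled
per step and a high percentile (default the 90th) of the pooled changes is the
AR target — an ambition level in the range of total country pledges rather
than any single scenario's path. The percentile estimator is the
linear-interpolation quantile; negative pooled percentiles are floored at zero
(the scenario adds forest only, and the reference comparator holds land use
constant). Regional targets are extracted the same way from the regional
records, then rescaled each step so their sum equals the global target while
preserving relative magnitudes. The 5-year cumulative series are annualized
with shape-preserving piecewise-cubic Hermite (PCHIP) interpolation, so knots
are honoured exactly and monotone inputs yield non-negative annual increments.

**Allocation.** Each region-year target is distributed over gridcells by an
iterative constrained algorithm. A cell is eligible when (a) convertible
grazing land remains, (b) the tier's restoration potential remains (see
below), (c) its forest cover has risen by less than the yearly cap, and
(d) at least the minimum forest cover (default 20% of cell area) has
historically been held or could potentially be sustained,
`max(f_1850, f_potential) >= 0.20`. The remaining target is split in equal
Mha over currently eligible cells ("uniform application"), each application
capped by the cell's binding constraint, and the residual carried to the next
iteration. Because each pass either meets the target exactly or saturates at
least one cell, the procedure converges to the water-filling solution
`alloc_i = min(capacity_i, lambda)`; tests verify exact agreement with an
independent bisection oracle on all small instances.

Three tiers are tried in order: cells with remaining GRS restoration
potential, then remaining ATL potential (GRS is a subset of ATL, so any
conversion decrements both, preventing double counting of the same restorable
land), then any cell passing (a), (c), (d). Within a tier, sources open
progressively region-wide: heavily managed pasture first, then rangeland
biodiversity groups 1 (least biodiverse) through 4. Rangeland in Very Low
Human Influence cells is treated as close to pristine and excluded outright;
remaining rangeland is grouped by the Low Human Influence agreement count
(0 is folded into group 1, since groups are defined for counts 1–4). Natural
grassy biomes and cropland are never converted. Interpretation choices that
the source material leaves open, fixed here: the yearly cap (c) is 10
percentage points of *cell area* (resolution-stable), not 10% of existing
forest; and the pasture-before-rangeland / ascending-biodiversity ordering is
enforced region-wide per source stage, which also implies the per-cell
ordering.

Bookkeeping tracks, per year and region: Mha converted per tier, per source
(pasture, rangeland group), the reforestation/afforestation split (gain up to
the 1850 forest area counts as reforestation), and any shortfall when a
target is infeasible — infeasibility is logged, never raised. Conservation
(forest gain = pasture loss + rangeland loss, per cell and year) holds to
1e-6 Mha by construction and is asserted in tests. Sensitivity
configurations reproduce the study variants: restoration maps without
biodiversity maps, GRS + biodiversity only, and no maps at all.

**Overlays.** `overlay_indicator` reports the percent and Mha of final-year
AR falling on cells where a socioeconomic indicator crosses a threshold
(indigenous-land extent, poverty, population density, governance, tenure
insecurity — all synthetic stand-ins here). The composite governance
indicator is the arithmetic mean of six components, with missing country
values filled by subregion means.

## Overshoot diagnostics

**Signal emergence (OVL).** The overlapping coefficient
`OVL = ∫ min(f1, f2) dx` measures similarity of two distributions (1 =
identical, 0 = disjoint). Densities are Gaussian KDEs with per-sample
Silverman bandwidths (`0.9 min(sd, IQR/1.349) n^(-1/5)`), floored at 1e-6 of
the pooled sd for degenerate samples, integrated by trapezoid on a grid
spanning five bandwidths beyond the combined sample range. The scalar `ovl`
uses a 2048-point grid; bootstrap and null-simulation paths use 512 points
(integration error < 1e-4 in every checked case) and express bootstrap
resampling as multinomial weights against a kernel matrix with the bandwidth
frozen at the original sample's value, which turns each resample into one
matrix product.

Member-years of the two ensembles are pooled over a sliding window (lengths
5–10), the mean OVL over bootstrap resamples is compared with an
AR(1)-surrogate null threshold: pairs of same-process ensembles are simulated
from an AR(1)-around-linear-trend model fitted to the reference ensemble, and
the alpha-quantile (default 5%) of their OVLs is the threshold. Two
calibration-critical choices: the null pairs are summarized with the *same*
bootstrap-mean statistic as the data (bootstrap resampling biases OVL low;
mixing a raw-OVL null with a bootstrap-mean data statistic produced ~10%
null emergence at nominal 5%); and emergence for a window length is labelled
by the *end* year of the first window from which the mean OVL stays below
the threshold through the record's end — the earliest year at which
detection is possible. With start-year labelling, a strong step change at
year Y is "detected" up to window-length−1 years before Y. The headline
emergence year is the mean ± sd over window lengths; when no window emerges
the result carries an explicit flag. The surrogate trend is the fitted
linear trend by default; detrending against the ensemble-mean trajectory is
available via `detrend="ensemble_mean"`.

**Peak and end-of-century statistics.** Per member, the hottest consecutive
5-year period is located; its values are pooled across members for the peak
mean and min–max, and the spread of member peak-period centre years gives
peak year ± sd (an across-member spread; a bootstrap spread would be an
alternative reading). The fixed end-of-century 5-year period is pooled
across member-years. Probabilities of staying within a warming level are
fractions of pooled member-year values at or below the threshold.

**Overshoot duration.** Per bootstrap draw, members are resampled with
replacement and averaged; the mean series is smoothed with a Savitzky-Golay
filter (polynomial order 3; window lengths 5–10 years, even lengths rounded
up to odd as the filter requires). Duration is the inclusive span from the
first to the last year at or above the threshold. Draws never exceeding the
threshold count as duration 0 and are flagged; draws still above it in the
final year are flagged right-censored. The estimate is the mean ± sd over
draws × window lengths. On the noiseless default trajectory (above 1.5 °C
from 2035 through 2099) the estimator returns 65 ± 0 years exactly; with
10 members and 0.1 °C AR(1) noise the recovery bias is under 3 years.

## Gridcell significance

The two-sample test per cell uses the lag-1-autocorrelation-adjusted
effective sample size `n_eff = n (1 − r1)/(1 + r1)` (r1 floored at 0) in a
Welch-form statistic: `n_eff` replaces `n` in both the standard error and
the Satterthwaite degrees of freedom. Two estimator details matter for
calibration and are therefore defaults rather than options left to the user:

- the sample r1 receives the first-order Marriott–Pope bias correction
  `r1 + (1 + 3 r1)/n`; without it the test ran at ~6.7% empirical size under
  an AR(1) null with phi = 0.5 and n = 40 (nominal 5%);
- in the gridded test, r1 is estimated from *full-record* residuals about
  the ensemble mean (averaged across members) and reused at every window
  position; an r1 estimated inside a 5-year pooling window is biased low far
  beyond first order and drove per-cell sizes above 10%.

With both in place the empirical type-I error at phi = 0.5, n = 40 is ~5%
(the acceptance script recomputes this), and the field-level null rate on a
100-cell grid with a 30-year window is ~5%. Short pooling windows are
slightly conservative (~2% field rate at a 5-year window), because the
asymptotic `n_eff` deflation overstates the variance inflation of short
means — the safe direction. The pure Welch reduction (no bias correction,
r1 floor at 0) is available via `bias_correct=False`.

Field significance controls the probability of at least one false positive
across the m tested cells via the Šidák level `1 − (1 − alpha)^(1/m)`
(Bonferroni available); a single rejection makes the field significant. The
sensitivity matrix scans pooling windows of 1–10 years crossed with a
requirement of 1–5 consecutive field-significant years, reporting the first
year opening each qualifying run.

## Carbon budgets and efficiencies

Pool deltas (atmosphere, land, ocean; GtCO2 relative to the baseline year)
are differenced between experiments and re-based so the baseline-year delta
is exactly zero. Units convert via the CO2:C molar mass ratio 44/12 and the
standard 2.124 PgC per ppm; printed-figure reproduction rounds half away
from zero. Efficiency metrics at a reference year: ocean offset
`−100 ΔC_ocean/ΔC_land`, net removal efficiency `−100 ΔC_atmo/ΔC_land`
(the two sum to 100% under mass conservation), °C per 100 GtCO2
land-sequestered or atmosphere-removed, °C and GtCO2 per 100 Mha, and mean
annual rates using the elapsed years of the record (85 for 2015–2100). The
sink-to-source transition year is the first year the Savitzky-Golay-smoothed
pool's year-on-year rate turns strictly negative and stays negative; a flat
stock is not a source.

## Synthetic world

The generators produce inputs with the statistical structure the analysis
assumes, not an emulation of any Earth-system model's physics:

- **Grid**: spherical cell areas (cosine-latitude weighting, Mha) on a
  regular lat-lon grid; spatially smooth cover fractions (Gaussian-filtered
  noise, periodic in longitude) rescaled to hit configured global totals
  exactly (defaults ~4 Gha forest, 0.8 Gha pasture, 2 Gha rangeland,
  1.55 Gha cropland); potential and pre-1850 forest fractions consistent
  with ~850 Mha of historical deforestation; GRS ⊂ ATL restoration
  potentials scaled to 400/800 Mha global totals so all three allocation
  tiers are exercised; VLHI mask, LHI agreement counts, and five contiguous
  longitude-band regions.
- **Scenario database**: forest increments per 5-year step drawn lognormally
  with a linearly declining percentile profile whose pooled 90th percentile
  cumulates to ~595 Mha by 2060 and ~935 Mha by 2100 (the pledge-range
  ambition level); pasture anti-correlated with forest, cropland stable.
- **Ensembles**: member = forced trajectory + AR(1) noise initialized from
  the stationary distribution (variance sigma²/(1−phi²)), so early years
  carry no spin-up artifact. The default forced trajectory is a
  shape-preserving Hermite rise–peak–decline through anchors placed half a
  year outside the intended crossing years, making the first/last years at
  or above the threshold exact ground truth. The demo pipeline uses
  phi = 0.5 and sigma = 0.08 °C (≈0.09 °C stationary spread, consistent
  with a ~0.4 °C member min–max range), REF overshoot 2035–2099 peaking at
  2.06 °C, AR 2036–2087 peaking at 1.98 °C. Gridded variants add a static
  smooth cell offset (shared between experiments via `offset_seed`), an
  optional deterministic cell signal, and independent per-cell AR(1) noise.
  The spatial covariance of real internal variability is *not* modelled;
  gridded results demonstrate the statistics, not any model's field.
- **Carbon pools**: cumulative emissions split by fixed airborne/land/ocean
  fractions; member noise added to land and subtracted from the atmosphere,
  and AR-driven extra land uptake drawn from atmosphere (74%) and foregone
  ocean uptake (26%), so the identity ΔC_atmo + ΔC_land + ΔC_ocean =
  cumulative emissions holds exactly every year. The emission pathway rises
  to 2040, reaches net zero around 2070 and −3.8 GtCO2/yr thereafter.

Passing tests on these inputs demonstrate the correctness and calibration of
the algorithms, not the Earth-system magnitudes of any real model: headline
numbers from coupled simulations (peak reduction, emergence year, overshoot
shortening) are *not* reproduced at desk scale, and the package makes no
claim about them beyond the arithmetic identities checked from printed
budget components.

## Numerical choices and limitations

- Allocation tolerances: targets met to 1e-6 Mha; a pass allocating below
  1e-9 Mha counts as stalled; iteration capped at 1e4 with a warning.
- Regions are processed in fixed alphabetical order; allocation is
  order-independent across regions since cells belong to exactly one region.
- The bootstrap-mean OVL freezes KDE bandwidths at the original sample's
  values across resamples; draw counts default to 1000 per operation, with
  the demo pipeline using 200 to keep end-to-end runs in seconds.
- `n_eff` uses the asymptotic AR(1) deflation; finite-window means have a
  smaller variance inflation, so short pooling windows test conservatively.
- Statistical-stage problem sizes in the demo (16×32 grid, 10 members, 200
  draws) are the package's choices for a desk-scale demonstration; every
  operation accepts larger values.
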