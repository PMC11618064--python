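# Methods

## Scope and data model

The package links a gridded daily exposure product to individual cohort
members in three steps: address-level extraction, per-subject series
assembly, and design-specific summarisation. It operates entirely in one
opaque planar coordinate system in metres (e.g. the British National Grid);
no reprojection is performed, and a coordinate-system mismatch is detected
only by comparing free-text CRS labels. Grid cells are referenced by their
**centroids**: cell (i, j) sits at (origin_x + i·Δx, origin_y + j·Δy), and a
point belongs to the cell whose centroid is within half a spacing in each
axis, with boundary ties resolved to the lower index so assignment is
deterministic. Missing cells (e.g. sea cells of a national grid) are carried
as an explicit boolean mask rather than sentinel values, which keeps every
missing-data policy explicit at the point of use.

All date intervals are closed on both ends. A residential period
[start, end] includes both days; abutting periods satisfy
next.start = previous.end + 1 day, so a move day belongs to the old address
and the following day to the new one. "Present" entries (ongoing follow-up
or residence) are parsed as OPEN and materialised at a caller-supplied
reference date while the OPEN flag is retained, so downstream code can
censor correctly.

## Step 1: spatial linkage

Bilinear interpolation is the default extraction method: with the four
bracketing centroids and fractional offsets fx, fy ∈ [0, 1], the weights are
(1−fx)(1−fy), fx(1−fy), (1−fx)fy, fx·fy. It is parameter-free, exact on
fields linear in each coordinate, computationally trivial, and produces a
continuous field whose values do not coincide with any published cell value
at non-centroid points — the privacy property that motivates preferring it
over nearest-cell assignment when the exposure product is public.
`privacy_diagnostic` measures exactly this: the fraction of days on which an
extracted value equals (bitwise float equality — the threat model is value
matching against a published grid) one of its four source-cell values.
Nearest-cell extraction scores 1.0 by construction; bilinear extraction at a
non-centroid point over a field with any continuous noise component scores 0
with probability 1.

Numerical choices:

- **Margins.** Points inside the half-cell band outside the centroid hull
  are clamped to the hull edge, so the interpolation degenerates to linear
  (edges) or single-centroid (corners) weights. Beyond the grid extent,
  strict mode raises and lenient mode returns an all-missing series; the
  pipeline uses lenient mode so that a single out-of-area address flags its
  days rather than aborting a cohort run.
- **Missing corners.** By default, weights are renormalised over the
  non-missing corners (unavoidable near coastlines); if the available
  corners carry zero total weight, or under the strict policy if any corner
  is missing, the day is missing. Weights always sum to 1 within 1e-12
  after renormalisation.
- **No temporal interpolation.** The product is already daily; missing days
  stay missing.
- Kriging and areal averaging are deliberately out of scope; inverse-
  distance weighting (power 2 by default, k-nearest or radius neighbourhood,
  exact pass-through at zero distance) is provided for monitor-based
  workflows.

## Step 2: series assembly

Each subject's series runs on a contiguous daily axis from the first to the
last covered day, even across gaps, and each day carries a provenance flag:
`ok`, `no_residence` (gap in the residential history), or
`exposure_unavailable` (residence predates or postdates the product's
coverage, or falls on a masked cell). The two non-ok flags are deliberately
distinct — a residence held from 2005 against a product that starts in 2008
is a different analytic situation from an unknown address — and both are
serialised. Gap days are never imputed. Residential histories are validated
under a lenient policy by default: overlapping self-reported periods are
repaired by truncating the earlier period at the later one's start − 1 day
(logged per repair; fully shadowed periods are dropped), because
self-reported histories are error-prone and a hard failure per overlap would
make large cohorts unusable. Strict mode raises instead. After validation,
every covered day maps to exactly one period (tested by exhaustive day
enumeration).

## Step 3: summaries

A lag window [min_lag, max_lag] reads the days index_date − lag backward
from an index date; lag 0 is the index day itself. No summary ever reads a
day after its own index date (tested by planting sentinel values after the
index). Each summary returns (value, completeness); the value is withheld
when completeness < min_completeness. The default min_completeness is 1.0
(only fully observed windows produce values); with a lower threshold the
aggregation runs over the available days. Sums over partial windows are
sums of available days — callers wanting an extrapolated sum should use the
mean and multiply.

**Risk sets** implement incidence-density sampling on either the age axis
(exact days, event_date − birth_date) or time-on-study. For each
first-occurrence case, eligible controls are subjects whose follow-up covers
the case's index time and who are event-free for the outcome up to the
calendar date at which they attain it; that member-specific date is the
control's index date, so each member's exposure is summarised backward from
a different calendar date. Day-exact age matching avoids caliper choices;
an optional ±day caliper is available for sparse cohorts. Eligibility is
outcome- and follow-up-based only: exposure-history completeness is reported
per member, not used as a filter (using it as one would select on exposure
observability). Controls may be sampled (seeded, without replacement) or
taken in full; both modes are deterministic. ICD-10 matching is
prefix-based ("C34" matches "C34.1"). Birth dates are an optional input:
the age axis requires them and fails loudly when absent rather than
inferring age from any other field.

**Case-crossover sets** use the time-stratified scheme: control days are all
days of the case's calendar year-month sharing its day-of-week, excluding
the case day — always 3 or 4, and symmetric (the case day is a control of
each of its controls). Sets whose case summary is missing are emitted
flagged, not dropped. For recurrent-event analyses the first-occurrence
restriction can be lifted.

**Distributed-lag matrices** aggregate one value per lag stratum. Strata
must be contiguous and non-overlapping; daily (width-1) strata return the
raw lagged values. "Monthly" strata are 30-day blocks by convention —
calendar months have no fixed width when counted backward from an arbitrary
index date — and yearly strata are 365-day blocks.

## Synthetic data

The grid generator composes mean level + planar trend + a few Gaussian
spatial bumps + annual seasonality (365.25-day cycle, so leap days share the
cycle) + a spatially uniform AR(1) day anomaly + iid cell-day noise, with an
optional static missing-cell mask. Defaults emulate a daily PM2.5 product at
toy scale: mean 12 µg/m³, AR(1) coefficient 0.8 with innovation sd 5 µg/m³
(stationary sd ≈ 8.3, realistic day-to-day variability with ~0.8 lag-1
autocorrelation), seasonal amplitude 3 µg/m³ peaking in winter, cell noise
sd 1.5 µg/m³ on 1 km cells.

The cohort generator draws residential coordinates uniformly over the grid
and rounds them to a 100 m lattice, mimicking privacy-buffer centroids;
histories start at the grid's first day, moves arrive as a Poisson count per
subject at uniform times, periods abut, and the last period is open-ended.
Events are drawn daily with hazard baseline · exp(β · z / 10), where z is
the configured backward lag-window mean of the subject's **true** exposure:
the smooth analytic field (trend + bumps + seasonality + day anomaly)
evaluated at the exact, pre-rounding coordinates. The cell-level iid noise
is treated as measurement error of the gridded product and excluded from the
truth, so the gap between a recovered and the true β measures the linkage
pipeline's misclassification cost directly. When only a realised grid is
available (no generator model), bilinear interpolation at the exact
coordinates serves as the operative truth.

What the generator does **not** emulate: real geography and population
density, spatially varying day anomalies (the synoptic term is uniform over
the toy domain), weekday structure in exposure or baseline hazard,
covariates and confounders, and competing risks. Passing tests therefore
demonstrate the correctness of the linkage mechanics and the calibration of
the designs under these idealised conditions, not the behaviour of any real
exposure product.

## Statistical checks and problem sizes

Two simulation studies back the summary designs, both run by the test suite
and by `scripts/acceptance.py`:

- **Null calibration**: 200 replicates of an 8×8 two-year grid with 150
  subjects each (~50 events per replicate, baseline hazard 1e-3/day) through
  the full pipeline into a time-stratified case-crossover conditional-
  logistic fit; the 95% CI for the odds ratio should cover 1 in ≥ 90% of
  replicates.
- **Effect recovery**: one 12×12 ten-year grid with 900 subjects and a
  short-term effect of β = log(1.2) per 10 µg/m³ on the lag 0–3 mean
  (~2,500 events); the recovered β̂ should land within 0.05 of the truth.
  The Monte-Carlo standard error of β̂ at this size is ≈ 0.035, so the 0.05
  band is ≈ 1.4 standard errors: an occasional seed will fall outside it
  even with a perfectly calibrated estimator, which is the expected
  behaviour of an unbiased method at this problem size.

These sizes were chosen so each study completes in well under a minute on a
single CPU while leaving the estimators enough events to be informative.

## Known limitations

- The long-CSV reader infers the lattice from the observed coordinates; a
  grid whose entire edge row or column is missing will be read with a
  shifted origin (interior missing rows/columns are handled, since all gaps
  must be integer multiples of the smallest spacing).
- The "monthly" lag strata are 30-day conventions, not calendar months.
- Case-crossover sets for recurrent events within the same stratum are
  emitted as independent sets with each other's event days serving as
  control days, the standard practical convention; the exact joint
  conditional likelihood for multiple events in one stratum is not
  implemented.
- Activity-space or workplace exposures, imputation of gap days, and model
  fitting beyond the demonstration tests are out of scope.
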