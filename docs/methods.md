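# Methods

This note documents the models and procedures implemented in `geolux`,
the defaults they run with, the design choices made where several
reasonable options existed, and the known limits of what the synthetic
tests demonstrate.

## Solar geometry

Sun elevation uses a standard low-accuracy solar ephemeris (USNO
"approximate solar coordinates"): mean anomaly and mean longitude linear
in days since J2000, a two-term equation of centre, linear obliquity,
declination and the equation of time from right ascension, then the
hour-angle equation. Against an independent higher-accuracy ephemeris
(a Meeus-style apparent-position computation kept in the test suite) the
worst error over 1990–2055 and |lat| ≤ 65° is ≈ 0.005°, far inside the
0.3° the threshold method can tolerate (0.3° of sun elevation is about
one minute of twilight timing). Refraction is not modelled separately;
in threshold geolocation it is absorbed into the calibrated
sun-elevation angle, which is the parameter of interest anyway.

Predicted twilights invert the hour-angle equation and re-evaluate the
solar coefficients at the predicted instant (three fixed-point
iterations; residual elevation error < 0.05°). Polar day/night returns
an explicit no-solution result.

## Twilight detection

Threshold crossings (default 3 lx) are located by linear interpolation
between the straddling samples, on raw lux. Each local solar day keeps
at most one sunrise (the earliest upward crossing) and one sunset (the
latest downward crossing); extra crossings — shading dips — collapse
onto those outermost crossings, because shading can only darken, so the
outermost crossings are the least biased. Extras farther than a guard
window (default 30 min) from the kept crossing flag the event. This
collapse rule is this package's explicit stand-in for the manual
twilight editing that field workflows apply before analysis.

## Position estimation

Longitude: local solar noon (midpoint of the twilight pair) against
12:00 UTC with the equation-of-time correction always applied — omitting
it introduces a ±4 min (≈ ±1° longitude) seasonal bias.

Latitude: vectorised bisection on the closed-form day-length equation,
using the symmetry D(φ, δ) = D(−φ, −δ) to make the problem monotone. A
conditioning floor declares latitude missing when
|∂(day length)/∂φ| < 1 min/°: this is the explicit, testable version of
the equinox degeneracy. Independently, latitudes within ±10 days of
March 20 / September 22 are masked (calendar dates are used; the sub-day
astronomical drift of the equinox instant is negligible against a
ten-day window). One position per sunrise→sunset pair ("noon" fix) is
produced; midnight fixes are not, since the source workflow's convention
is not recorded and one fix per day keeps the segmentation simple.

Near the mask boundary (10–20 days from an equinox) latitudes are
formally present but poorly conditioned: a minute of twilight noise maps
to degrees of latitude. Period statistics inherit that uncertainty, and
the recovery tests treat such sites as latitude-indeterminate.

## Sun-elevation calibration

The angle grid spans −6°…+1° in 0.25° steps; the published best-fit
range for this kind of data (−3°…0°) lies well inside it, and the grid
bound is a search bound, not a prior.

**Hill-Ekström.** For each candidate angle, latitudes are computed for
all fixes inside known-stationary windows (excluding dates within 25
days of an equinox — a wider buffer than the 10-day reporting mask,
because calibration needs well-conditioned latitudes, not merely
unmasked ones). Two comparability rules matter in practice:

1. within a window, only fixes whose latitude is finite at *every*
   scanned angle enter the variance — otherwise the objective compares
   different fix sets at different angles, and windows straddling the
   equinox generate spurious minima where badly-conditioned fixes drop
   in and out of the scan;
2. window variances combine df-weighted (the pooled within-window
   variance) rather than as a plain sum — a short noisy window would
   otherwise drown out a long, well-conditioned residency. In seeded
   experiments this raised the shaded-noise angle-recovery rate from
   ≈ 90% to 96–100%.

The chosen angle is the grid argmin, ties broken toward the least
negative angle. Windows are supplied by the caller or derived
automatically: because longitude does not depend on the angle, the track
is segmented on longitude first, and the resulting stationary windows
are screened to those with at least 20 fixes clear of the equinox buffer
and a provisional |latitude| ≤ 35°. The latitude screen exists because
the variance objective degenerates for temperate-summer stays — pushing
candidate angles so that latitudes approach the polar-day boundary
shrinks the variance without bound — whereas tropical winter residencies
are well conditioned. This mirrors field practice: Hill-Ekström
calibration is classically applied to the winter stationary period.

**Known-site.** Over a pre-departure window at the capture site
(minimum 5 days), each angle's fixes are scored by RMS rhumb distance to
the known location; smallest wins. On clean data the two methods agree
within 0.5°, which is the package's analogue of the observation that
breeding-site calibration and Hill-Ekström give similar spatiotemporal
patterns.

## Segmentation and labelling

A stationary period is a maximal window in which every daily longitude
lies within `dev_tol` of the window median and the first-two-day and
last-two-day mean longitudes differ by at most `net_tol`, spanning at
least 5 calendar days. Defaults `dev_tol = net_tol = 2°` are roughly
twice the clean-data longitude noise; the stationarity criterion uses
longitude only (latitude is unusable near equinoxes), though latitude
statistics are reported per period. The greedy left-to-right scan
(earliest feasible start, farthest feasible end) is tested equal to
exhaustive window enumeration. Adjacent windows separated by ≤ 3 days
with median longitudes within `dev_tol` are re-joined: longitude noise
can split one residency, and moves below the ≈ 2° longitudinal
resolution of the threshold method are not resolvable in any case.

Outlier removal is a single pass (no iteration): a fix is dropped iff
its longitude, or its present latitude, deviates strictly more than 10°
from the period median; medians are then recomputed once.

Labels follow the flyway's geometry. The leading run of periods still at
the deployment longitude is the breeding stay. Winter opens at the first
period that is (a) south of the Sahara (median latitude < 20° N, with a
fully-masked period counted as southern when it starts after the date of
the track's westernmost fixes — the detour turn is already in the
Sahel), (b) at least 14 days long, and (c) clearly east (≥ 2°) of the
westernmost longitude, i.e. after the coastal detour turn. Everything
between breeding and winter is staging. The 14-day floor resolves the
ambiguity between long post-Sahara staging and winter residency in
favour of winter; the timing table additionally reports the banded count
of staging sites of 5–12 days duration, so both readings are available.

## Metrics

Rhumb-line (loxodromic) geometry on a 6371-km sphere, via meridional
parts; along a parallel the distance reduces to Δλ·R·cos φ. Verified
against an independent geodesic implementation (R `geosphere`, values
frozen in the test fixtures) to 0.1% and to machine precision in spot
checks. Centres of mass are arithmetic means of decimal degrees with no
dateline handling — valid for this flyway's span (≈ −15°…+24° E) and
documented as a limitation.

Winter spread: five-day bins; per-individual centre of mass; population
centre longitude = mean of individual centre longitudes; each
individual's spread is the rhumb distance from the population-centre
longitude to its own centre measured along its own parallel (matching
the centre-longitude-only definition of the population reference). Bins
with one individual report a missing spread.

Detour projection: the bird is assumed to travel one rhumb leg from the
last European staging site at 300 km/day; the bearing is solved
(southwest quadrant, Brent root-finding on the destination longitude) so
the leg ends at the observed westernmost longitude (mean of the three
westernmost fixes, first-arrival date), and the leg's end latitude is
reported. Individual projections carry the ±2-day ambiguity of the turn
date (≈ ±2° latitude); the population mean is the reported quantity and
is recovered within ≈ 0.5° on synthetic studies.

## Vegetation analyses

NDVI rasters are 16-day composites on a regular lat/lon grid,
timestamped at composite start. Site extraction averages pixels whose
centres fall inside a geodesic circle of 50 km (pixel-centre inclusion;
at 0.05–0.1° resolution this agrees with area weighting to within about
one pixel ring). A composite is attributed to a date range when its
16-day span overlaps the range, so the composite covering an arrival
date is included. Within-site trend is the OLS slope of buffer-mean
NDVI against day, with Pearson r; between-site change compares the last
composite at the old site with the first at the new one (usually the
same or the adjacent composite, so the seasonal term largely cancels and
the spatial difference dominates); among-year consistency correlates the
site-vector of winter-mean (Nov–Feb) NDVI between winters, requiring at
least three sites.

## Statistics

Sign test: exact binomial(n, ½), two-sided p = 2·min(tails) capped at 1;
ties are dropped upstream and logged. Twelve concordant moves of twelve
give p = 2·0.5¹² = 0.000488, printing as 0.0005. Pearson r with the
t-based p on n−2 df. Levene's test in its classic mean-centred form
(the variant plainly called "Levene's test"; the median-centred
Brown-Forsythe flavour is available by flag). Welch's t with
Satterthwaite df. All four are written from their defining formulas with
only the t/F distribution functions taken from scipy, and are tested
against reference implementations to 1e-9 and for nominal type-I error.
No multiple-testing correction is applied anywhere, matching how this
kind of exploratory field study reports its tests; this is deliberate.

## Synthetic data: what it emulates, and what it does not

The study generator builds 15 itineraries shaped like the source
deployment: breeding at 55.61° N 12.57° E from late May, departure in
early August (±6 d), an Iberian staging site (≈ 40° N, −4.5° E,
7–34 days), a coastal detour to a westernmost turn at −14.4° ± 1.4° E
near 11.7° N (0–21 days), a first winter site with longitude uniform on
[−11.5°, 19.7°] — the spread regime of the study population — and, for
12 of 15 birds, a second winter site south and east of the first,
occupied until tracking ends in February. Two deployment years are
interleaved. Movement legs run along rhumb lines at exactly 300 km/day
(gap = ceil(distance/speed) days; great-circle interpolation is a config
option). Itinerancy moves are drawn at ≥ 2.5° of longitude and ≥ 1° of
latitude: moves below the threshold method's ≈ 2° longitudinal
resolution would be invisible to the analysis, as they would have been
to the source study. A consequence of the exact-speed legs is that the
simulated migration takes ≈ 45–55 days, at the fast end of the real
50–92-day range — real passage includes slack the generator does not
model.

Light is an exponential function of sun elevation: one decade of lux
per 3° of elevation, anchored at 3 lx exactly at the reference
sun-elevation angle (default −1.5°), clipped at 10,000 lx, sampled every
5 minutes (Intigeo-class cadence). The 3°/decade transition keeps the
linear-in-lux crossing interpolation accurate to well under a minute at
that cadence; with a much steeper response the interpolation itself
biases twilights by minutes, which real workflows absorb into the
calibrated angle. Shading events (Poisson per day, mean 90 min,
multiplicative attenuation 0.2) only darken, so they delay sunrise and
advance sunset — the day-shortening bias that calibration must absorb;
clock jitter perturbs morning and evening timing independently
(default sd 2 min). Together these produce day-length errors of ≈ 3.5
min sd, typical of field-grade twilight data after editing. Not
modelled: weather, radiative transfer, logger clock drift beyond
Gaussian jitter, or behaviourally-structured shading (e.g. habitat
choice at dawn).

NDVI fields are a north–south greenness gradient (−0.015 NDVI/° lat,
greener southward), a triangular seasonal cycle whose dry-season segment
(1 Oct–1 Mar) declines linearly at −0.0025 NDVI/day (a typical Sahel
dry-down rate, matching the magnitude such studies report), white
per-composite noise (sd 0.01), and a per-winter random field
(sd 0.005) that perturbs but does not destroy the stable spatial
pattern. The within-pixel dry-season slope is exactly the configured
slope in the noise-free case (the seasonal term is piecewise linear and
composites are timestamped at period start). Real NDVI has QA artefacts,
spatially correlated noise and interannual phenology shifts that this
model does not attempt.

Passing the synthetic suite therefore shows that the pipeline inverts
its own generative assumptions correctly and robustly at realistic noise
levels — it does not certify accuracy on any particular real logger,
where light response, shading structure and habitat are different.

## Numerical choices and degenerate inputs

- Latitude bisection: 55 iterations on [−89.9°, 89.9°]; residual
  day-length tolerance 0.5 min; conditioning floor 1 min/°.
- Calibration needs ≥ 5 finite latitudes per window (windows below that
  drop out); no scanned angle usable raises a calibration error.
- Empty fix series, all-dark days, polar day/night, single-individual
  spread bins, constant NDVI series, and all-outlier periods all have
  explicit, tested behaviours (empty results, flags, missing values, or
  errors naming the offending record).
- All timestamps are UTC; longitudes live in [−180°, 180°), enforced at
  module boundaries.

## Known limitations

- Longitudinal resolution ≈ 2° at the segmentation defaults: stationary
  sites closer than that in longitude merge, and boundaries of stops
  approached along a meridian (slow longitude change) blur by a few
  days. When a track's two winter sites are longitudinally confounded,
  the calibration windows mix two latitudes and the chosen angle can
  shift by up to two grid steps, biasing that track's latitudes by
  1–2°.
- Latitude 10–20 days from an equinox is reported but poorly
  conditioned; treat it as indicative only.
- Centre-of-mass longitudes assume the study's span stays far from the
  antimeridian.
- The detour projection is a population-level quantity; individual
  projections inherit the turn-date ambiguity.
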