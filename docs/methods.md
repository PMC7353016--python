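# Methods

This note records the statistical model `selmap` implements, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not establish.

## Data model and cohort processing

The unit of record is one surveyed individual: enumeration area (EA),
region, demographic group (young children, school-age children, men,
women of reproductive age), sex, residence, survey weight, WGS84
coordinates and serum Se in µg/L. Records are screened in a fixed
precedence — missing GPS, then missing demographics, then flagged
outliers — so each exclusion is counted exactly once and the audit log
reconciles by construction. Outlier flagging uses Tukey's fences on the
unweighted sample with type-7 (linear-interpolation) quartiles: values
beyond Q1 − 3·IQR or Q3 + 3·IQR are "probable outliers". The same screen
is applied twice, deliberately and independently: once to individual
serum values before any aggregation, and once to EA means before
variography. An EA mean flagged at the second screen is excluded from
variogram estimation only; it is reinstated as data for kriging
prediction (extreme but credible observations should inform local
prediction even when they would destabilise variance estimation).

Summaries are survey-weighted by default (a flag gives unweighted
output, since published tables of this kind are often ambiguous about
which statistics the weights entered). The weighted quantile is the
inverse of the cumulative-weight CDF after pooling duplicate values, with
the midpoint of adjacent distinct values taken when a probability lands
exactly on a jump boundary; with equal weights this reproduces the
ordinary sample median. Prevalence uses the strict inequality
(serum < threshold). The GPx3 threshold is derived, not hard-coded: the
midpoint of the 1.00–1.15 µmol/L optimal-activity range times the molar
mass of Se (78.97 g/mol, configurable), rounded to 0.1 µg/L → 84.9.

EA aggregation takes arithmetic means of serum values and of raw
lat/lon degrees. EAs are a few km across while the field's effective
range is ~400 km, so the planar-averaging error in the centroid is
negligible against the lag scale.

## Geometry

All lags are great-circle distances on a sphere of radius 6378.137 km
(configurable), computed with the haversine form; no projection is ever
applied, because no single planar projection is acceptable across a
domain spanning ~12° of latitude. Bearings are taken at the arrival
point of the arc and folded to [0, 180) for directional variography,
since a lag and its reverse belong to the same direction class.

## Variography

Three per-bin estimators are implemented; with *d* the pair differences
in a bin of *N* pairs:

* Matheron: Σd² / (2N)
* Cressie–Hawkins: (mean |d|^½)⁴ / (2(0.457 + 0.494/N))
* Dowd: 2.198 · median(|d|)² / 2

Default binning is 25 equal-width bins from 0 to **0.3× the maximum pair
distance**, each bin requiring ≥ 30 pairs, with the fit positioned at the
mean pair distance within each bin (not the midpoint; with pair density
growing with lag, midpoints misplace the short-lag bins where the nugget
information lives). The 0.3 cutoff is close to the bbox-diagonal/3
convention of gstat. We verified by simulation (300 replicates from the
default model at 345 uniform locations) that extending the cutoff to
half the maximum distance — so that ~80% of bins sit at the sill —
roughly doubles the mean error of the recovered nugget and distance
parameter; the long lags add almost no information about the model but a
lot of single-realization fluctuation.

The exponential model is fitted by weighted least squares with bounded
multistart (3 deterministic starts, lowest objective wins; c0, c1 ≥ 0).
Two weight schemes are available; the default is Cressie's
n_k/γ(h_k;θ)², with plain pair counts n_k as the alternative. The same
simulation experiment showed plain pair-count weights let the many-pair
sill bins dominate, inflating the mean recovered nugget and distance
parameter by ~2×, while the Cressie scheme brings both within ~15% of
truth. The distance parameter is bounded above by the largest fitted lag:
the data cannot inform a range beyond the observed lag span, and the
unbounded exponential model has a degenerate ridge (a and c1 growing
together to mimic a straight line) that multistart optimisation
occasionally finds.

Directional variograms use 4 classes of 45° centred at 0/45/90/135° by
default; they exist to check the isotropy assumption, not to fit
anisotropic models.

## Kriging and validation

Ordinary kriging uses a global neighbourhood — every EA mean enters
every system. At ~350 data points one symmetric-indefinite factorization
of the bordered matrix serves all grid nodes, and a global
neighbourhood avoids the artifacts of moving search windows. Duplicate
data locations are collapsed to their mean with a warning (a duplicate
with zero nugget is exactly singular). Kriging variances within a small
negative rounding tolerance are clipped to zero; larger negatives raise.

Leave-one-out cross-validation standardizes each squared error by its
kriging variance (SSPE). Under a valid model with Gaussian errors each
SSPE is χ²₁, median 0.455. Because the LOO weights depend only on the
layout and the model, they are computed once and reused: the 95%
validity interval of the median SSPE is obtained by simulating (default
1000) Gaussian fields from the fitted model at the actual data locations
and pushing each through the precomputed weights. The interval is
layout-specific, not a universal constant. Model selection accepts the
Matheron fit outright when its median SSPE falls in its interval (it is
the most efficient estimator, so the robust fits are then never
cross-validated); otherwise the robust fits are cross-validated and the
valid one with median closest to 0.455 wins; if none validates the
pipeline aborts explicitly rather than mapping with an invalid model.

One caveat the user should know: the model being cross-validated was
fitted to the same realization, which biases the median SSPE slightly
below 0.455 on average (the interval simulation assumes the model is
independent truth). Marginal selection failures on perfectly reasonable
data are therefore possible, and the pipeline reports them as failures
rather than silently proceeding.

## Risk mapping

The prediction distribution at a node is taken as Gaussian with the OK
mean and kriging variance — a plug-in assumption implied by using those
two moments, stated here prominently because exceedance probabilities
inherit it. P(Z < t) = Φ((t − Ẑ)/σ), with the degenerate σ = 0 case
mapping to {0, ½, 1}. The phrase scale follows the IPCC calibrated
vocabulary, made non-overlapping (the published ranges overlap at their
endpoints): exceptionally unlikely [0, 0.01), very unlikely [0.01, 0.10),
unlikely [0.10, 0.33), about as likely as not [0.33, 0.66), likely
[0.66, 0.90), very likely [0.90, 0.99), virtually certain [0.99, 1].
Interior boundaries belong to the upper bin. Grids are regular in
degrees, with km spacing converted at the domain's central latitude and
nodes filtered to the boundary polygon.

## Synthetic surveys

The generator states one world and keeps it: 346 EAs uniform in a
lon 33–48°E, lat 3–15°N box; EA-mean serum Se drawn from a Gaussian
random field with covariance c1·exp(−h/a) plus iid nugget c0
(measurement-error interpretation), defaults c0 = 2.51, c1 = 26.23
(µg/L)², a = 132.8 km, mean 100 µg/L; group totals 584/1034/419/1339
(YC/SAC/MEN/WRA, 3376 records) allocated round-robin so configured
counts are met exactly; missingness by rate or exact per-group counts;
optional extreme-value injection for the outlier screen. Fields are
drawn by dense Cholesky with 1e-8·sill diagonal jitter. Serum values are
resampled below 1 µg/L (truncation is negligible at the default
mean/sill but keeps the support physical).

Within-EA individual scatter defaults to 3 µg/L. This is deliberately
small: an EA mean of ~4 group members inherits sd²/4 of sampling noise,
and a "biological" sd of 25 µg/L would add ~160 (µg/L)² — burying the
stated EA-level covariance entirely. With sd = 3 the aggregation noise
(~2.3) is on the order of the nugget, so the individual-level and
EA-level worlds are mutually consistent. The flip side is documented as
a limitation below.

A deterministic 3376-record fixture reproduces a published survey's
exclusion anatomy exactly — 101 GPS-missing (5 men, 63 young children,
24 school-age children, 9 women), 5 demographic-missing (3 school-age
children, 2 women), one injected extreme serum value among the women —
and, among the 3269 retained, the published composition: 1327 women of
reproductive age (40.6%), 841 urban / 2428 rural (74.3%), 284 male young
children, 451 male school-age children.

**What a green test does not establish.** The generator emulates the
spatial field, the clustering and the exclusion structure, not the full
marginal distribution of individual serum Se: real surveys of this kind
show individual IQRs spanning tens of µg/L driven by diet, inflammation
and demography, which this world compresses. Prevalence machinery is
therefore exercised for correctness (weights, strict inequality,
monotonicity), not for realistic national prevalence levels. The
generator also ignores the preferential (population-proportional)
placement of real EAs, household clustering within EAs, and real admin
boundaries — uniform placement in a bounding box stands in for all
three.

## Numerical conventions

* Quantiles: type-7 for Tukey fences; documented cumulative-weight rule
  for weighted summaries.
* Lag bins are left-closed; zero-distance pairs never enter a variogram.
* All Monte-Carlo operations take an explicit seed; there is no hidden
  global random state, and the WLS multistart perturbations use a fixed
  internal generator so fits are deterministic.
* Bordered kriging systems are solved with scipy's symmetric-indefinite
  path (`assume_a="sym"`); the LOO weight matrix is dense, suitable for
  the few-hundred-EA regime this package targets (n ≲ 3000 for field
  simulation, n ≲ 1000 for LOO).

## Known limitations

* Exponential variograms only — the one family generally valid on the
  sphere; no Matérn/spherical alternatives, no REML/ML fitting.
* Plain ordinary kriging: no covariates, no trans-Gaussian or indicator
  variants; exceedance probabilities are plug-in Gaussian, not derived
  from conditional simulation.
* Survey weights are consumed, never constructed; no design-based
  confidence intervals on prevalence.
* The SSPE validity check inherits the same-data fitting bias described
  above.
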