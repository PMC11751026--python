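# Methods

## Data model and censoring

The universal input is a long-format residue table: one row per (site,
management system, matrix, distance class, month, compound) with a
concentration in µg/kg dry weight (≡ ng/g) and a censoring status. Months
are an ordinal index 0–12 covering February of year 1 through February of
year 2; calendar parsing is a reader concern only. Distance classes map
in-field → 0 m (the in-field sample, taken 20 m inside the crop, is treated
as representative of the field-margin source strength) and the adjacent
meadow points to 1, 5 and 20 m.

Left-censoring follows monitoring convention and is enforced as a table
invariant, not a downstream habit:

* `quantified` ⟺ concentration ≥ LOQ;
* `below_loq` — the compound was seen between LOD and LOQ; it **counts as a
  detection** (CUP counts, detection frequencies, mixture keys, risk
  coverage denominators) but carries concentration **0** in every
  concentration sum;
* `not_detected` — below LOD; counts nowhere.

`not_detected` and `below_loq` are deliberately distinct statuses: only the
latter contributes to "number of CUPs detected". Units are canonicalised at
read time (µg/kg for concentrations, mg/kg for soil endpoints, ng/bee for
bee contact LD₅₀, with declared-unit columns converted on ingestion), so no
equation downstream carries a hidden factor of 1000.

## Synthetic campaign generator

The generator emulates the design of a year-long field campaign — 3 sites
per management system (arable, vegetable, viticulture) × 4 distance
classes × 13 monthly samplings × a 93-compound target list (36 fungicides,
36 herbicides, 21 insecticides) in topsoil and vegetation — with a
mechanistically minimal but statistically faithful model:

* **Application calendars.** Each compound is assigned to zero or more
  systems with per-compound pulse months. Arable land gets spring
  programmes plus an autumn herbicide window; vegetable fields get
  staggered succession-planting pulses; viticulture is fungicide-heavy with
  a May–August spray programme and essentially no insecticides. Roughly a
  quarter of the roster is applied nowhere, emulating a target list wider
  than the compounds actually in use.
* **Soil.** The non-intercepted dose fraction enters topsoil and dissipates
  first-order with a per-compound half-life `dt50` (0.3–1.5 months). The
  same calendar is assumed to have run in the previous season
  (`soil_carryover`, default on), so persistent compounds carry a non-zero
  baseline into the first February — fields are not pristine at campaign
  start, and soil counts show a year-round baseline rather than a winter
  zero.
* **Vegetation.** The intercepted fraction (default 0.75) lands on the
  standing crop and declines geometrically by a per-month dilution factor
  (default 0.30, lumping growth dilution and wash-off). Off-field meadow
  vegetation is additionally reset by mowing events (default months 4 and
  8); a pulse applied before a cut no longer contributes after it.
* **Drift.** Off-field concentration at distance *x* is the in-field level
  times `exp(b_true·x)`, with per-system `b_true` of −0.35 (arable), −0.47
  (vegetable) and −0.60 (viticulture) m⁻¹.
* **Observation.** Observed = noiseless × lognormal noise with mean 1 and
  CV `noise_cv` (default 0.3), then censored per compound at LOD/LOQ
  (defaults cycle over LOQ 1/2/5 µg/kg with LOD = 0.3·LOQ). Everything is
  deterministic under a fixed seed; compound doses and half-lives are a
  package constant drawn once from a fixed internal seed.

Defaults were chosen so the generated campaign reproduces the descriptive
structure such studies report — on the order of 10 CUPs per soil sample and
7 per vegetation sample on average, an in-field maximum in the high
twenties to thirties, a persistent soil baseline with summer maxima, and
standing-vegetation compound counts cresting in June–August.

**Ground truth.** Alongside the table the generator returns the noiseless
concentration of every record, the true per-system drift decay, and the
planted seasonal maxima. The planted peak months are defined
operationally: the same detrend + δ-threshold detector the analysis uses,
applied to the *noiseless* in-field detected-count series — i.e. the
estimator's noise-free target, not a hand-picked month list.

**What the generator does not emulate.** Crop-specific interception and
growth stages, weather-driven drift, leaching, volatilisation, metabolite
formation, spatial heterogeneity within a field, analytical batch effects,
and between-replicate structural differences (replicate sites differ only
by measurement noise). Passing tests therefore demonstrate estimator
correctness under the assumed generative structure, not robustness to every
feature of real field data — in particular, the generator produces far more
empty off-field vegetation samples in winter than a real campaign would.

## Loess smoothing and KL divergence

The seasonal statistic is the per-month mean of per-sample detected-CUP
counts over the pooled replicate sites of one (system, matrix, distance
class). The smoother is a hand-rolled locally weighted polynomial
regression: tricube weights over the `⌈span·n⌉` nearest points, local
degree 2 by default (degree 1 reproduces the classical lowess and is
cross-checked against `statsmodels` in the tests), no robustness
iterations. The span is selected by leave-one-out CV over the candidate
grid {0.3, 0.4, …, 1.0}; ties break towards the largest (smoothest) span;
infeasible windows are skipped.

KL divergence needs distributions, so each smooth is floored at
ε = 1e−6 (clipping any negative excursion of the quadratic fit) and
L1-normalised over the 13-month grid; ε and the smoothing settings are
recorded in the outputs. The divergence is reported in bits. The floor
makes KL finite and non-negative on the ε-simplex; identical inputs give
exactly 0.

## Peak detection

A single forward pass tracks running maximum and minimum candidates; when
the series moves more than δ away from the current candidate, that
candidate is emitted (position and value) and the search direction flips,
so emitted kinds alternate strictly. δ defaults to 0.3 in the units of the
detrended statistic (CUP counts). Detection operates on residuals of an OLS
line of value on month, which removes the annual trend so that δ measures
short-term fluctuation. Convention decided here (the classical algorithm
leaves it open): a trailing candidate the series never moves δ away from
remains *pending* and is not emitted; the first emission's kind is
determined by the first δ-crossing.

## Exponential distance decay

Model `y = a·e^{bx} + c` for per-sample response vs. metres from the
margin. `c` is **fixed, never estimated**: by the stated convention it is
the mean response of the x = 0 (in-field) subset of the same matrix ×
system. Only (a, b) are free, fitted with Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `lm`, xtol/ftol/gtol 1e−12,
initialisation a₀ = max(mean(y|x=0) − mean(y|x=x_max), 1e−3), b₀ = −0.1).
`b` is unconstrained; fits with b > 0 or a ≤ 0 are returned but flagged.
The x = 0 observations are included in the residual sum by default
(`include_infield` switch).

Two caveats, both deliberate:

* Applied to *counts* with the in-field-mean background, the model is
  internally tense — the background then nearly equals the fitted value at
  x = 0, so the optimiser typically returns a small negative `a` with
  b > 0, which the result flags. The fit is still a usable summary of the
  gradient shape; `c` can alternatively be supplied explicitly (e.g. 0 for
  concentrations, which vanish far from the field).
* On campaign totals, left-censoring removes sub-LOQ mass preferentially at
  far distances, biasing the fitted decay steep by roughly 10–20% at the
  default LOQs. Parameter-recovery tests therefore distinguish the
  censoring-free model-based check (recovery to optimizer tolerance
  noiseless, within 15% under CV-0.3 lognormal noise at n = 156) from the
  campaign-level fit, where the truncation bias is expected.

## Mixture risk and hazard

* **PNEC** (mg/kg soil) = NOEC/10, or LC50/1000 when no NOEC exists; NOEC
  preferred when both are present. Collembola use NOECs only; earthworms
  may fall back to LC50.
* **RQ** = MEC/PNEC (both in µg/kg after conversion); **MRQ** = Σ RQ over a
  sample's compounds. Below-LOQ detections contribute RQ = 0 but count in
  the coverage denominator; compounds without an endpoint are excluded from
  the sum (never imputed) and reduce `coverage`.
* **Categories** are left-closed: negligible [0, 0.01), low [0.01, 0.1),
  medium [0.1, 1), high exactly 1, very high > 1. The source conventions
  disagree at the edges; both "high" and "very high" mean at/above the
  threshold of 1 in summaries.
* **Bee hazard**: HQ = (2.23 g × MEC [ng/g]) / (LD₅₀ [ng/bee] / 10), the
  2.23 g being the soil a female ground-nesting bee contacts during 48 h of
  burrowing and the divisor 10 converting the honey-bee endpoint to a
  surrogate solitary-bee LD₅₀. MHQ = Σ HQ; the hazard flag is strictly
  MHQ > 1. All mass terms are ng, so the quotient is dimensionless.
* **Attribution**: `rq_max` (resp. `hq_max`) is the largest single-compound
  quotient; the share of risk explained by one compound is the per-sample
  fraction rq_max/MRQ, averaged over samples (computing it on summed
  quantities instead is possible but not the default).
* **Aggregation**: arithmetic mean and max over the n = 3 replicate sites
  per (system, month, distance class); groups with missing replicates are
  flagged, not silently averaged.

MRQ/MHQ are exactly additive — the engines are tested against brute-force
sums to 1e−12 and under compound-set partitions.

## Problem sizes and reproducibility

The default campaign is 87 048 records (9 sites × 4 distances × 13 months ×
93 compounds × 2 matrices); a full pipeline run takes a few seconds on one
core. Tests use the full design where the check concerns campaign structure
and reduced rosters (6–12 compounds) for closed-form oracles. All
randomness flows from explicit seeds (`numpy.random.default_rng`); reruns
with the same config and seed produce byte-identical outputs, which the
pipeline manifest verifies by content hash.

## Known limitations

* Additivity is assumed for mixtures; synergistic interactions are out of
  scope, so MRQ/MHQ are lower bounds under synergy.
* Only soil contact exposure enters the bee hazard; oral and
  vegetation-mediated routes are not modelled.
* The loess/KL comparison provides no significance test; KL magnitudes are
  descriptive.
* The in-field-mean background convention makes count-based decay fits
  qualitative (see above); confidence intervals for (a, b) are not
  computed.
* Endpoint tables generated synthetically are labelled as such and only
  emulate the magnitude structure of regulatory databases.
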