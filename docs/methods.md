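# Methods

`poctherm` asks whether burial temperature controls the long-term (millions
of years) degradation of particulate organic carbon (POC) in marine
sediments, using the statistical design of the global ocean-drilling POC
compilation: a kinetic forward model ranks drill sites by the temperatures
their sediments experienced, and the POC-versus-age relationship is then
compared between the coldest and warmest site sets with weights that remove
the confounding influence of sedimentation rate.

## Forward model and temperature score

Each site needs an age-depth model (piecewise-linear interpolation between
dated horizons, with a virtual node at the seafloor: depth 0, age 0) and a
linear geotherm `T(z) = T_sf + Γ z` fitted by ordinary least squares to the
in-situ temperature measurements.  Quality control keeps sites with at
least 2 measurements, r² ≥ 0.95 when 3 or more points make r² informative,
a positive gradient, and a fitted seafloor temperature within 2 °C of the
near-bottom water temperature.  The r² and offset thresholds are
configurable defaults: the underlying criteria ("well-defined linear
gradient", "consistent with bottom-water temperature") are qualitative, so
these are our quantitative renderings.  Two-point fits pass the linearity
check trivially (r² is not informative there), since some sites legitimately
carry only two measurements.

For a sediment parcel whose present age is `a`, the burial temperature
history on an even grid of elapsed times `t ∈ [0, a]` is

    depth(t) = z(a) − z(a − t),      T(t) = T_sf + Γ · depth(t),

which assumes the present gradient and depth-age relation held throughout
burial.  The labile (degradable) fraction `G` of deposited POC follows
first-order kinetics with the Arrhenius rate constant

    k(T) = A · exp(−Ea / (R T)),     dG/dt = −k(T(t)) · G,

with defaults `A = 3e18 /Ma` and `Ea = 110 kJ/mol`, chosen so predicted
degradation over 0–10 Ma spans the full range from negligible (cold, slowly
buried sites) to complete (warm, rapidly buried ones).  `G` is evaluated as
`G0 · exp(−∫ k dt)` with the integral taken by the trapezoidal rule on the
history's time grid — integrating `k` and exponentiating once is far more
accurate at high `k` than stepping `G` itself.  The per-parcel grid uses
`n_steps = 200` (default); halving the step moves site scores by < 1e-4,
two orders of magnitude below between-site score differences.

The site's predicted curve `G(t)` is evaluated at 100 evenly spaced ages on
[0, 10] Ma (both endpoints included, spacing 10/99 Ma) and summarised by the
temperature score

    S = 1 − (1/10 Ma) · ∫₀¹⁰ G(t) dt,

a number in [0, 1]: 0 when nothing degrades, approaching 1 when degradation
is immediate.  Only the *ordering* of S is consumed downstream, which makes
the ranking insensitive to the exact activation energy (verified by a test
that halves and doubles `Ea`).  The integral uses trapezoid weights
normalised by their own sum so the two limits are exact in floating point.
Because valid age models are strictly monotone and extrapolate below the
deepest node with the last segment's slope, every age ≤ 10 Ma is reachable
at finite depth and no truncation branch is needed.

Scored sites are ranked by ascending S; the lowest `floor(0.40 N)` form the
low-temperature set and the highest `ceil(0.40 N)` the high-temperature set
(82 and 83 when N = 207).  Ties break by site id for cross-platform
determinism.

## Weighted POC-age averages

Every POC measurement is annotated with its age and the local sedimentation
rate (the slope of the age-model segment containing its depth; a query
exactly on a node takes the deeper segment).  Because sedimentation rate
influences both the temperature history and POC deposition/preservation,
the low- and high-temperature sets differ systematically in rate, and raw
set averages would confound rate with temperature.  Each point therefore
receives a distribution-matching weight

    w_i = f_target(ln r_i) / f_set(ln r_i),

where `f_target` is a lognormal fitted (mean and standard deviation of
`ln r`) over all sites with age models, and `f_set` is a Gaussian kernel
density estimate of the set's own log-rates with Silverman's bandwidth
(evaluated on a 512-point grid spanning the sample ±4 bandwidths and
interpolated — resolution far below the bandwidth, so the approximation
error is negligible).  Weights are zeroed outside the rate interval spanned
by *both* sets, capped at 20 against density-tail instability, and rescaled
to mean 1 over the nonzero-weight points (rescaling never changes a weighted
mean; it stabilises the bootstrap).  The cap and the point-level common
range are our choices where the procedure's description is silent.

POC-age curves are computed in equal-count age bins: points are sorted by
age and cut into `floor(n / target)` rank blocks (targets: 250 points per
bin for the all-site curve, 70 for per-set curves), with edges midway
between straddling ages and the remainder folded into the last bin.  The
uncertainty of each binned weighted mean is the central 68% interval (±1σ
for a normal) of 1000 bootstrap resamples of the bin's points, weights
travelling with their points.  Interval averages over 1–2 Ma and 5–10 Ma
summarise the early and late parts of the curves.

## Randomization test

The observed statistic is `|mean_low − mean_high|` of the 5–10 Ma weighted
averages (two-sided reading of "as large as or larger"; a signed one-sided
variant is exposed via `statistic="signed"`).  Each of 1000 iterations draws
two disjoint random site sets of the observed sizes, recomputes the common
range, the per-set weights, and the statistic; the p-value is the plain
fraction of iterations with a statistic ≥ the observed one (no continuity
correction).  Iterations in which either random set has no weighted data in
the age interval are redrawn, up to 10× the iteration count.

### Known limitation: mild anti-conservatism

With unit weights this test is exactly calibrated under a null ensemble
(verified: Kolmogorov–Smirnov p ≈ 0.9 over 100 null runs).  With the
distribution-matching weights it is mildly anti-conservative: the observed
partition is, by construction, extreme in covariate (rate) space, so its
recomputed weights have higher variance — hence a lower effective sample
size and a larger-variance statistic — than the near-unit weights of random
re-partitions.  Measured over 200 null calibration runs, P(p < 0.05) ≈ 0.13
rather than 0.05 and the KS statistic against uniformity is ≈ 0.12
(marginally beyond the α = 0.01 critical value ≈ 0.115).  This is intrinsic
to re-computing set-specific weights inside a randomization scheme whenever
the ranking covaries with the weighting variable — precisely the situation
the weights exist to address — so small p-values near the 5% level deserve
a grain of salt, while the effect sizes this analysis targets yield
p-values far below that regime.

## Synthetic drill-site generator

The generator is first-class, tested code that emulates the statistical
structure of the real compilation:

* **Sedimentation rates**: site medians lognormal (median 100 m/Ma, log-sd
  1.0, spanning ≈ 8–2000 m/Ma); within each site, per-segment rates jitter
  around the site median (log-sd 0.6 across 6 age-model segments).  The
  within-site variability matters: it is why the real low- and
  high-temperature sets both span nearly the full rate range and why ~90% of
  points fall inside the common rate interval; without it the synthetic sets
  separate completely in rate and the weighting degenerates.
* **Thermal state**: seafloor temperatures normal around the median
  2.67 °C (sd 0.8, floored at −1.5 °C); gradients lognormal with median
  0.053 °C/m and log-sd 0.8 (spanning ≈ 0.01 to > 0.3 °C/m).
* **Deposition history**: deposited POC rises smoothly from 1.0% at age 0 to
  a 1.3% plateau at 1 Ma and stays there, so any late decline in synthetic
  POC is attributable to degradation alone.  Each site carries a lognormal
  deposition factor (log-sd 0.4): in the real data, POC scatter at any age
  far exceeds measurement noise, and this site-level variability is what a
  site-randomization test's variance is driven by.
* **Truth and noise**: measured POC = site factor × deposition ×
  [(1 − labile) + labile · G_true], with labile share 0.7 so long-term
  profiles plateau above zero, plus method-dependent noise (sd 0.1% for
  acidified-direct, 0.25% for the TC−IC difference method) truncated at 0.
  `G_true` is computed by a local fine-grid Simpson integrator (801 points)
  that shares no code with the pipeline's integrator, so the truth table is
  an independent oracle.  Setting `Ea = 0` makes degradation
  temperature-independent; the packaged null preset also sets `A = 0`
  (no degradation), giving identical expected POC at fixed age across cold
  and warm sites.
* **Sampling**: holes are lognormal-deep (median 300 m, clipped 60–1200 m)
  and sampled every 10 m, so rapidly accumulating sites rarely reach
  sediment older than ~4.5 Ma — the same age-coverage asymmetry the real
  compilation shows.  An alternative mode (`n_samples_per_site`) draws a
  fixed number of samples evenly spaced in age, which makes sites
  exchangeable; calibration studies use it because a randomization test is
  only expected to be calibrated under exchangeability.

What passing tests on this generator do *not* show about real data: the
generator has no compaction or porosity trends, no glacial–interglacial
deposition cyclicity, no correlation between sedimentation rate and
gradient (configurable, default independent), no spatial structure, and its
POC variability model (one lognormal site factor plus iid noise) is far
simpler than real geological variability.

## Study sizes

Chosen once for the packaged studies: the headline synthetic analysis
generates 230 sites (≈ 200 scored after the deposition filter and geotherm
QC, matching the 207-site scale of the real temperature data set) and runs
the full 1000-iteration randomization test; the null-calibration study uses
200 runs of 60-site exchangeable ensembles with 200 iterations each; the
effect-recovery study uses 100 replicates of 150-site ensembles sampled
every 20 m with 200 iterations each.  Replicates whose observed
high-temperature set has no weighted 5–10 Ma data cannot define the
observed statistic and are skipped (calibration) or counted as failures
(effect recovery).

## Numerical and degenerate-input choices

* Age models with < 2 nodes, non-monotone depths, or age reversals are
  rejected at ingestion, not repaired.
* Geotherm fits require ≥ 2 distinct depths; zero depth variance is an
  error; r² of a two-point fit is defined as 1.
* `equal_count_bins` with fewer points than the target returns a single bin
  with a warning; bins with zero total weight report missing means.
* Bootstrap bands need ≥ 2 points; resamples with zero total weight are
  dropped from the percentile computation.
* Weight computation rejects non-positive or degenerate (all-equal) rate
  samples; the target fit requires ≥ 10 positive rates and non-zero
  variance up to roundoff.
* All randomness flows through `numpy.random.Generator` seeds; fixed seeds
  give bit-identical outputs, including the generator's tables.
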